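"""Statistical layer: nonparametric comparisons, ROC/Youden, logistic models.

Small-cohort conventions throughout: two-sided tests, significance at
p <= 0.05, no multiple-comparison correction (the analysis is exploratory
and each subject contributes one aggregated value per feature).  Exact
p-value paths are used where the sample sizes allow them, since group sizes
of 8-28 make asymptotic approximations questionable.

Conventions per test
--------------------
* Mann-Whitney U: mid-ranks for ties; exact enumeration when n*m <= 400 and
  there are no ties, otherwise normal approximation with tie correction.
* Wilcoxon signed-rank: zero differences dropped; exact for n <= 15 without
  ties, else normal approximation with continuity correction.
* 2x2 categorical: Fisher's exact test when any expected count < 5, else
  Pearson chi-square with Yates continuity correction (the convention of R's
  ``chisq.test``, which reported analyses of this kind use).
* Spearman: Pearson correlation of mid-ranks, t-approximation p.
* ROC: empirical curve over all thresholds; AUC by trapezoid (equals the
  mid-rank U statistic scaled by n1*n2); DeLong 95% CI; Youden-optimal
  cutoff reported as the midpoint between adjacent distinct scores, ties
  broken toward higher specificity.
* Logistic regression: maximum likelihood by IRLS, Wald inference from the
  inverse observed information, McFadden R^2, AIC, likelihood-ratio test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "categorical_test",
    "spearman_rho",
    "roc_analysis",
    "RocResult",
    "logistic_fit_univariate",
    "LogisticFit",
    "percent_change",
    "run_paper_analyses",
]


def _median_iqr(x) -> Tuple[float, float]:
    x = np.asarray(x, dtype=float)
    q1, q3 = np.percentile(x, [25, 75])
    return float(np.median(x)), float(q3 - q1)


def mann_whitney_u(x, y) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test. Returns (U of x, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("constant pooled sample: p set to 1")
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(x, y) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples. Returns (W, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all differences are zero: p set to 1")
        return 0.0, 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 15 and not has_ties) else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method,
                       correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue)


def categorical_test(table) -> Tuple[str, float, float]:
    """2x2 count comparison. Returns (test_name, statistic, p).

    Fisher's exact (two-sided) when any expected cell is below 5, otherwise
    Pearson chi-square with Yates continuity correction.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("table must be 2x2 non-negative integer counts")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("zero margin in 2x2 table: p set to 1")
        return "chi2", 0.0, 1.0
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected < 5).any():
        stat, p = sps.fisher_exact(t, alternative="two-sided")
        return "fisher", float(stat), float(p)
    chi2, p, _, _ = sps.chi2_contingency(t, correction=True)
    return "chi2", float(chi2), float(p)


def spearman_rho(x, y) -> Tuple[float, float]:
    """Spearman rank correlation (mid-ranks), two-sided t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("equal-length samples of size >= 3 required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman rho undefined")
        return float("nan"), float("nan")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci95: Tuple[float, float]
    youden_threshold: float
    youden_sens: float
    youden_spec: float

    @property
    def youden_j(self) -> float:
        return self.youden_sens + self.youden_spec - 1.0


def _delong_ci(scores, labels, auc, alpha=0.05):
    """DeLong variance of the empirical AUC and Wald CI (clipped to [0, 1])."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    # structural components via mid-rank comparison
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = sps.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return (float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1)))


def roc_analysis(scores, labels, positive_direction: str = "greater") -> RocResult:
    """Empirical ROC with AUC, DeLong CI and Youden-optimal cutoff.

    ``labels`` are binary (1 = positive class); ``positive_direction``
    "greater" means higher scores indicate the positive class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    if positive_direction not in ("greater", "less"):
        raise ValueError("positive_direction must be 'greater' or 'less'")
    s = scores if positive_direction == "greater" else -scores

    fpr, tpr, thr = _sk_roc_curve(labels, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))

    # Youden scan over midpoints between adjacent distinct scores
    u = np.unique(s)
    cand = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1] + 1.0]])
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    best = (-np.inf, -np.inf)  # (J, specificity) for tie-break
    best_c, best_sens, best_spec = cand[0], 0.0, 0.0
    for c in cand:
        pred = s > c
        sens = float(np.sum(pred & (labels == 1)) / n_pos)
        spec = float(np.sum(~pred & (labels == 0)) / n_neg)
        j = sens + spec - 1.0
        if (j, spec) > best:
            best = (j, spec)
            best_c, best_sens, best_spec = c, sens, spec
    thr_out = best_c if positive_direction == "greater" else -best_c
    return RocResult(
        thresholds=thr if positive_direction == "greater" else -thr,
        sensitivity=tpr, specificity=1.0 - fpr, auc=auc,
        auc_ci95=_delong_ci(s, labels, auc),
        youden_threshold=float(thr_out),
        youden_sens=best_sens, youden_spec=best_spec)


@dataclass
class LogisticFit:
    params: np.ndarray  # (intercept, slope)
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    llf: float
    llnull: float
    mcfadden_r2: float
    aic: float
    lrt_p: float
    converged: bool
    separation: bool

    def summary(self) -> str:
        rows = ["univariate logistic regression (IRLS)",
                f"{'':12s}{'coef':>10s}{'se':>10s}{'z':>8s}{'p':>9s}"]
        for name, b, s, z, p in zip(("intercept", "slope"), self.params,
                                    self.bse, self.zvalues, self.pvalues):
            rows.append(f"{name:12s}{b:10.3f}{s:10.3f}{z:8.2f}{p:9.4f}")
        rows.append(f"lnL {self.llf:.3f}  lnL0 {self.llnull:.3f}  "
                    f"McFadden R2 {self.mcfadden_r2:.3f}  AIC {self.aic:.2f}  "
                    f"LRT p {self.lrt_p:.4f}")
        if self.separation:
            rows.append("warning: (quasi-)separation, monotone likelihood")
        return "\n".join(rows)


def logistic_fit_univariate(x, y, max_iter: int = 100,
                            tol: float = 1e-8) -> LogisticFit:
    """Univariate binary logistic regression by IRLS.

    Standard errors come from the inverse observed information at the
    optimum; model fit is summarised by McFadden's R^2 (1 - lnL/lnL0), the
    AIC (4 - 2 lnL for the two-parameter model) and the likelihood-ratio
    test against the intercept-only model.  Perfect separation is detected
    (diverging |beta| / saturating linear predictor) and flagged rather than
    raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    n = y.size
    X = np.column_stack([np.ones(n), x])
    beta = np.zeros(2)
    converged = False
    separation = False
    for _ in range(max_iter):
        eta = X @ beta
        if np.max(np.abs(eta)) > 30.0:
            separation = True
            break
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        info = X.T @ (w[:, None] * X)
        try:
            beta = beta + np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            separation = True
            break

    eta = np.clip(X @ beta, -500, 500)
    p = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    llf = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    pbar = y.mean()
    llnull = float(n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar)))
    w = np.clip(p * (1.0 - p), eps, None)
    info = X.T @ (w[:, None] * X)
    try:
        cov = np.linalg.inv(info)
        bse = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        bse = np.full(2, np.inf)
    zvals = beta / bse
    pvals = 2.0 * sps.norm.sf(np.abs(zvals))
    mcf = 1.0 - llf / llnull if llnull != 0 else 0.0
    lrt = 2.0 * (llf - llnull)
    lrt_p = float(sps.chi2.sf(max(lrt, 0.0), df=1))
    if separation:
        warnings.warn("perfect or quasi separation: monotone likelihood, "
                      "coefficients diverge")
    return LogisticFit(params=beta, bse=bse, zvalues=zvals, pvalues=pvals,
                       llf=llf, llnull=llnull, mcfadden_r2=float(mcf),
                       aic=float(4.0 - 2.0 * llf), lrt_p=lrt_p,
                       converged=converged, separation=separation)


def percent_change(median_ref: float, median_test: float) -> float:
    """Relative change of a test median against a reference median, in
    percent, rounded to one decimal (reporting convention)."""
    if median_ref <= 0:
        raise ValueError("reference median must be positive")
    return round(100.0 * (median_test - median_ref) / median_ref, 1)


# ---------------------------------------------------------------------------
# full analysis battery
# ---------------------------------------------------------------------------

_FEATURES = ("volume", "t2", "pd")
_LEVEL_COLS = ("L5", "S1", "mean")


def _group_rows(df: pd.DataFrame, groups) -> pd.DataFrame:
    return df[df["group"].isin(groups)]


def _compare(df, col, groups_a, groups_b) -> Dict:
    a = _group_rows(df, groups_a)[col].to_numpy(dtype=float)
    b = _group_rows(df, groups_b)[col].to_numpy(dtype=float)
    u, p = mann_whitney_u(a, b)
    med_a, iqr_a = _median_iqr(a)
    med_b, iqr_b = _median_iqr(b)
    return {"median_a": med_a, "iqr_a": iqr_a, "median_b": med_b,
            "iqr_b": iqr_b, "U": u, "p": p,
            "percent_change": percent_change(med_a, med_b)}


def run_paper_analyses(cohort: pd.DataFrame,
                       long_table: Optional[pd.DataFrame] = None) -> Dict:
    """Run the full analysis battery on an aggregated cohort table.

    Expects one row per subject with columns ``group`` (HC/NF1n/NF1p),
    ``sex`` (F/M), ``age``, and ``{feature}_{L5,S1,mean}`` for volume/t2/pd
    (``height``/``weight``/``bmi`` are used when present).  Optionally a long
    per-DRG table (columns ``subject_id, level, side, rater_id, volume,
    t2_mean, pd``) enables the paired left-right contrasts.

    Returns a nested dict: demographics comparisons, HC vs NF1 and NF1n vs
    NF1p feature comparisons with medians/IQRs and percent changes, paired
    level and side contrasts, Spearman correlations, and — for the pain
    discrimination question — exactly one ROC analysis plus one univariate
    logistic fit per feature.  No multiplicity correction is applied.
    """
    required = ["group", "sex"] + [f"{f}_{lv}" for f in _FEATURES for lv in _LEVEL_COLS]
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    nf1 = ("NF1n", "NF1p")
    report: Dict = {"n": {g: int((cohort["group"] == g).sum())
                          for g in ("HC", "NF1n", "NF1p")}}

    # demographics: HC vs NF1 and NF1n vs NF1p
    demo: Dict = {}
    for name, ga, gb in (("HC_vs_NF1", ("HC",), nf1),
                         ("NF1n_vs_NF1p", ("NF1n",), ("NF1p",))):
        block: Dict = {}
        for col in ("age", "height", "weight", "bmi"):
            if col in cohort.columns:
                block[col] = _compare(cohort, col, ga, gb)
        a, b = _group_rows(cohort, ga), _group_rows(cohort, gb)
        tab = np.array([[int((a["sex"] == "F").sum()), int((a["sex"] == "M").sum())],
                        [int((b["sex"] == "F").sum()), int((b["sex"] == "M").sum())]])
        tname, stat, p = categorical_test(tab)
        block["sex"] = {"table": tab.tolist(), "test": tname,
                        "statistic": stat, "p": p}
        demo[name] = block
    report["demographics"] = demo

    # feature comparisons at each level
    comp: Dict = {}
    for name, ga, gb in (("HC_vs_NF1", ("HC",), nf1),
                         ("NF1n_vs_NF1p", ("NF1n",), ("NF1p",))):
        comp[name] = {f"{feat}_{lv}": _compare(cohort, f"{feat}_{lv}", ga, gb)
                      for feat in _FEATURES for lv in _LEVEL_COLS}
    report["features"] = comp

    # paired level contrast (S1 vs L5) within each diagnostic group
    paired: Dict = {}
    for gname, gsel in (("HC", ("HC",)), ("NF1", nf1)):
        sub = _group_rows(cohort, gsel)
        block = {}
        for feat in _FEATURES:
            w, p = wilcoxon_signed_rank(sub[f"{feat}_S1"], sub[f"{feat}_L5"])
            block[feat] = {"W": w, "p": p,
                           "median_S1": float(sub[f"{feat}_S1"].median()),
                           "median_L5": float(sub[f"{feat}_L5"].median())}
        paired[gname] = block
    report["level_contrast_S1_vs_L5"] = paired

    # paired side contrast (left vs right), needs the long table
    if long_table is not None:
        side: Dict = {}
        col_of = {"volume": "volume", "t2": "t2_mean", "pd": "pd"}
        merged = long_table.merge(
            cohort.reset_index()[["subject_id", "group"]], on="subject_id")
        for gname, gsel in (("HC", ("HC",)), ("NF1", nf1)):
            sub = merged[merged["group"].isin(gsel)]
            block = {}
            for feat in _FEATURES:
                piv = sub.pivot_table(values=col_of[feat], index="subject_id",
                                      columns="side", aggfunc="mean")
                w, p = wilcoxon_signed_rank(piv["L"], piv["R"])
                block[feat] = {"W": w, "p": p,
                               "median_L": float(piv["L"].median()),
                               "median_R": float(piv["R"].median()),
                               "mean_L": float(piv["L"].mean()),
                               "mean_R": float(piv["R"].mean())}
            side[gname] = block
        report["side_contrast_L_vs_R"] = side

    # Spearman correlations of demographics with features, per group
    corr: Dict = {}
    for gname, gsel in (("HC", ("HC",)), ("NF1", nf1)):
        sub = _group_rows(cohort, gsel)
        block = {}
        for dcol in ("age", "weight"):
            if dcol not in sub.columns:
                continue
            for feat in _FEATURES:
                if len(sub) < 3:
                    rho, p = float("nan"), float("nan")
                else:
                    rho, p = spearman_rho(sub[dcol], sub[f"{feat}_mean"])
                block[f"{dcol}_vs_{feat}"] = {"rho": rho, "p": p}
        corr[gname] = block
    report["correlations"] = corr

    # pain discrimination within NF1: ROC + logistic per feature
    nf1_df = _group_rows(cohort, nf1)
    y = (nf1_df["group"] == "NF1p").to_numpy(dtype=int)
    disc: Dict = {}
    for feat in _FEATURES:
        scores = nf1_df[f"{feat}_mean"].to_numpy(dtype=float)
        roc = roc_analysis(scores, y, positive_direction="greater")
        logit = logistic_fit_univariate(scores, y)
        disc[feat] = {
            "auc": roc.auc, "auc_ci95": list(roc.auc_ci95),
            "youden_threshold": roc.youden_threshold,
            "sensitivity": roc.youden_sens, "specificity": roc.youden_spec,
            "beta0": float(logit.params[0]), "beta1": float(logit.params[1]),
            "se0": float(logit.bse[0]), "se1": float(logit.bse[1]),
            "p_beta1": float(logit.pvalues[1]),
            "mcfadden_r2": logit.mcfadden_r2, "aic": logit.aic,
            "lrt_p": logit.lrt_p, "separation": logit.separation,
        }
    report["pain_discrimination"] = disc
    return report
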