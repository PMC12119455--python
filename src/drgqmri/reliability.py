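"""Inter-rater reliability via the two-way absolute-agreement ICC.

Each of ``n`` targets (individual DRGs) is measured by the same ``k`` raters,
a two-way layout with targets as random rows and raters as random columns.
The single-measure absolute-agreement coefficient ICC(A,1) is built from the
two-way ANOVA mean squares

    ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

which, unlike the consistency form, charges systematic rater offsets (the
column effect MS_C) against agreement.  The 95% confidence interval is the
exact F-based interval of McGraw & Wong; the average-measure coefficient
ICC(A,k) is also reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats as sps

__all__ = ["IccResult", "icc_agreement"]


@dataclass(frozen=True)
class IccResult:
    icc: float  # single-measure ICC(A,1)
    ci95: Tuple[float, float]
    icc_average: float  # ICC(A,k)
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int


def icc_agreement(ratings: np.ndarray, alpha: float = 0.05) -> IccResult:
    """ICC(A,1) with exact F-based CI from a complete n x k ratings matrix."""
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ratings must be a 2D n_targets x k_raters matrix")
    if x.shape[0] < 5:
        raise ValueError("at least 5 targets are required")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings matrix must be complete (no missing cells)")
    n, k = x.shape

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))

    if ss_total <= 1e-30:
        warnings.warn("zero total variance: ICC defined as 1 with degenerate CI")
        return IccResult(1.0, (1.0, 1.0), 1.0, ms_r, ms_c, ms_e, n, k)

    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    icc = (ms_r - ms_e) / denom
    denom_k = ms_r + (ms_c - ms_e) / n
    icc_k = (ms_r - ms_e) / denom_k if abs(denom_k) > 1e-30 else 1.0

    # McGraw & Wong exact interval for ICC(A,1)
    r = icc
    a = (k * r) / (n * (1.0 - r)) if r < 1 else np.inf
    b = 1.0 + (k * r * (n - 1)) / (n * (1.0 - r)) if r < 1 else np.inf
    if np.isfinite(a) and ms_e > 0:
        num_df = (a * ms_c + b * ms_e) ** 2
        den_df = ((a * ms_c) ** 2 / (k - 1)
                  + (b * ms_e) ** 2 / ((n - 1) * (k - 1)))
        v = num_df / den_df if den_df > 0 else 1.0
        f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        common = k * ms_c + (k * n - k - n) * ms_e
        lo = n * (ms_r - f_l * ms_e) / (f_l * common + n * ms_r)
        hi = n * (f_u * ms_r - ms_e) / (common + n * f_u * ms_r)
        lo, hi = float(min(lo, icc)), float(max(hi, icc))
    else:
        lo, hi = icc, icc
    return IccResult(float(icc), (lo, hi), float(icc_k),
                     float(ms_r), float(ms_c), float(ms_e), n, k)
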