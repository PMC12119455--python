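"""Statistical layer: enumeration/permutation oracles and invariants."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from drgqmri.stats import (categorical_test, logistic_fit_univariate,
                           mann_whitney_u, percent_change, roc_analysis,
                           run_paper_analyses, spearman_rho,
                           wilcoxon_signed_rank)


class TestMannWhitney:
    def test_fully_separated_small_samples_exact(self):
        """{1,2,3} vs {4,5,6}: U = 0, exact two-sided p = 2/20 = 0.1."""
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u in (0.0, 9.0)
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples(self):
        with pytest.warns(UserWarning):
            _, p = mann_whitney_u([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_matches_permutation_oracle(self):
        """20 vs 20 with ties: asymptotic p within Monte-Carlo error of a
        permutation distribution of the U statistic."""
        rng = np.random.default_rng(8)
        x = np.round(rng.normal(0, 1, 20), 1)
        y = np.round(rng.normal(0.6, 1, 20), 1)
        u_obs, p = mann_whitney_u(x, y)
        pooled = np.concatenate([x, y])
        n = len(x)
        mid = n * len(y) / 2.0
        count = 0
        n_perm = 100_000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            ranks = sps.rankdata(pooled)
            u_perm = ranks[:n].sum() - n * (n + 1) / 2.0
            if abs(u_perm - mid) >= abs(u_obs - mid) - 1e-9:
                count += 1
        p_perm = count / n_perm
        assert p == pytest.approx(p_perm, abs=4 * np.sqrt(p_perm / n_perm) + 5e-3)


class TestWilcoxon:
    def test_all_positive_differences_n5_exact(self):
        """n = 5, all differences one sign: exact two-sided p = 2/2^5."""
        x = np.array([5.0, 6.0, 7.0, 8.0, 9.0])
        y = x - np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        _, p = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(0.0625, abs=1e-12)

    def test_identical_pairs_warn(self):
        x = np.arange(5.0)
        with pytest.warns(UserWarning):
            _, p = wilcoxon_signed_rank(x, x)
        assert p == 1.0

    def test_signed_asymmetry_significant_despite_equal_medians(self):
        """Paired samples with identical medians can still differ: many small
        positive shifts against few large negative ones."""
        d = np.array([0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4,
                      1.5, 1.6, -0.1, -0.2, 0.4, 0.3, 1.7, 1.8, 1.9, 2.0])
        x = np.linspace(100, 120, 20)
        y = x - d
        assert np.median(d) > 0
        _, p = wilcoxon_signed_rank(x, y)
        assert p < 0.05


class TestCategorical:
    def test_balanced_sex_table_chi_square(self):
        """The 14/14 vs 9/11 sex split is nowhere near significant."""
        name, stat, p = categorical_test([[14, 14], [9, 11]])
        assert name == "chi2"
        assert p == pytest.approx(0.961, abs=5e-4)

    def test_fisher_on_sparse_diagonal_table(self):
        """[[5,0],[0,5]] by hypergeometric enumeration: p = 2/C(10,5)."""
        name, stat, p = categorical_test([[5, 0], [0, 5]])
        assert name == "fisher"
        assert p == pytest.approx(2.0 / 252.0, abs=1e-12)

    def test_symmetric_table_p_one(self):
        _, _, p = categorical_test([[7, 7], [3, 3]])
        assert p == pytest.approx(1.0)

    def test_zero_margin_warns(self):
        with pytest.warns(UserWarning):
            _, _, p = categorical_test([[0, 0], [3, 5]])
        assert p == 1.0


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0, 20.0])
        rho, _ = spearman_rho(x, np.exp(x / 10))
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_rho(x, -x ** 3)
        assert rho == pytest.approx(-1.0)

    def test_p_matches_exact_permutation_distribution(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        rho_obs, p = spearman_rho(x, y)
        rx = sps.rankdata(x)
        count, total = 0, 0
        for perm in itertools.permutations(sps.rankdata(y)):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= abs(rho_obs) - 1e-9
            total += 1
        p_exact = count / total
        assert p == pytest.approx(p_exact, abs=0.06)

    def test_constant_vector_warns(self):
        with pytest.warns(UserWarning):
            rho, p = spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho)


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(1.0)
        assert res.youden_j == pytest.approx(1.0)
        assert 3 < res.youden_threshold < 10

    def test_null_case_auc_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, 2000)
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_exhaustive_pair_counting(self):
        """8 vs 12 scores: AUC = (concordant + half ties) / (n1*n2)."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            pos = np.round(rng.normal(1, 1, 8), 1)
            neg = np.round(rng.normal(0, 1, 12), 1)
            scores = np.concatenate([neg, pos])
            labels = np.array([0] * 12 + [1] * 8)
            res = roc_analysis(scores, labels)
            pairs = sum(1.0 if p > q else 0.5 if p == q else 0.0
                        for p in pos for q in neg)
            assert res.auc == pytest.approx(pairs / (8 * 12), abs=1e-12)

    def test_auc_identity_with_u_statistic(self):
        """AUC == U/(n1 n2) to 1e-12, ties included (mid-rank convention)."""
        rng = np.random.default_rng(6)
        for _ in range(100):
            n1, n0 = rng.integers(5, 15), rng.integers(5, 15)
            scores = np.round(rng.normal(size=n1 + n0), 1)
            labels = np.array([1] * n1 + [0] * n0)
            res = roc_analysis(scores, labels)
            u = sps.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                                 alternative="two-sided").statistic
            assert res.auc == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_youden_matches_brute_force(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            scores = np.round(rng.normal(size=20), 1)
            labels = rng.integers(0, 2, 20)
            if labels.min() == labels.max():
                continue
            res = roc_analysis(scores, labels)
            best_j = max(
                (np.mean(scores[labels == 1] > c)
                 + np.mean(scores[labels == 0] <= c) - 1.0)
                for c in np.concatenate([scores - 1e-6, scores + 1e-6]))
            assert res.youden_j == pytest.approx(best_j, abs=1e-9)

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            roc_analysis([1.0, 2.0], [1, 1])


class TestLogistic:
    def test_separable_data_flagged(self):
        x = np.array([-3, -2, -1, 1, 2, 3], dtype=float)
        y = (x > 0).astype(int)
        with pytest.warns(UserWarning, match="separation"):
            fit = logistic_fit_univariate(x, y)
        assert fit.separation

    def test_null_case(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=200)
        y = rng.integers(0, 2, 200)
        fit = logistic_fit_univariate(x, y)
        assert abs(fit.params[1]) < 0.3
        assert fit.mcfadden_r2 < 0.02
        assert 0 <= fit.lrt_p <= 1

    def test_score_equations_satisfied(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=50)
        y = (rng.random(50) < 1 / (1 + np.exp(-(0.5 + 1.2 * x)))).astype(int)
        fit = logistic_fit_univariate(x, y)
        p = 1 / (1 + np.exp(-(fit.params[0] + fit.params[1] * x)))
        assert abs(np.sum(y - p)) < 1e-6
        assert abs(np.sum(x * (y - p))) < 1e-6

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(15)
        x = rng.normal(size=60)
        y = (rng.random(60) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(int)
        fit = logistic_fit_univariate(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.bse, ref.bse, atol=1e-5)
        assert fit.llf == pytest.approx(ref.llf, abs=1e-8)
        assert fit.aic == pytest.approx(ref.aic, abs=1e-6)
        assert fit.mcfadden_r2 == pytest.approx(ref.prsquared, abs=1e-8)

    def test_slope_recovery_at_study_scale(self):
        """n = 20 outcomes from the reported model (beta = (-19.73, 21.59))
        with predictors on the normalised-PD scale: the median slope estimate
        over replicates lands within 25% of truth."""
        rng = np.random.default_rng(16)
        slopes = []
        for _ in range(500):
            x = rng.uniform(0.82, 1.02, 20)
            p = 1 / (1 + np.exp(-(-19.73 + 21.59 * x)))
            y = (rng.random(20) < p).astype(int)
            if y.min() == y.max():
                continue
            fit = logistic_fit_univariate(x, y)
            if not fit.separation:
                slopes.append(fit.params[1])
        assert abs(np.median(slopes) / 21.59 - 1) < 0.25


class TestPercentChange:
    @pytest.mark.parametrize("ref,test,expected", [
        (628.4, 1736.5, 176.3),
        (96.2, 118.2, 22.9),
        (0.833, 0.903, 8.4),
        (5.0, 5.0, 0.0),
    ])
    def test_reference_values(self, ref, test, expected):
        assert percent_change(ref, test) == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)


class TestAnalysisBattery:
    @staticmethod
    def _synthetic_cohort(seed=0):
        """Feature-level cohort drawn directly at the published group
        distributions (no imaging), for exercising the report structure."""
        import pandas as pd
        from drgqmri.phantom import default_cohort_config, sample_cohort
        from drgqmri.features import LEVELS, SIDES
        specs = sample_cohort(default_cohort_config(seed=seed))
        rows = []
        for s in specs:
            row = {"subject_id": s.subject_id, "group": s.group, "sex": s.sex,
                   "age": s.age, "height": s.height, "weight": s.weight,
                   "bmi": s.weight / (s.height / 100) ** 2}
            for feat, d in (("volume", s.drg_volume), ("t2", s.drg_t2),
                            ("pd", s.drg_pd)):
                lv_means = {lv: np.mean([d[(lv, sd)] for sd in SIDES])
                            for lv in LEVELS}
                for lv in LEVELS:
                    row[f"{feat}_{lv}"] = lv_means[lv]
                row[f"{feat}_mean"] = np.mean(list(lv_means.values()))
            rows.append(row)
        return pd.DataFrame(rows)

    def test_report_structure_and_roc_count(self):
        report = run_paper_analyses(self._synthetic_cohort())
        assert set(report["pain_discrimination"]) == {"volume", "t2", "pd"}
        assert len(report["pain_discrimination"]) == 3
        assert report["n"] == {"HC": 28, "NF1n": 12, "NF1p": 8}
        for d in report["pain_discrimination"].values():
            assert 0.0 <= d["auc"] <= 1.0

    def test_volume_contrast_detected_under_published_effect(self):
        """HC vs NF1 volume (628 vs ~1700 mm^3) is significant in nearly all
        replicate cohorts."""
        hits = 0
        for seed in range(20):
            rep = run_paper_analyses(self._synthetic_cohort(seed))
            hits += rep["features"]["HC_vs_NF1"]["volume_mean"]["p"] <= 0.05
        assert hits >= 19

    def test_degenerate_cohort_percent_change_exact(self):
        import pandas as pd
        from drgqmri.phantom import default_cohort_config, sample_cohort
        cfg = default_cohort_config(seed=5).scaled(0.0)
        df = self._synthetic_cohort()  # structure only; rebuild degenerate
        from drgqmri.features import LEVELS, SIDES
        specs = sample_cohort(cfg)
        rows = []
        for s in specs:
            row = {"subject_id": s.subject_id, "group": s.group, "sex": s.sex,
                   "age": s.age, "height": s.height, "weight": s.weight}
            for feat, d in (("volume", s.drg_volume), ("t2", s.drg_t2),
                            ("pd", s.drg_pd)):
                lv_means = {lv: np.mean([d[(lv, sd)] for sd in SIDES])
                            for lv in LEVELS}
                for lv in LEVELS:
                    row[f"{feat}_{lv}"] = lv_means[lv]
                row[f"{feat}_mean"] = np.mean(list(lv_means.values()))
            rows.append(row)
        rep = run_paper_analyses(pd.DataFrame(rows))
        blk = rep["features"]["HC_vs_NF1"]
        # degenerate NF1 median is the case-weighted group median of the
        # configured NF1n/NF1p medians: here the 12 NF1n dominate
        assert blk["volume_mean"]["median_a"] == pytest.approx(628.4)
        assert blk["t2_mean"]["percent_change"] == pytest.approx(
            round(100 * (np.median([110.3] * 12 + [125.7] * 8) / 96.2 - 1), 1),
            abs=0.05)

    def test_missing_columns_schema_error(self):
        import pandas as pd
        with pytest.raises(ValueError, match="missing columns"):
            run_paper_analyses(pd.DataFrame({"group": ["HC"], "sex": ["F"]}))
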