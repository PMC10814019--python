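import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from choromvq.stats import (
    auc_ci_bootstrap,
    auc_mw,
    firth_logistic,
    missingness_lrt,
    pearson_pairwise,
    run_group_analysis,
    wilcoxon_rank_sum,
)
from choromvq.synth.cohort import generate_cohort, study_cohort_spec
from conftest import exact_ranksum_p


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0
        assert wilcoxon_rank_sum([5.0] * 4, [5.0] * 3) == 1.0

    def test_small_sample_example(self):
        assert wilcoxon_rank_sum([1, 2], [3, 4]) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        x = rng.normal(size=nx)
        y = rng.normal(size=ny)
        assert wilcoxon_rank_sum(x, y, mode="exact") == pytest.approx(
            exact_ranksum_p(x, y), rel=1e-9
        )

    def test_type_one_error_asymptotic(self):
        """Gaussian null at n=21/15: rejection rate ~ alpha = 0.05."""
        rng = np.random.default_rng(42)
        rej = 0
        N = 10_000
        for _ in range(N):
            x = rng.standard_normal(21)
            y = rng.standard_normal(15)
            rej += wilcoxon_rank_sum(x, y, mode="asymptotic") < 0.05
        assert 0.04 <= rej / N <= 0.06

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestAUC:
    def test_trivial_cases(self):
        assert auc_mw([10, 11], [1, 2]) == 1.0
        assert auc_mw([3.0] * 5, [3.0] * 4) == 0.5

    def test_brute_force_example(self):
        assert auc_mw([3, 1], [2, 0]) == pytest.approx(0.75)

    def test_matches_pair_counting(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(1, 1, 20), rng.normal(0, 1, 15)
        brute = np.mean([(xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y])
        assert auc_mw(x, y) == pytest.approx(brute, rel=1e-12)


class TestBootstrapCI:
    def test_perfect_separation_degenerate_interval(self):
        x = np.arange(100, 130, dtype=float)
        y = np.arange(0, 30, dtype=float)
        lo, hi = auc_ci_bootstrap(x, y, B=300, seed=1)
        assert lo == 1.0 and hi == 1.0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(1, 1, 21), rng.normal(0, 1, 15)
        assert auc_ci_bootstrap(x, y, B=400, seed=9) == auc_ci_bootstrap(x, y, B=400, seed=9)
        assert auc_ci_bootstrap(x, y, B=400, seed=9) != auc_ci_bootstrap(x, y, B=400, seed=10)

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0.8, 1, 21), rng.normal(0, 1, 15)
        a = auc_mw(x, y)
        lo, hi = auc_ci_bootstrap(x, y, B=500, seed=2)
        assert lo <= a <= hi

    def test_small_B_rejected(self):
        with pytest.raises(ValueError):
            auc_ci_bootstrap([1, 2], [0, 1], B=50)


class TestFirth:
    @pytest.mark.parametrize("n,k", [(10, 3), (36, 21), (8, 0), (8, 8)])
    def test_intercept_only_closed_form(self, n, k):
        """Jeffreys-penalized binomial: p-hat = (k + 1/2) / (n + 1)."""
        y = np.r_[np.ones(k), np.zeros(n - k)]
        fit = firth_logistic(y, np.ones((n, 1)), tol=1e-10)
        assert expit(fit.coef[0]) == pytest.approx((k + 0.5) / (n + 1), abs=1e-8)

    def test_finite_under_complete_separation(self):
        y = np.r_[np.ones(6), np.zeros(6)]
        x = np.r_[np.ones(6), -np.ones(6)]
        fit = firth_logistic(y, np.c_[np.ones(12), x])
        assert np.isfinite(fit.coef).all()
        assert fit.converged

    def test_optimum_matches_grid_search(self):
        """Dense grid over (b0, b1) on a small problem: penalized likelihood
        at the Newton optimum is within 1e-4 of the grid maximum."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=15)
        y = (rng.random(15) < expit(0.5 + 0.8 * x)).astype(float)
        X = np.c_[np.ones(15), x]
        fit = firth_logistic(y, X, tol=1e-10)

        from choromvq.stats import _penalized_loglik

        b0s = np.linspace(fit.coef[0] - 1.5, fit.coef[0] + 1.5, 121)
        b1s = np.linspace(fit.coef[1] - 1.5, fit.coef[1] + 1.5, 121)
        grid_best = max(
            _penalized_loglik(y, X, np.array([b0, b1])) for b0 in b0s for b1 in b1s
        )
        assert fit.penalized_loglik >= grid_best - 1e-4

    def test_rank_deficient_design_rejected(self):
        y = np.r_[np.ones(4), np.zeros(4)]
        X = np.c_[np.ones(8), np.ones(8)]
        with pytest.raises(ValueError):
            firth_logistic(y, X)


class TestMissingnessLRT:
    def test_fill_value_irrelevant(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 36).astype(float)
        obs = np.r_[np.ones(21), (rng.random(15) < 0.5)].astype(float)
        val = rng.normal(size=36)
        ps = []
        for fill in (0.0, 99.0, -7.0, np.nan):
            v = val.copy()
            v[obs == 0] = fill
            ps.append(missingness_lrt(y, v, obs).lrt_p)
        assert len({round(p, 14) for p in ps}) == 1

    def test_all_observed_reduces_to_value_only_model(self):
        """X1 = 1 everywhere: the X1 column duplicates the intercept and is
        dropped, leaving a 1-df test on the value."""
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 30).astype(float)
        v = rng.normal(size=30)
        with pytest.warns(UserWarning, match="redundant"):
            fit = missingness_lrt(y, v, np.ones(30))
        assert fit.lrt_df == 1
        assert fit.columns == ["intercept", "X1*X2"]

    def test_power_under_benign_missingness(self):
        """Strong value effect + benign-only missingness (21/21 vs 8/15
        observed): LRT rejects in >= 80% of simulations."""
        rej = 0
        N = 100
        for s in range(N):
            r = np.random.default_rng(s)
            y = np.r_[np.ones(21), np.zeros(15)]
            obs = np.r_[np.ones(21), (r.random(15) < 8 / 15)].astype(float)
            v = np.where(y == 1, r.normal(1.5, 1, 36), r.normal(0.0, 1, 36))
            v[obs == 0] = np.nan
            rej += missingness_lrt(y, v, obs).lrt_p < 0.05
        assert rej / N >= 0.8

    def test_missing_value_where_observed_rejected(self):
        y = np.r_[np.ones(3), np.zeros(3)]
        v = np.array([1.0, np.nan, 2.0, 0.5, 0.1, 0.2])
        obs = np.ones(6)
        with pytest.raises(ValueError):
            missingness_lrt(y, v, obs)


class TestPearson:
    def test_exact_linear(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 4, 6]})
        corr = pearson_pairwise(df)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "a"] == 1.0

    def test_hand_computed_four_points(self):
        x = np.array([1.0, 2.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 6.0])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        corr = pearson_pairwise(pd.DataFrame({"x": x, "y": y}))
        assert corr.loc["x", "y"] == pytest.approx(num / den, abs=1e-12)

    def test_pairwise_complete_and_flags(self):
        df = pd.DataFrame(
            {
                "a": [1.0, 2, 3, 4, np.nan],
                "b": [2.0, 4, 6, np.nan, 10],
                "c": [5.0, 5, 5, 5, 5],          # constant
                "d": [1.0, np.nan, np.nan, np.nan, 2.0],  # only 2 pairs
            }
        )
        corr = pearson_pairwise(df)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert np.isnan(corr.loc["a", "c"])
        assert np.isnan(corr.loc["a", "d"])


class TestRunGroupAnalysis:
    @pytest.fixture(scope="class")
    def cohort(self):
        return generate_cohort(study_cohort_spec(seed=21))

    def test_table_layouts(self, cohort):
        ga = run_group_analysis(cohort, seed=0, bootstrap_B=300)
        assert len(ga.comparison) == 8
        assert len(ga.branching) == 4
        assert set(ga.comparison.columns) >= {"biomarker", "p_value", "auc", "auc_ci_low"}
        assert ((ga.comparison["auc_ci_low"] <= ga.comparison["auc"])
                & (ga.comparison["auc"] <= ga.comparison["auc_ci_high"])).all()
        assert ga.correlations.shape == (12, 12)

    def test_cutoff_larger_than_all_thicknesses(self, cohort):
        ga = run_group_analysis(cohort, thickness_cutoff_mm=1e9, seed=0, bootstrap_B=300)
        full = run_group_analysis(cohort, thickness_cutoff_mm=2.5, seed=0, bootstrap_B=300)
        pd.testing.assert_frame_equal(
            ga.subset_comparison,
            full.comparison.drop(columns=["auc", "auc_ci_low", "auc_ci_high"]),
        )

    def test_power_ordering_matches_observed_significance_split(self):
        """Across simulated cohorts at the study moments, the six biomarkers
        reported significant have smaller median Wilcoxon p than Dmean and
        tau_mean."""
        sig = ["NV", "NB", "tau_max", "Dmax", "VD", "mvFD"]
        nonsig = ["Dmean", "tau_mean"]
        ps = {b: [] for b in sig + nonsig}
        for s in range(200):
            df = generate_cohort(study_cohort_spec(seed=3000 + s))
            mal = df[df["label"] == "malignant"]
            ben = df[df["label"] == "benign"]
            for b in ps:
                ps[b].append(wilcoxon_rank_sum(mal[b], ben[b]))
        med = {b: np.median(v) for b, v in ps.items()}
        assert max(med[b] for b in sig) < min(med[b] for b in nonsig)

    def test_permuted_labels_calibrated(self):
        """Label permutation: rejection rate across biomarkers ~ alpha."""
        rej = tot = 0
        for s in range(40):
            rng = np.random.default_rng(777 + s)
            df = generate_cohort(study_cohort_spec(seed=888 + s))
            df = df.assign(label=rng.permutation(df["label"].to_numpy()))
            mal = df[df["label"] == "malignant"]
            ben = df[df["label"] == "benign"]
            for b in ("VD", "NV", "NB", "Dmax", "tau_max", "mvFD", "Dmean", "tau_mean"):
                rej += wilcoxon_rank_sum(mal[b], ben[b]) < 0.05
                tot += 1
        assert rej / tot <= 0.12

    def test_missing_group_rejected(self, cohort):
        with pytest.raises(ValueError):
            run_group_analysis(cohort[cohort["label"] == "benign"])
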