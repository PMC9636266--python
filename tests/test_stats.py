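"""Statistics layer vs closed-form / enumeration / midrank oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from fcsweep import (
    compare_omst_vs_matched,
    connectivity_descriptives,
    cross_threshold_correlations,
    fit_density_regression,
    group_effect_profile,
    permutation_ttest,
    significant_intervals,
)
from fcsweep.stats import cohens_d
from tests.conftest import make_matrix


class TestDescriptives:
    def test_constant_matrix(self):
        w = np.full((5, 5), 0.3)
        np.fill_diagonal(w, 0)
        row = connectivity_descriptives(make_matrix(w))
        assert row.median == 0.3
        assert row.mean == pytest.approx(0.3, abs=1e-12)
        assert row.mad == 0.0 and row.sd == pytest.approx(0.0, abs=1e-12)

    def test_one_to_six_hand_computation(self):
        w = np.zeros((4, 4))
        w[np.triu_indices(4, 1)] = [1, 2, 3, 4, 5, 6]
        row = connectivity_descriptives(make_matrix(w + w.T))
        assert row.median == 3.5 and row.mean == 3.5
        assert row.mad == 1.5  # median{2.5,1.5,0.5,0.5,1.5,2.5}

    def test_invariant_to_node_relabelling(self):
        rng = np.random.default_rng(0)
        a = rng.random((6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        perm = rng.permutation(6)
        r1 = connectivity_descriptives(make_matrix(a))
        r2 = connectivity_descriptives(make_matrix(a[np.ix_(perm, perm)]))
        for f in ("median", "mean", "mad", "sd"):
            assert getattr(r1, f) == pytest.approx(getattr(r2, f))


class TestRegression:
    def test_exact_line(self):
        df = pd.DataFrame({"q": np.linspace(0, 1, 50)})
        df["cpl"] = 2.0 - df["q"]
        fit = fit_density_regression(df, "cpl")
        assert fit.intercept == pytest.approx(2.0)
        assert fit.slope == pytest.approx(-1.0)
        assert fit.adj_r_squared == pytest.approx(1.0)

    def test_null_relationship_adj_r2_near_zero(self):
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(100):
            df = pd.DataFrame({"q": rng.random(500), "m": rng.normal(size=500)})
            vals.append(fit_density_regression(df, "m").adj_r_squared)
        assert abs(np.mean(vals)) < 0.02

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.random(80)
        y = 1.3 + 0.7 * x + rng.normal(0, 0.2, 80)
        df = pd.DataFrame({"q": x, "m": y})
        fit = fit_density_regression(df, "m")
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_zero_variance_regressor_rejected(self):
        df = pd.DataFrame({"q": [0.5] * 10, "m": np.arange(10.0)})
        with pytest.raises(ValueError, match="zero variance"):
            fit_density_regression(df, "m")


def metric_records(values_by_q, subjects=None):
    rows = []
    for q, vals in values_by_q.items():
        for s, v in enumerate(vals):
            rows.append({"subject": f"s{s}", "measure": "wpli", "q": q,
                         "metric": v})
    return pd.DataFrame(rows)


class TestCrossThresholdCorrelations:
    def test_identical_and_reversed_vectors(self):
        base = [1.0, 2.0, 3.0, 4.0, 5.0]
        df = metric_records({0.1: base, 0.2: base, 0.3: base[::-1]})
        rho, p = cross_threshold_correlations(df, "metric")
        assert rho.loc[0.1, 0.2] == pytest.approx(1.0)
        assert rho.loc[0.1, 0.3] == pytest.approx(-1.0)
        assert (np.diag(rho) == 1.0).all()

    def test_ties_match_midrank_pearson_oracle(self):
        a = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0]
        b = [3.0, 1.0, 4.0, 4.0, 2.0, 5.0]
        df = metric_records({0.1: a, 0.2: b})
        rho, _ = cross_threshold_correlations(df, "metric")
        ra = scipy.stats.rankdata(a)  # midranks
        rb = scipy.stats.rankdata(b)
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert rho.loc[0.1, 0.2] == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_recorded_missing(self):
        df = metric_records({0.1: [1, 2, 3, 4], 0.2: [2.0] * 4})
        rho, p = cross_threshold_correlations(df, "metric")
        assert np.isnan(rho.loc[0.1, 0.2])


class TestPermutationTTest:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        res = permutation_ttest(a, a.copy(), seed=0)
        assert res.cohens_d == 0.0 and res.p_value == 1.0

    def test_exact_enumeration_at_4v4(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 4), rng.normal(1.5, 1, 4)
        exact = permutation_ttest(a, b)
        assert exact.exact and exact.n_permutations == 70
        # Monte-Carlo agrees with full enumeration within 0.02
        mc = permutation_ttest(a, b, n_permutations=20_000, seed=1,
                               force_monte_carlo=True)
        assert abs(mc.p_value - exact.p_value) < 0.02

    def test_exact_p_matches_manual_enumeration(self):
        a = np.array([0.1, 0.9, 0.4, 0.6])
        b = np.array([1.2, 1.8, 1.1, 2.0])
        res = permutation_ttest(a, b)
        pooled = np.concatenate([a, b])
        t_obs = scipy.stats.ttest_ind(a, b, equal_var=False).statistic
        hits = 0
        for idx in combinations(range(8), 4):
            mask = np.zeros(8, bool)
            mask[list(idx)] = True
            t = scipy.stats.ttest_ind(pooled[mask], pooled[~mask],
                                      equal_var=False).statistic
            hits += abs(t) >= abs(t_obs) - 1e-12
        assert res.p_value == pytest.approx(hits / 70)
        assert res.t_stat == pytest.approx(t_obs)

    def test_cohens_d_closed_form(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 200)
        b = a + 1.0  # pooled SD equals SD(a), d = 1/SD(a)
        assert cohens_d(b, a) == pytest.approx(1.0 / a.std(ddof=1), rel=1e-12)

    def test_antisymmetry_under_label_swap(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        r1 = permutation_ttest(a, b, seed=0)
        r2 = permutation_ttest(b, a, seed=0)
        assert r1.cohens_d == pytest.approx(-r2.cohens_d)

    def test_power_at_large_effect(self):
        # d = 1.2 at n = 30/group: rejection rate must exceed 0.9
        rng = np.random.default_rng(6)
        rejections = 0
        reps = 100
        for k in range(reps):
            a = rng.normal(0, 1, 30)
            b = rng.normal(1.2, 1, 30)
            res = permutation_ttest(a, b, n_permutations=500, seed=k)
            rejections += res.p_value < 0.05
        assert rejections / reps > 0.9


class TestGroupProfile:
    def fabricated_sweep(self, effect_qs, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for q in np.round(np.arange(0.05, 1.0, 0.05), 2):
            for g, shift in (("A", 0.0), ("B", 2.0 if q in effect_qs else 0.0)):
                for s in range(12):
                    rows.append({"subject": f"{g}{s}", "group": g,
                                 "measure": "wpli", "q": q,
                                 "clustering": rng.normal(shift, 1)})
        return pd.DataFrame(rows)

    def test_planted_block_detected_and_null_flat(self):
        effect = {0.4, 0.45, 0.5, 0.55, 0.6}
        df = self.fabricated_sweep(effect, seed=1)
        prof = group_effect_profile(df, "clustering", n_permutations=999, seed=2)
        sig_qs = set(prof.loc[prof.significant, "q"].round(2))
        assert {0.45, 0.5, 0.55} <= sig_qs or len(sig_qs & effect) >= 3

    def test_interval_splitting_on_sign_change(self):
        prof = pd.DataFrame({
            "q": [0.1, 0.2, 0.3, 0.4, 0.5],
            "significant": [True, True, False, True, True],
            "d_sign": [1.0, 1.0, 1.0, -1.0, -1.0],
        })
        runs = significant_intervals(prof)
        assert len(runs) == 2
        assert runs[0]["d_sign"] == 1.0 and runs[1]["d_sign"] == -1.0
        assert runs[1]["q_start"] == 0.4 and runs[1]["n_levels"] == 2

    def test_requires_two_groups(self):
        df = self.fabricated_sweep(set())
        df["group"] = "A"
        with pytest.raises(ValueError, match="2 groups"):
            group_effect_profile(df, "clustering")


class TestOMSTComparison:
    def frame(self, values, measures=("wpli",)):
        rows = []
        for meas in measures:
            for s, v in enumerate(values):
                rows.append({"subject": f"s{s}", "measure": meas, "cpl": v,
                             "clustering": v, "participation": v, "swi": v})
        return pd.DataFrame(rows)

    def test_identical_sets_give_zero_d(self):
        a = self.frame([1.0, 2.0, 3.0, 4.0])
        out = compare_omst_vs_matched(a, a.copy(), seed=0)
        assert (out["Cohen's d"] == 0.0).all()
        assert (out["p-value"] == 1.0).all()

    def test_shifted_copy_d_near_one(self):
        rng = np.random.default_rng(7)
        base = rng.normal(0, 1, 60)
        a = self.frame(base + 1.0)
        b = self.frame(base)
        out = compare_omst_vs_matched(a, b, metrics=("cpl",), seed=0)
        assert out["Cohen's d"].iloc[0] == pytest.approx(
            1.0 / base.std(ddof=1), rel=1e-9
        )

    def test_row_count_is_measures_times_metrics(self):
        a = self.frame([1, 2, 3, 4.0], measures=("wpli", "imcoh"))
        out = compare_omst_vs_matched(a, a.copy(), seed=0)
        assert len(out) == 2 * 4

    def test_unmatched_subjects_listed(self):
        a = self.frame([1, 2, 3, 4.0])
        b = self.frame([1, 2, 3.0])
        with pytest.raises(ValueError, match="unmatched subjects.*s3"):
            compare_omst_vs_matched(a, b)
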