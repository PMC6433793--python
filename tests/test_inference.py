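"""Residualization, permutation tests, BH-FDR, partial correlation,
demographics — each checked against an independent oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fcnet.inference import (
    compare_groups,
    correlate_clinical,
    demographics_compare,
    fdr_bh,
    partial_correlation,
    permutation_test,
    permutation_test_many,
    residualize,
)

from .oracles import bh_reject_bruteforce, exhaustive_permutation_p


class TestResidualize:
    def test_orthogonal_covariate_just_demeans(self, rng):
        n = 128
        t = np.arange(n)
        values = np.sin(2 * np.pi * t / 16) + 5.0
        cov = np.cos(2 * np.pi * t / 16)  # orthogonal over full periods
        out = residualize(values, cov)
        assert np.allclose(out, values - values.mean(), atol=1e-10)

    def test_linear_in_covariate_vanishes(self, rng):
        cov = rng.normal(size=60)
        values = 3.0 * cov + 2.0
        out = residualize(values, cov)
        assert np.linalg.norm(out) < 1e-8 * np.linalg.norm(values)

    def test_recovery_identity(self, rng):
        age = rng.uniform(40, 75, size=80)
        signal = rng.normal(size=80)
        contaminated = signal + 0.5 * age
        r1 = residualize(contaminated, age)
        r2 = residualize(signal, age)
        assert np.allclose(r1, r2, atol=1e-8)

    def test_matrix_valued_outcomes(self, rng):
        cov = rng.normal(size=(50, 2))
        values = rng.normal(size=(50, 7))
        out = residualize(values, cov)
        assert np.all(np.abs(cov.T @ out) < 1e-8)

    def test_collinear_warns(self, rng):
        base = rng.normal(size=40)
        cov = np.column_stack([base, base * 2])
        with pytest.warns(UserWarning, match="collinear"):
            residualize(rng.normal(size=40), cov)


class TestPermutationTest:
    def test_exhaustive_three_vs_three(self):
        values = np.array([10.0, 10.0, 10.0, 0.0, 0.0, 0.0])
        groups = ["a"] * 3 + ["b"] * 3
        res = permutation_test(values, groups, exhaustive=True)
        assert res.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 splits

    def test_constant_values_give_p_one(self):
        values = np.ones(10)
        groups = ["a"] * 5 + ["b"] * 5
        res = permutation_test(values, groups, n_perm=199, seed=1)
        assert res.p_value == 1.0

    def test_monte_carlo_matches_exhaustive_small_cohorts(self, rng):
        """Exact equality of the rejection region for <= 10 subjects."""
        for trial in range(10):
            local = np.random.default_rng(200 + trial)
            n_a = int(local.integers(2, 5))
            n_b = int(local.integers(2, 6))
            values = local.normal(size=n_a + n_b)
            groups = ["a"] * n_a + ["b"] * n_b
            res = permutation_test(values, groups, exhaustive=True)
            oracle = exhaustive_permutation_p(
                values, np.array([g == "a" for g in groups])
            )
            assert res.p_value == pytest.approx(oracle)

    def test_deterministic_given_seed(self, rng):
        values = rng.normal(size=20)
        groups = ["a"] * 10 + ["b"] * 10
        r1 = permutation_test(values, groups, n_perm=500, seed=7)
        r2 = permutation_test(values, groups, n_perm=500, seed=7)
        assert r1.p_value == r2.p_value

    def test_low_n_perm_warns(self, rng):
        values = rng.normal(size=10)
        with pytest.warns(UserWarning, match="very low"):
            permutation_test(values, ["a"] * 5 + ["b"] * 5, n_perm=50, seed=0)

    def test_strong_effect_detected(self, rng):
        values = np.concatenate([rng.normal(5, 1, 20), rng.normal(0, 1, 20)])
        groups = ["a"] * 20 + ["b"] * 20
        res = permutation_test(values, groups, n_perm=999, seed=3)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_vectorized_matches_scalar(self, rng):
        values = rng.normal(size=(24, 5))
        groups = np.array(["a"] * 12 + ["b"] * 12)
        obs, p = permutation_test_many(values, groups, n_perm=2000, seed=9)
        for j in range(5):
            res = permutation_test(values[:, j], groups, n_perm=2000, seed=11)
            assert obs[j] == pytest.approx(res.observed_diff)
            # same null law, different draws: p-values agree statistically
            assert abs(p[j] - res.p_value) < 0.08


class TestFdrBH:
    def test_all_four_rejected(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        adj, reject = fdr_bh(p, q=0.05)
        assert reject.all()
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        adj, reject = fdr_bh(np.ones(6), q=0.05)
        assert not reject.any()
        assert np.all(adj == 1.0)

    def test_single_p_unchanged(self):
        adj, _ = fdr_bh(np.array([0.012]), q=0.05)
        assert adj[0] == pytest.approx(0.012)

    def test_adjusted_monotone_in_rank(self, rng):
        p = rng.uniform(size=30)
        adj, _ = fdr_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_matches_bruteforce_oracle_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            q = float(rng.uniform(0.01, 0.2))
            _, reject = fdr_bh(p, q)
            assert np.array_equal(reject, bh_reject_bruteforce(p, q))


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        from scipy import stats

        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        r, p = partial_correlation(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert r == pytest.approx(r_ref)
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_identical_vectors_give_one(self, rng):
        x = rng.normal(size=30)
        cov = rng.normal(size=(30, 2))
        r, p = partial_correlation(x, x.copy(), cov)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_three_variable_closed_form(self, rng):
        """r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))."""
        n = 500
        z = rng.normal(size=n)
        x = 0.6 * z + rng.normal(size=n)
        y = -0.4 * z + rng.normal(size=n)
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        expected = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        r, _ = partial_correlation(x, y, z)
        assert r == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_residual_raises(self, rng):
        z = rng.normal(size=30)
        with pytest.raises(ValueError, match="zero-variance"):
            partial_correlation(2.0 * z, rng.normal(size=30), z)


class TestDemographics:
    @staticmethod
    def _cohort_from_counts(male_a, female_a, male_b, female_b):
        sex = [1] * male_a + [0] * female_a + [1] * male_b + [0] * female_b
        group = ["patient"] * (male_a + female_a) + ["control"] * (male_b + female_b)
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(len(sex))],
                "group": group,
                "sex": sex,
                "age": rng.uniform(40, 75, len(sex)),
            }
        )

    def test_gender_exact_test_on_printed_counts(self):
        cohort = self._cohort_from_counts(35, 20, 21, 26)
        table = demographics_compare(cohort)
        p = table.loc[table["variable"] == "sex", "p_value"].item()
        assert p == pytest.approx(0.073, abs=0.005)

    def test_balanced_table_gives_p_one(self):
        cohort = self._cohort_from_counts(5, 5, 5, 5)
        table = demographics_compare(cohort)
        assert table.loc[table["variable"] == "sex", "p_value"].item() == 1.0

    def test_identical_continuous_values_give_p_one(self):
        cohort = self._cohort_from_counts(3, 3, 3, 3)
        cohort["age"] = 50.0
        table = demographics_compare(cohort)
        assert table.loc[table["variable"] == "age", "p_value"].item() == 1.0

    def test_continuous_matches_scipy_ttest(self, rng):
        from scipy import stats

        cohort = self._cohort_from_counts(10, 10, 8, 8)
        table = demographics_compare(cohort)
        a = cohort.loc[cohort["group"] == "patient", "age"]
        b = cohort.loc[cohort["group"] == "control", "age"]
        _, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert table.loc[table["variable"] == "age", "p_value"].item() == pytest.approx(
            p_ref
        )


class TestTableLevelWrappers:
    @staticmethod
    def _tables(rng, n_a=12, n_b=10, n_nodes=4, shift=0.0):
        n = n_a + n_b
        cohort = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "group": ["patient"] * n_a + ["control"] * n_b,
                "age": rng.uniform(40, 75, n),
                "sex": rng.integers(0, 2, n),
                "bmi": rng.normal(25, 3, n),
            }
        )
        rows = []
        for i in range(n):
            for j in range(n_nodes):
                val = rng.normal() + (shift if (i < n_a and j == 0) else 0.0)
                rows.append((f"s{i}", "efficiency", f"node{j}", val))
            rows.append((f"s{i}", "cp", "", rng.normal()))
        auc = pd.DataFrame(rows, columns=["subject_id", "metric", "node", "auc"])
        return auc, cohort

    def test_compare_groups_output_shape(self, rng):
        auc, cohort = self._tables(rng)
        out = compare_groups(auc, cohort, n_perm=199, seed=1)
        assert set(out["metric"]) == {"efficiency", "cp"}
        assert len(out) == 5  # 4 nodes + 1 global
        assert (out["p_fdr"] >= out["p_value"] - 1e-12).all()

    def test_compare_groups_finds_large_shift(self, rng):
        auc, cohort = self._tables(rng, shift=5.0)
        out = compare_groups(auc, cohort, n_perm=999, seed=1)
        hit = out[(out["metric"] == "efficiency") & (out["node"] == "node0")]
        assert hit["significant"].item()

    def test_correlate_clinical_columns(self, rng):
        auc, cohort = self._tables(rng)
        out = correlate_clinical(auc, cohort, ["bmi"], group="patient")
        assert {"metric", "node", "clinical_var", "r", "p_value"} <= set(out.columns)
        assert (out["clinical_var"] == "bmi").all()
        assert out["r"].between(-1, 1).all()


def test_permutation_type_one_error_calibrated():
    """Null rejection rate at alpha = 0.05 stays in [0.035, 0.065]."""
    rng = np.random.default_rng(2024)
    n_sims, n_perm = 1000, 999
    n_a, n_b = 20, 20
    groups = np.array(["a"] * n_a + ["b"] * n_b)
    rejections = 0
    for sim in range(n_sims):
        values = rng.normal(size=(n_a + n_b, 1))
        _, p = permutation_test_many(
            values, groups, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        rejections += p[0] <= 0.05
    assert 0.035 <= rejections / n_sims <= 0.065


def test_partial_correlation_recovery_from_cohort():
    """Target clinical association r = 0.31 at n = 102: the age/sex-adjusted
    partial correlation against the injected coupling lands in [0.1, 0.5]."""
    from fcnet.synthetic import make_cohort, make_small_world_graph, SimulationSpec

    gt = make_small_world_graph(20, 4, 0.1, seed=3)
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        spec = SimulationSpec(
            n_per_group=(55, 47), n_timepoints=40, effect_nodes=(),
            clinical_assoc=("bmi", "efficiency", 0.31), seed=seed,
        )
        _, cohort = make_cohort(spec, gt)
        r, _ = partial_correlation(
            cohort["bmi"].to_numpy(),
            cohort["coupling_jitter"].to_numpy(),
            cohort[["age", "sex"]].to_numpy(float),
        )
        hits += 0.1 <= r <= 0.5
    assert hits >= int(0.9 * n_seeds)
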