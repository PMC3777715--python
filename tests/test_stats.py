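"""Permutation, NBS, partial-correlation and demographic-test checks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from slgraph import (
    critical_t,
    demographic_tests,
    nbs,
    partial_correlation,
    permutation_test,
)

from _oracles import oracle_chi2


class TestPermutationTest:
    def test_degenerate_identical_values(self):
        values = np.ones(20)
        groups = ["a"] * 10 + ["b"] * 10
        res = permutation_test(values, groups, n_perm=200, seed=0)
        assert res.observed_t == 0.0
        assert res.p_value == 1.0

    def test_detects_planted_shift(self):
        """1-SD shift at n=30+30 is found at alpha=.05 in >=80% of replicates."""
        hits = 0
        n_rep = 100
        for r in range(n_rep):
            rng = np.random.default_rng(r)
            values = np.concatenate([rng.normal(1.0, 1.0, 30), rng.normal(0.0, 1.0, 30)])
            groups = ["a"] * 30 + ["b"] * 30
            res = permutation_test(values, groups, n_perm=499, seed=r)
            hits += res.p_value < 0.05
        assert hits / n_rep >= 0.80

    def test_covariate_confound_is_removed(self):
        """A group difference driven entirely by age vanishes after adjustment."""
        rng = np.random.default_rng(3)
        age = np.concatenate([rng.uniform(40, 60, 25), rng.uniform(20, 40, 25)])
        values = 0.1 * age + rng.normal(0, 0.2, 50)
        groups = ["a"] * 25 + ["b"] * 25
        cov = pd.DataFrame({"age": age})
        naive = permutation_test(values, groups, n_perm=999, seed=4)
        adjusted = permutation_test(values, groups, covariates=cov, n_perm=999, seed=4)
        assert naive.p_value < 0.01
        assert adjusted.p_value > 0.05

    def test_reproducible_under_seed(self, rng):
        values = rng.standard_normal(30)
        groups = ["a"] * 15 + ["b"] * 15
        a = permutation_test(values, groups, n_perm=500, seed=7)
        b = permutation_test(values, groups, n_perm=500, seed=7)
        assert a == b

    def test_p_value_bounded_below(self, rng):
        values = np.concatenate([rng.normal(10, 0.1, 10), rng.normal(0, 0.1, 10)])
        groups = ["a"] * 10 + ["b"] * 10
        res = permutation_test(values, groups, n_perm=99, seed=1)
        assert res.p_value == pytest.approx(1 / 100)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            permutation_test([1.0, 2.0, 3.0], ["a", "b", "b"], n_perm=10)

    def test_one_sided_option(self, rng):
        values = np.concatenate([rng.normal(1, 1, 20), rng.normal(0, 1, 20)])
        groups = ["a"] * 20 + ["b"] * 20
        res = permutation_test(values, groups, n_perm=999, seed=2,
                               alternative="greater")
        assert res.alternative == "greater"
        assert res.p_value < 0.5


class TestCriticalT:
    def test_study_threshold(self):
        assert critical_t(0.005, 142) == pytest.approx(2.61, abs=0.005)

    def test_normal_limit(self):
        assert critical_t(0.005, 10**6) == pytest.approx(2.5758, abs=1e-3)

    def test_textbook_value(self):
        assert critical_t(0.025, 10) == pytest.approx(2.228, abs=5e-4)

    @pytest.mark.parametrize("bad", [0.0, 0.5, -0.1])
    def test_invalid_tail_rejected(self, bad):
        with pytest.raises(ValueError):
            critical_t(bad, 10)


def _matrix_stack(rng, n_subjects, n_nodes=10, effect_edges=None, shift=0.0):
    """Symmetric noise matrices; optionally shift chosen edges down."""
    stack = np.zeros((n_subjects, n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    for s in range(n_subjects):
        vals = rng.normal(0.5, 0.1, iu[0].size)
        m = np.zeros((n_nodes, n_nodes))
        m[iu] = vals
        stack[s] = m + m.T
    if effect_edges:
        for i, j in effect_edges:
            stack[:, i, j] += shift
            stack[:, j, i] += shift
    return stack


class TestNBS:
    def test_identical_groups_high_threshold_yields_nothing(self, rng):
        stack = _matrix_stack(rng, 30)
        groups = ["a"] * 15 + ["b"] * 15
        res = nbs(stack, groups, t_threshold=6.0, n_perm=100, seed=0)
        assert res.suprathreshold_edges == []
        assert res.components == []
        assert res.corrected_p == []
        assert res.max_component_links == 0

    def test_planted_component_recovered(self):
        rng = np.random.default_rng(5)
        planted = [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4), (2, 4)]
        stack = _matrix_stack(rng, 40)
        # depress the planted edges for the second half ("patients")
        for i, j in planted:
            stack[20:, i, j] -= 0.15
            stack[20:, j, i] -= 0.15
        groups = ["control"] * 20 + ["patient"] * 20
        res = nbs(stack, groups, t_threshold=2.61, n_perm=500, seed=6)
        assert res.components, "no component found"
        top = set(map(tuple, res.components[0]))
        assert len(top & set(planted)) >= 4
        assert res.corrected_p[0] < 0.05

    def test_corrected_p_uses_max_component_null(self, rng):
        stack = _matrix_stack(rng, 24)
        groups = ["a"] * 12 + ["b"] * 12
        res = nbs(stack, groups, t_threshold=2.0, n_perm=200, seed=3)
        for p in res.corrected_p:
            assert 1 / 201 <= p <= 1.0

    def test_group_sizes_preserved_and_reproducible(self, rng):
        stack = _matrix_stack(rng, 20)
        groups = ["a"] * 8 + ["b"] * 12
        a = nbs(stack, groups, t_threshold=2.0, n_perm=300, seed=9)
        b = nbs(stack, groups, t_threshold=2.0, n_perm=300, seed=9)
        assert a.component_sizes == b.component_sizes
        assert a.corrected_p == b.corrected_p


class TestPartialCorrelation:
    def test_identical_variables_give_one(self, rng):
        x = rng.standard_normal(50)
        cov = pd.DataFrame({"c": rng.standard_normal(50)})
        res = partial_correlation(x, x, cov)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_known_partial_correlation_recovered(self):
        """Trivariate Gaussian with analytic partial correlation 0.5."""
        rng = np.random.default_rng(8)
        n = 500
        z = rng.standard_normal(n)  # confounder
        e1, e2 = rng.standard_normal(n), rng.standard_normal(n)
        # cor(x, y | z) = 0.5 by construction: shared residual factor
        shared = rng.standard_normal(n)
        x = z + shared + e1
        y = z + shared + e2
        # residual correlation = var(shared)/(var(shared)+var(e)) = 1/2
        res = partial_correlation(x, y, pd.DataFrame({"z": z}))
        assert res.r == pytest.approx(0.5, abs=0.1)
        assert res.p_value < 1e-6

    def test_matches_reference_implementation(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.standard_normal(60)
        y = 0.4 * x + rng.standard_normal(60)
        c1, c2 = rng.standard_normal(60), rng.standard_normal(60)
        df = pd.DataFrame({"x": x, "y": y, "c1": c1, "c2": c2})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        res = partial_correlation(x, y, df[["c1", "c2"]])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_constant_input_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            partial_correlation(np.ones(20), rng.standard_normal(20),
                                pd.DataFrame({"c": rng.standard_normal(20)}))

    def test_too_few_cases_rejected(self, rng):
        cov = pd.DataFrame({"a": rng.standard_normal(4), "b": rng.standard_normal(4)})
        with pytest.raises(ValueError, match="at least"):
            partial_correlation(rng.standard_normal(4), rng.standard_normal(4), cov)


def _meta_from_counts(pat_mf, ctl_mf, rng):
    rows = []
    for group, (males, females) in (("patient", pat_mf), ("control", ctl_mf)):
        for k in range(males + females):
            rows.append({
                "subject_id": f"{group[0]}{k}", "group": group,
                "sex": "male" if k < males else "female",
                "age": rng.normal(40, 10), "education": rng.normal(13, 3),
                "iq": rng.normal(105, 15), "ymrs": 0, "madrs": 0,
            })
    return pd.DataFrame(rows)


class TestDemographicTests:
    def test_study_sex_table(self, rng):
        meta = _meta_from_counts((25, 32), (35, 52), rng)
        out = demographic_tests(meta)
        chi2 = out.loc[out.variable == "sex", "statistic"].iloc[0]
        assert chi2 == pytest.approx(0.187, abs=5e-4)
        assert out.loc[out.variable == "sex", "df"].iloc[0] == 1

    def test_chi2_matches_closed_form(self, rng):
        for counts in (((10, 14), (20, 9)), ((7, 7), (9, 13))):
            meta = _meta_from_counts(*counts, rng)
            out = demographic_tests(meta)
            chi2 = out.loc[out.variable == "sex", "statistic"].iloc[0]
            assert chi2 == pytest.approx(oracle_chi2(np.array(counts)), abs=1e-10)

    def test_balanced_table_gives_zero(self, rng):
        meta = _meta_from_counts((10, 10), (10, 10), rng)
        out = demographic_tests(meta)
        assert out.loc[out.variable == "sex", "statistic"].iloc[0] == 0.0

    def test_t_statistics_match_scipy(self, rng):
        meta = _meta_from_counts((12, 10), (9, 15), rng)
        out = demographic_tests(meta)
        pat = meta[meta.group == "patient"]
        ctl = meta[meta.group == "control"]
        for var in ("age", "education", "iq"):
            t, p = sps.ttest_ind(pat[var], ctl[var])
            row = out[out.variable == var].iloc[0]
            assert row.statistic == pytest.approx(t)
            assert row.p_value == pytest.approx(p)

    def test_empty_sex_cell_rejected(self, rng):
        meta = _meta_from_counts((0, 20), (10, 10), rng)
        with pytest.raises(ValueError, match="empty cells"):
            demographic_tests(meta)
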