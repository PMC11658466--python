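"""Ranking methods against independent closed-form and brute-force oracles."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelforge import (
    CohortSpec,
    differential_abundance,
    generate_cohort,
    normalize,
    rf_importance_ranking,
    severity_correlation_ranking,
    ttest_ranking,
)
from panelforge.rankers import DifferentialResult

from conftest import make_normalized


def _dataset_from_z(z, groups):
    """Pair a z-matrix with a raw dataset whose RFU is 2**z, so log2 fold
    changes are directly readable."""
    from panelforge import ProteomicDataset

    z = np.asarray(z, dtype=float)
    n, m = z.shape
    return ProteomicDataset(
        sample_ids=[f"s{i}" for i in range(n)],
        group=np.array(groups, dtype=object),
        analyte_ids=[f"P{j}" for j in range(m)],
        rfu=np.power(2.0, z),
        qc_pass=np.ones(m, dtype=bool),
    )


class TestDifferentialAbundance:
    def test_welch_matches_hand_computation(self):
        # case (1,2,3) vs control (4,5,6): t = -3.6742 at df = 4
        z = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        groups = ["case"] * 3 + ["control"] * 3
        ds = _dataset_from_z(z, groups)
        diff = differential_abundance(make_normalized(z), ds, ds.group)
        row = diff.table.iloc[0]
        # closed form: means 2 and 5, both variances 1, se = sqrt(2/3)
        t_oracle = (2 - 5) / np.sqrt(1 / 3 + 1 / 3)
        assert row.t_statistic == pytest.approx(t_oracle, abs=1e-10)
        assert row.t_statistic == pytest.approx(-3.6742, abs=5e-5)
        assert row.p_value == pytest.approx(0.0214, abs=5e-4)

    def test_exact_null_identical_groups(self):
        rng = np.random.default_rng(0)
        half = rng.standard_normal((5, 4))
        z = np.vstack([half, half])  # case matrix equals control matrix
        ds = _dataset_from_z(z, ["case"] * 5 + ["control"] * 5)
        diff = differential_abundance(make_normalized(z), ds, ds.group)
        np.testing.assert_allclose(diff.table["log2_fold_change"], 0.0, atol=1e-12)
        np.testing.assert_allclose(diff.table["p_value"], 1.0)
        assert (diff.table["direction"] == "ns").all()

    def test_log2_fold_change_from_raw_means(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((8, 3))
        groups = ["case"] * 4 + ["control"] * 4
        ds = _dataset_from_z(z, groups)
        diff = differential_abundance(make_normalized(z), ds, ds.group)
        raw = ds.rfu
        oracle = np.log2(raw[:4].mean(axis=0)) - np.log2(raw[4:].mean(axis=0))
        np.testing.assert_allclose(diff.table["log2_fold_change"], oracle, rtol=1e-12)

    def test_zero_variance_both_groups(self):
        z = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 2.0], [1.0, 2.0]])
        ds = _dataset_from_z(z, ["case", "case", "control", "control"])
        diff = differential_abundance(make_normalized(z), ds, ds.group)
        assert diff.table.iloc[0].p_value == 1.0  # equal constant means
        assert diff.table.iloc[1].p_value == 0.0  # unequal constant means

    def test_single_class_rejected(self):
        z = np.ones((4, 2))
        ds = _dataset_from_z(z, ["case"] * 4)
        with pytest.raises(ValueError, match="two samples in each group"):
            differential_abundance(make_normalized(z), ds, ds.group)


def _bh_oracle(p, alpha=0.05):
    """Brute-force BH step-up: largest k with p_(k) <= k/m * alpha."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k / m * alpha:
            k_max = k
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_max]] = True
    return rejected


@given(st.integers(min_value=0, max_value=2**32 - 1), st.integers(min_value=2, max_value=1000))
@settings(max_examples=30, deadline=None)
def test_bh_rejection_set_matches_step_up_definition(seed, m):
    rng = np.random.default_rng(seed)
    p = rng.beta(0.4, 1.0, size=m)  # mixture-like p-values with small values
    from statsmodels.stats.multitest import multipletests

    _, q, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_array_equal(q < 0.05, _bh_oracle(p, 0.05))
    # q is monotone non-decreasing in p-rank
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-15)


class TestTtestRanking:
    def _diff(self, p, t):
        table = pd.DataFrame(
            {
                "analyte_id": [f"P{j}" for j in range(len(p))],
                "log2_fold_change": np.zeros(len(p)),
                "t_statistic": t,
                "p_value": p,
                "fdr_q": p,
                "direction": "ns",
            }
        )
        return DifferentialResult(table=table)

    def test_orders_by_p_then_abs_t_then_id(self):
        diff = self._diff(p=[0.5, 0.5, 0.5, 0.01], t=[2.0, -3.0, 3.0, 1.0])
        ranked = ttest_ranking(diff, k=4)
        # P3 wins on p; then |t| descending with the id tie between P1/P2
        assert ranked.analytes == ["P3", "P1", "P2", "P0"]

    def test_k_larger_than_available_warns(self):
        diff = self._diff(p=[0.1, 0.2], t=[1.0, 2.0])
        with pytest.warns(UserWarning, match="full ordering"):
            ranked = ttest_ranking(diff, k=10)
        assert len(ranked.entries) == 2
        assert [r for _, _, r in ranked.entries] == [1, 2]


class TestSeverityCorrelation:
    def test_pearson_hand_example(self):
        # x = (1..5), y = (2,1,4,3,5): r = 0.8 by the direct formula
        z = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        sev = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        ranked = severity_correlation_ranking(make_normalized(z), sev, k=1)
        assert ranked.entries[0][1] == pytest.approx(0.8, abs=1e-12)

    def test_proportional_analyte_is_rank_one_with_r_one(self):
        rng = np.random.default_rng(2)
        sev = np.array([8.0, 12, 15, 20, 23, 26, 10, 17])
        z = np.c_[rng.standard_normal((8, 3)), (sev - sev.mean()) / sev.std()]
        ranked = severity_correlation_ranking(make_normalized(z), sev, k=2)
        assert ranked.entries[0][0] == "P3"
        assert ranked.entries[0][1] == pytest.approx(1.0, abs=1e-12)

    def test_controls_never_read(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal((10, 6))
        sev = np.r_[np.array([10.0, 14, 9, 22, 17]), np.full(5, np.nan)]
        base = severity_correlation_ranking(make_normalized(z), sev)
        mutated = z.copy()
        mutated[5:] = rng.standard_normal((5, 6)) * 100
        after = severity_correlation_ranking(make_normalized(mutated), sev)
        assert base.entries == after.entries
        pd.testing.assert_frame_equal(base.table, after.table)

    def test_all_absent_refused_with_case_only_message(self):
        z = np.ones((4, 2))
        with pytest.raises(ValueError, match="controls"):
            severity_correlation_ranking(make_normalized(z), np.full(4, np.nan))

    def test_spearman_option_monotonic(self):
        z = np.array([[1.0], [2.0], [8.0], [20.0], [100.0]])
        sev = np.array([5.0, 7, 9, 15, 21])
        ranked = severity_correlation_ranking(make_normalized(z), sev, method="spearman")
        assert ranked.entries[0][1] == pytest.approx(1.0)


class TestRandomForestRanking:
    def test_perfect_separator_is_rank_one(self):
        spec = CohortSpec(
            n_case=30, n_control=30, n_analytes=40, n_qc_fail=0,
            planted_group_effects=((13, 4.0),), seed=9,
        )
        ds = generate_cohort(spec).dataset
        z = normalize(ds)
        ranked = rf_importance_ranking(z, ds.group, n_repeats=5, seed=1, n_trees=100)
        assert ranked.analytes[0] == "PROT_0013"
        # dominates: importance far above the runner-up
        assert ranked.entries[0][1] > 3 * ranked.entries[1][1]

    def test_deterministic_under_seed(self, small_cohort):
        ds = small_cohort.dataset
        z = normalize(ds)
        a = rf_importance_ranking(z, ds.group, n_repeats=2, seed=3, n_trees=50)
        b = rf_importance_ranking(z, ds.group, n_repeats=2, seed=3, n_trees=50)
        assert a.entries == b.entries
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_single_class_rejected(self):
        z = make_normalized(np.ones((4, 3)))
        with pytest.raises(ValueError, match="two samples in each group"):
            rf_importance_ranking(z, np.array(["case"] * 4, dtype=object), n_repeats=1)

    def test_planted_signal_recovered_in_top_k(self, small_cohort):
        ds = small_cohort.dataset
        z = normalize(ds)
        ranked = rf_importance_ranking(z, ds.group, n_repeats=5, seed=0, n_trees=100)
        planted = set(small_cohort.planted_group_analytes)
        assert planted <= set(ranked.analytes)
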