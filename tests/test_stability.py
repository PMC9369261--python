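"""The four stability estimators: analytic limits, worked examples against
independent oracles, and structural invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from refstab.errors import EstimationError
from refstab.stability import (bestkeeper_stability, delta_ct_stability,
                               genorm_stability, normfinder_stability,
                               run_all)

from conftest import make_collapsed, random_collapsed, table_as_dict
from oracles import (bestkeeper_oracle, delta_ct_oracle, genorm_oracle,
                     normfinder_oracle)

hyp = settings(derandomize=True, max_examples=25, deadline=None)


def small_tables():
    """Hypothesis strategy: 3-5 genes x 4-8 samples of Cq in 10..35."""
    return st.integers(3, 5).flatmap(
        lambda g: st.integers(4, 8).flatmap(
            lambda s: st.lists(
                st.lists(st.floats(10, 35, allow_nan=False, width=32),
                         min_size=s, max_size=s),
                min_size=g, max_size=g)))


# ---------------------------------------------------------------------------
# comparative delta-Ct
# ---------------------------------------------------------------------------

class TestDeltaCt:
    def test_constant_offset_pair_is_perfectly_stable(self):
        t = make_collapsed([[20, 21, 22, 23], [22, 23, 24, 25]])
        res = delta_ct_stability(t)
        assert res.values.tolist() == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_three_gene_example_matches_brute_force(self):
        t = make_collapsed([[20, 20, 20, 20], [21, 21, 21, 21],
                            [20, 21, 20, 21]], genes=["A", "B", "C"])
        res = delta_ct_stability(t)
        sd_ac = np.std([0, -1, 0, -1], ddof=1)
        assert res.values["A"] == pytest.approx(np.mean([0.0, sd_ac]))
        assert res.values["B"] == pytest.approx(np.mean([0.0, sd_ac]))
        assert res.values["C"] == pytest.approx(sd_ac)
        oracle = delta_ct_oracle(table_as_dict(t))
        for g in "ABC":
            assert res.values[g] == pytest.approx(oracle[g], rel=1e-12)

    def test_single_gene_errors(self):
        with pytest.raises(EstimationError, match="2 genes"):
            delta_ct_stability(make_collapsed([[20, 21, 22]]))

    def test_insufficient_shared_samples_names_pair(self):
        t = make_collapsed([[20, 21, np.nan, np.nan],
                            [np.nan, np.nan, 22, 23]], genes=["A", "B"])
        with pytest.raises(EstimationError, match="'A'.*'B'"):
            delta_ct_stability(t)

    def test_gene_constant_offset_invariance(self, rng):
        t = random_collapsed(rng, 4, 6)
        base = delta_ct_stability(t).values
        shifted = t.values.copy()
        shifted.iloc[2] += 5.0
        t2 = make_collapsed(shifted.to_numpy(), genes=t.genes)
        np.testing.assert_allclose(delta_ct_stability(t2).values, base,
                                   rtol=1e-10)


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

class TestGeNorm:
    def test_constant_ratio_pair_has_zero_m(self):
        t = make_collapsed([[20, 21, 22], [23, 24, 25]])
        res = genorm_stability(t)
        assert res.values.tolist() == pytest.approx([0.0, 0.0], abs=1e-12)
        assert res.ranks.tolist() == [1.5, 1.5]

    def test_jittered_gene_excluded_first_and_m_matches_oracle(self, rng):
        base = np.linspace(20, 24, 6)
        arr = np.vstack([base, base + 1, base + 2,
                         base + rng.normal(0, 0.8, 6)])
        t = make_collapsed(arr, genes=["A", "B", "C", "D"])
        res = genorm_stability(t)
        assert res.diagnostics["exclusion_order"][0] == "D"
        m_oracle, order_oracle, ranks_oracle = genorm_oracle(table_as_dict(t))
        assert res.diagnostics["exclusion_order"] == order_oracle
        for g in "ABCD":
            assert res.values[g] == pytest.approx(m_oracle[g], rel=1e-12)
            assert res.ranks[g] == ranks_oracle[g]

    def test_v23_zero_when_third_gene_tracks_top_pair(self):
        # third gene at constant offset from the top-2 geometric mean
        a = np.array([20.0, 21.0, 22.0, 23.0])
        b = a + 1.0
        c = (a + b) / 2 + 3.0
        # add a 4th clearly unstable gene so V2/3 is defined
        d = a + np.array([0.0, 2.0, -2.0, 1.0])
        t = make_collapsed(np.vstack([a, b, c, d]), genes=["A", "B", "C", "D"])
        res = genorm_stability(t)
        assert res.diagnostics["V"]["V2/3"] == pytest.approx(0.0, abs=1e-12)

    def test_final_two_share_best_tied_rank(self, rng):
        for _ in range(5):
            t = random_collapsed(rng, 5, 7)
            res = genorm_stability(t)
            order = res.diagnostics["ranking_best_first"]
            assert res.ranks[order[0]] == 1.5
            assert res.ranks[order[1]] == 1.5

    def test_exclusion_values_match_exhaustive_oracle(self, rng):
        t = random_collapsed(rng, 6, 8)
        res = genorm_stability(t)
        m_oracle, order_oracle, _ = genorm_oracle(table_as_dict(t))
        assert res.diagnostics["exclusion_order"] == order_oracle
        for g in t.genes:
            assert res.values[g] == pytest.approx(m_oracle[g], rel=1e-10)


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

class TestBestKeeper:
    def test_constant_gene_has_zero_sd_cv(self):
        t = make_collapsed([[20, 20, 20], [22, 23, 24]], genes=["A", "B"])
        res = bestkeeper_stability(t)
        assert res.values["A"] == 0.0
        assert res.diagnostics["cv_percent"]["A"] == 0.0

    def test_mad_hand_example(self):
        t = make_collapsed([[20, 22, 24], [30, 30.1, 30.2]], genes=["A", "B"])
        res = bestkeeper_stability(t)
        assert res.values["A"] == pytest.approx(4 / 3)

    def test_gene_equal_to_index_has_r_one(self):
        a = np.array([20.0, 22.0, 24.0, 26.0])
        b = a.copy()  # index = geomean(a, b) = a
        t = make_collapsed(np.vstack([a, b]), genes=["A", "B"])
        res = bestkeeper_stability(t)
        assert res.diagnostics["r"]["A"] == pytest.approx(1.0)

    def test_matches_formula_oracle(self, rng):
        t = random_collapsed(rng, 5, 9)
        res = bestkeeper_stability(t)
        mad, cv, index, r, r_p = bestkeeper_oracle(table_as_dict(t))
        for g in t.genes:
            assert res.values[g] == pytest.approx(mad[g], rel=1e-12)
            assert res.diagnostics["cv_percent"][g] == pytest.approx(cv[g], rel=1e-12)
            assert res.diagnostics["r"][g] == pytest.approx(r[g], rel=1e-9)
            assert res.diagnostics["r_pvalue"][g] == pytest.approx(r_p[g], rel=1e-7)
        np.testing.assert_allclose(res.diagnostics["index"].to_numpy(),
                                   index, rtol=1e-12)

    def test_constant_gene_r_undefined_but_ranked(self):
        t = make_collapsed([[20, 20, 20, 20], [22, 23, 24, 25]],
                           genes=["A", "B"])
        res = bestkeeper_stability(t)
        assert np.isnan(res.diagnostics["r"]["A"])
        assert "A" in res.diagnostics["r_warnings"]
        assert res.ranks["A"] == 1.0  # still ranked, by SD


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

class TestNormFinder:
    def test_identical_genes_all_minimal_and_tied(self):
        row = [20.0, 21.0, 19.5, 22.0]
        t = make_collapsed([row, row, row], genes=["A", "B", "C"])
        res = normfinder_stability(t)
        assert res.values.tolist() == pytest.approx([0.0] * 3, abs=1e-12)
        assert res.ranks.tolist() == [2.0, 2.0, 2.0]

    def test_per_sample_shift_invariance(self, rng):
        t = random_collapsed(rng, 4, 6, two_genotypes=True)
        base = normfinder_stability(t, groups="genotype").values
        arr = t.values.to_numpy().copy()
        arr[:, 2] += 3.7  # constant added to every gene of one sample
        t2 = make_collapsed(arr, genes=t.genes,
                            genotypes=t.samples["genotype"].tolist())
        shifted = normfinder_stability(t2, groups="genotype").values
        np.testing.assert_allclose(shifted, base, rtol=1e-9, atol=1e-12)

    def test_two_group_shift_matches_transcription_oracle(self):
        flat = [20.0, 20.1, 19.9, 20.05, 19.95, 20.0]
        shifted = [25.0, 25.1, 24.9, 26.05, 25.95, 26.0]  # +1 between groups
        other = [22.0, 21.9, 22.1, 22.0, 22.05, 21.95]
        groups = ["WT"] * 3 + ["PWScr"] * 3
        t = make_collapsed([flat, shifted, other], genes=["A", "B", "C"],
                           genotypes=groups)
        res = normfinder_stability(t, groups="genotype")
        oracle = normfinder_oracle(table_as_dict(t), groups)
        for g in "ABC":
            assert res.values[g] == pytest.approx(oracle[g], rel=1e-12)
        # the shifted gene is the least stable
        assert res.ranks["B"] == 3.0

    def test_intergroup_deviations_sum_to_zero(self, rng):
        t = random_collapsed(rng, 5, 10, two_genotypes=True)
        res = normfinder_stability(t, groups="genotype")
        d = res.diagnostics["intergroup_deviation"]
        np.testing.assert_allclose(d.sum(axis=0), 0.0, atol=1e-10)

    def test_ungrouped_matches_oracle(self, rng):
        t = random_collapsed(rng, 5, 8)
        res = normfinder_stability(t)
        oracle = normfinder_oracle(table_as_dict(t), None)
        for g in t.genes:
            assert res.values[g] == pytest.approx(oracle[g], rel=1e-12, abs=1e-12)

    def test_too_few_genes_errors(self):
        with pytest.raises(EstimationError, match="3 genes"):
            normfinder_stability(make_collapsed([[20, 21, 22], [23, 24, 25]]))

    def test_small_group_errors(self):
        t = make_collapsed(np.random.default_rng(0).uniform(15, 30, (3, 3)),
                           genotypes=["WT", "WT", "PWScr"])
        with pytest.raises(EstimationError, match="PWScr"):
            normfinder_stability(t, groups="genotype")


# ---------------------------------------------------------------------------
# cross-method invariants
# ---------------------------------------------------------------------------

@hyp
@given(small_tables())
def test_relabeling_and_sample_reordering_invariance(data):
    arr = np.array(data)
    t = make_collapsed(arr)
    base = run_all(t)
    perm = np.random.RandomState(0).permutation(arr.shape[1])
    t_perm = make_collapsed(arr[:, perm])
    relabeled = make_collapsed(arr, genes=[f"Z{i}" for i in range(arr.shape[0])])
    for method, res in base.items():
        res_p = run_all(t_perm)[method]
        np.testing.assert_allclose(res_p.values.to_numpy(),
                                   res.values.to_numpy(), rtol=1e-9, atol=1e-12)
        res_r = run_all(relabeled)[method]
        np.testing.assert_allclose(res_r.values.to_numpy(),
                                   res.values.to_numpy(), rtol=1e-9, atol=1e-12)


@hyp
@given(small_tables())
def test_ranks_are_sorted_ranks_of_values(data):
    """delta-Ct, BestKeeper and NormFinder rank ascending by value with
    average ties (sort-based oracle); geNorm ranks by exclusion order with
    the final pair tied at the top."""
    t = make_collapsed(np.array(data))
    for method, res in run_all(t).items():
        if method == "genorm":
            order = res.diagnostics["ranking_best_first"]
            assert sorted(res.ranks.tolist()) == sorted(
                [1.5, 1.5] + list(range(3, len(order) + 1)))
            for worst_pos, g in enumerate(res.diagnostics["exclusion_order"]):
                assert res.ranks[g] == len(order) - worst_pos
            continue
        expected = stats.rankdata(res.values.to_numpy(), method="average")
        np.testing.assert_allclose(res.ranks.to_numpy(), expected)


def test_values_are_nonnegative(rng):
    t = random_collapsed(rng, 5, 8, two_genotypes=True)
    for method, res in run_all(t, normfinder_groups="genotype").items():
        assert (res.values.to_numpy() >= 0).all(), method


def test_report_frame_layout(rng):
    t = random_collapsed(rng, 4, 6)
    frame = bestkeeper_stability(t).to_frame()
    assert {"gene", "value", "rank", "cv_percent", "r", "r_pvalue"} <= set(frame.columns)
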