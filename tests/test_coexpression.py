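"""Normalization, probe merging, Hobohm-2 pruning and gene correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assocnet.coexpression import (
    GeneProfileMatrix,
    PruneConfig,
    SimilarityMatrix,
    array_similarity,
    gene_correlation,
    hobohm2_prune,
    merge_probes,
    normalize_dual_channel,
    normalize_single_channel,
    pool_experiments,
)
from assocnet.io import DUAL, SINGLE, ExperimentSet, ProbeGeneMap
from conftest import make_experiment


def profiles_from(values, gene_ids=None, array_ids=None, channel=DUAL):
    values = np.asarray(values, dtype=float)
    g, a = values.shape
    return GeneProfileMatrix(
        organism_id="org",
        channel=channel,
        gene_ids=tuple(gene_ids or (f"g{i}" for i in range(g))),
        array_ids=tuple(array_ids or (f"a{j}" for j in range(a))),
        values=values,
    )


class TestNormalizeSingleChannel:
    def test_equals_manual_log2_rowcenter_zscore(self):
        rng = np.random.default_rng(0)
        m = make_experiment("E", 4, 3, channel=SINGLE, values=2.0 ** rng.normal(5, 1, (4, 3)))
        out = normalize_single_channel(m)
        manual = np.log2(m.values)
        manual -= manual.mean(axis=1, keepdims=True)
        manual = (manual - manual.mean(axis=0)) / manual.std(axis=0)
        np.testing.assert_allclose(out.values, manual, atol=1e-9)

    def test_row_mean_subtraction_closed_form(self):
        # probe (2, 8): log2 -> (1, 3), minus row mean 2 -> (-1, +1);
        # use two mirrored probes so the z-step rescales both columns equally
        m = make_experiment("E", 2, 2, channel=SINGLE, values=np.array([[2.0, 8.0], [8.0, 2.0]]))
        out = normalize_single_channel(m)
        # after row-centering rows are (-1,+1) and (+1,-1); z-step divides by sd 1
        np.testing.assert_allclose(out.values, [[-1, 1], [1, -1]], atol=1e-9)

    def test_output_columns_standardized(self):
        rng = np.random.default_rng(1)
        m = make_experiment("E", 40, 3, channel=SINGLE, values=2.0 ** rng.normal(8, 2, (40, 3)))
        out = normalize_single_channel(m)
        np.testing.assert_allclose(out.values.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(out.values.std(axis=0), 1, atol=1e-9)

    def test_nonpositive_values_become_missing(self):
        m = make_experiment("E", 2, 2, channel=SINGLE, values=np.array([[2.0, -1.0], [4.0, 8.0]]))
        out = normalize_single_channel(m)
        assert np.isnan(out.values[0, 1])

    def test_channel_mismatch_rejected(self, small_dual_matrix):
        with pytest.raises(ValueError, match="single"):
            normalize_single_channel(small_dual_matrix)


class TestNormalizeDualChannel:
    def test_population_zscore_closed_form(self):
        m = make_experiment("E", 3, 1, values=np.array([[-1.0], [0.0], [1.0]]))
        out = normalize_dual_channel(m)
        np.testing.assert_allclose(out.values[:, 0], [-1.2247, 0, 1.2247], atol=1e-3)

    def test_constant_column_maps_to_zeros(self):
        m = make_experiment("E", 3, 2, values=np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        out = normalize_dual_channel(m)
        np.testing.assert_array_equal(out.values[:, 0], 0.0)

    def test_all_missing_column_stays_missing(self):
        m = make_experiment("E", 3, 2, values=np.array([[np.nan, 1.0], [np.nan, 2.0], [np.nan, 3.0]]))
        out = normalize_dual_channel(m)
        assert np.isnan(out.values[:, 0]).all()

    def test_idempotent(self, small_dual_matrix):
        once = normalize_dual_channel(small_dual_matrix)
        twice = normalize_dual_channel(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-9)

    def test_channel_mismatch_rejected(self):
        m = make_experiment("E", 2, 2, channel=SINGLE)
        with pytest.raises(ValueError, match="dual"):
            normalize_dual_channel(m)


class TestMergeProbes:
    def test_multi_probe_gene_averaged(self):
        m = make_experiment("E", 2, 1, values=np.array([[1.0], [3.0]]))
        pmap = ProbeGeneMap({"p1": "gX", "p2": "gX"})
        out = merge_probes(m, pmap)
        assert out.probe_ids == ("gX",)
        assert out.values[0, 0] == 2.0

    def test_missing_aware_mean(self):
        m = make_experiment("E", 2, 1, values=np.array([[1.0], [np.nan]]))
        out = merge_probes(m, ProbeGeneMap({"p1": "gX", "p2": "gX"}))
        assert out.values[0, 0] == 1.0

    def test_unmapped_probes_dropped(self):
        m = make_experiment("E", 3, 2)
        out = merge_probes(m, ProbeGeneMap({"p1": "gA"}))
        assert out.probe_ids == ("gA",)

    def test_zero_overlap_map_yields_empty(self):
        m = make_experiment("E", 3, 2)
        out = merge_probes(m, ProbeGeneMap({"q1": "gA"}))
        assert out.n_probes == 0


class TestArraySimilarity:
    def test_identical_columns_give_one(self):
        v = np.random.default_rng(0).normal(size=(30, 1))
        p = profiles_from(np.hstack([v, v]))
        sims = array_similarity(p, min_overlap=20)
        assert sims.sims[0, 1] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        col = np.arange(1.0, 26.0)
        p = profiles_from(np.column_stack([col, col[::-1]]))
        sims = array_similarity(p, min_overlap=20)
        assert sims.sims[0, 1] == pytest.approx(-1.0)

    def test_hand_enumerated_spearman(self):
        # ranks (1,2,3,4) vs (1,3,2,4): rho = 1 - 6*2/(4*15) = 0.8
        p = profiles_from(np.column_stack([[1, 2, 3, 4], [1, 3, 2, 4]]))
        sims = array_similarity(p, min_overlap=2)
        assert sims.sims[0, 1] == pytest.approx(0.8)

    def test_insufficient_overlap_is_missing(self):
        v = np.random.default_rng(0).normal(size=(10, 2))
        v[:6, 0] = np.nan  # only 4 shared genes
        sims = array_similarity(profiles_from(v), min_overlap=5)
        assert np.isnan(sims.sims[0, 1])

    def test_single_array_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            array_similarity(profiles_from(np.zeros((5, 1))))

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=(40, 5))
        ids = [f"a{j}" for j in range(5)]
        sims = array_similarity(profiles_from(v, array_ids=ids), 20)
        perm = [3, 1, 4, 0, 2]
        sims_p = array_similarity(
            profiles_from(v[:, perm], array_ids=[ids[j] for j in perm]), 20
        )
        for i, j in itertools.combinations(range(5), 2):
            pi, pj = perm.index(i), perm.index(j)
            assert sims.sims[i, j] == pytest.approx(sims_p.sims[pi, pj], abs=1e-12)


def greedy_prune_oracle(ids, sims, threshold):
    """Independent step-by-step simulation of the Hobohm-2 greedy rule."""
    edges = {
        frozenset((a, b))
        for i, a in enumerate(ids)
        for j, b in enumerate(ids)
        if i < j and np.isfinite(sims[i, j]) and sims[i, j] > threshold
    }
    alive = set(ids)
    while True:
        deg = {v: sum(1 for e in edges if v in e and e <= alive) for v in alive}
        worst = max(deg.values(), default=0)
        if worst == 0:
            return sorted(alive)
        # delete the lexicographically largest among the max-degree vertices
        victim = max(v for v in alive if deg[v] == worst)
        alive.discard(victim)


class TestHobohm2:
    def test_edgeless_graph_keeps_everything(self):
        sims = SimilarityMatrix(("a", "b", "c"), np.eye(3) * 1.0)
        assert hobohm2_prune(sims, 0.7) == ["a", "b", "c"]

    def test_hub_removed_first(self):
        # (A,B)=0.8, (A,C)=0.8, (B,C)=0.1 at threshold 0.7: A has degree 2
        s = np.array([[1.0, 0.8, 0.8], [0.8, 1.0, 0.1], [0.8, 0.1, 1.0]])
        sims = SimilarityMatrix(("A", "B", "C"), s)
        retained = hobohm2_prune(sims, 0.7)
        assert retained == ["B", "C"]
        # brute force: {B, C} is a maximal conflict-free subset
        for extra in ({"A", "B"}, {"A", "C"}):
            pairs = itertools.combinations(sorted(extra), 2)
            assert any(
                s[("A", "B", "C").index(x)][("A", "B", "C").index(y)] > 0.7
                for x, y in pairs
            )

    def test_channel_default_thresholds(self):
        cfg = PruneConfig()
        assert cfg.threshold_for(SINGLE) == 0.7
        assert cfg.threshold_for(DUAL) == 0.95

    def test_threshold_similarity_not_redundant(self):
        # similarity exactly at the threshold is not an edge (strict >)
        s = np.array([[1.0, 0.7], [0.7, 1.0]])
        assert hobohm2_prune(SimilarityMatrix(("a", "b"), s), 0.7) == ["a", "b"]

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        raw = rng.uniform(-1, 1, (n, n))
        s = (raw + raw.T) / 2
        np.fill_diagonal(s, 1.0)
        ids = tuple(f"a{k}" for k in range(n))
        threshold = float(rng.uniform(0.2, 0.9))
        retained = hobohm2_prune(SimilarityMatrix(ids, s), threshold)
        assert retained == greedy_prune_oracle(ids, s, threshold)
        for x, y in itertools.combinations(retained, 2):
            assert not s[ids.index(x), ids.index(y)] > threshold

    def test_exact_duplicate_array_pruned(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(50, 4))
        base = profiles_from(v)
        dup = profiles_from(
            np.hstack([v, v[:, [1]]]), array_ids=[f"a{j}" for j in range(4)] + ["a1dup"]
        )
        t = 0.9
        retained_base = hobohm2_prune(array_similarity(base, 20), t)
        retained_dup = hobohm2_prune(array_similarity(dup, 20), t)
        assert len(retained_dup) == len(retained_base)
        assert len({"a1", "a1dup"} & set(retained_dup)) == 1


class TestGeneCorrelation:
    def test_exact_anticorrelation(self):
        p = profiles_from(np.array([[1.0, 2, 3], [3, 2, 1]]), gene_ids=["gA", "gB"])
        out = gene_correlation(p, list(p.array_ids), min_overlap=3)
        assert out.table.loc[0, "r"] == pytest.approx(-1.0)
        assert out.table.loc[0, "n_arrays"] == 3

    def test_matches_textbook_formula(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 4, 5, 9])
        p = profiles_from(np.vstack([x, y]), gene_ids=["gA", "gB"])
        out = gene_correlation(p, list(p.array_ids), min_overlap=4)
        expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert out.table.loc[0, "r"] == pytest.approx(expected, abs=1e-9)

    def test_pairs_below_overlap_omitted(self):
        v = np.random.default_rng(0).normal(size=(3, 10))
        v[0, :8] = np.nan
        out = gene_correlation(profiles_from(v), [f"a{j}" for j in range(10)], min_overlap=5)
        genes_in_pairs = set(out.table["gene_a"]) | set(out.table["gene_b"])
        assert "g0" not in genes_in_pairs
        assert len(out.table) == 1

    def test_empty_retained_rejected(self):
        p = profiles_from(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="empty"):
            gene_correlation(p, [], min_overlap=2)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(9)
        v = rng.normal(size=(5, 30))
        ids = [f"g{i}" for i in range(5)]
        out1 = gene_correlation(profiles_from(v, gene_ids=ids), [f"a{j}" for j in range(30)], 20)
        perm = [4, 2, 0, 3, 1]
        out2 = gene_correlation(
            profiles_from(v[perm], gene_ids=[ids[i] for i in perm]),
            [f"a{j}" for j in range(30)],
            20,
        )
        pd.testing.assert_frame_equal(out1.table, out2.table)


def test_pool_experiments_traces_columns():
    e1 = make_experiment("E1", 3, 2, seed=1)
    e2 = make_experiment("E2", 3, 2, seed=2)
    pmap = ProbeGeneMap({"p1": "g1", "p2": "g2", "p3": "g3"})
    pooled = pool_experiments(ExperimentSet("org", (e1, e2)), pmap, DUAL)
    assert pooled.array_ids == ("E1:s1", "E1:s2", "E2:s1", "E2:s2")
    assert pooled.gene_ids == ("g1", "g2", "g3")


def test_pool_experiments_channel_filtering():
    e1 = make_experiment("E1", 3, 2, channel=SINGLE)
    pmap = ProbeGeneMap({"p1": "g1"})
    assert pool_experiments(ExperimentSet("org", (e1,)), pmap, DUAL) is None


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_zscore_idempotence_property(seed):
    rng = np.random.default_rng(seed)
    m = make_experiment("E", 6, 4, values=rng.normal(size=(6, 4)))
    once = normalize_dual_channel(m)
    twice = normalize_dual_channel(once)
    np.testing.assert_allclose(once.values, twice.values, atol=1e-9)
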