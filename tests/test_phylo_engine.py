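import sys

import numpy as np
import pytest

from plastonoise import (
    Alignment,
    bootstrap_support,
    external_tree_adapter,
    jc_correct,
    nj_tree,
    pairwise_distances,
    read_tree,
    rf_distance,
    branch_score,
)
from plastonoise.tree_metrics import split_table

from conftest import path_distance_matrix, random_additive_tree


class TestDistances:
    def test_identical_sequences(self):
        aln = Alignment.from_sequences([("a", "ACGT"), ("b", "ACGT")])
        assert pairwise_distances(aln, "none").values[0, 1] == 0
        assert pairwise_distances(aln, "jc").values[0, 1] == 0

    def test_quarter_mismatch_jc_closed_form(self):
        aln = Alignment.from_sequences([("a", "AAAA"), ("b", "AAAC")])
        dm_p = pairwise_distances(aln, "none")
        dm_jc = pairwise_distances(aln, "jc")
        assert dm_p.values[0, 1] == pytest.approx(0.25)
        assert dm_jc.values[0, 1] == pytest.approx(-0.75 * np.log(1 - 1 / 3))
        assert dm_jc.values[0, 1] == pytest.approx(0.30410, abs=1e-5)

    def test_pairwise_deletion(self):
        aln = Alignment.from_sequences([("a", "AA-A"), ("b", "AACA")])
        dm = pairwise_distances(aln, "none")
        assert dm.n_compared[0, 1] == 3
        assert dm.values[0, 1] == 0

    def test_saturated_pair_flagged_undefined(self):
        aln = Alignment.from_sequences([("a", "AAAAA"), ("b", "CCCCA")])
        dm = pairwise_distances(aln, "jc")  # p = 0.8
        assert dm.undefined[0, 1]
        assert np.isnan(dm.values[0, 1])

    def test_zero_overlap_pair_undefined_not_exception(self):
        aln = Alignment.from_sequences([("a", "AA--"), ("b", "--AA"), ("c", "AAAA")])
        dm = pairwise_distances(aln, "none")
        assert dm.undefined[0, 1] and not dm.undefined[0, 2]

    def test_complete_deletion_drops_gapped_columns(self):
        aln = Alignment.from_sequences([("a", "A-CT"), ("b", "AACA"), ("c", "AACA")])
        dm = pairwise_distances(aln, "none", deletion="complete")
        assert dm.n_compared[1, 2] == 3

    def test_jc_monotone_and_above_identity(self):
        p = np.linspace(0.0, 0.74, 200)
        d = jc_correct(p)
        assert (np.diff(d) > 0).all()
        assert (d >= p - 1e-12).all()


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        gen = read_tree("((a:1,b:2):1,(c:3,d:1):1);")
        dm = path_distance_matrix(gen)
        tree = nj_tree(dm)
        assert rf_distance(tree, gen) == 0
        assert branch_score(tree, gen) == pytest.approx(0.0, abs=1e-20)

    def test_three_taxa_three_point_lengths(self):
        from plastonoise import DistanceMatrix

        vals = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
        dm = DistanceMatrix(("a", "b", "c"), vals, np.ones((3, 3)), "p_distance")
        tree = nj_tree(dm)
        lens = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lens == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_star_matrix_zero_internal_lengths(self):
        from plastonoise import DistanceMatrix

        n = 5
        vals = np.full((n, n), 2.0)
        np.fill_diagonal(vals, 0.0)
        dm = DistanceMatrix(tuple("abcde"), vals, np.ones((n, n)), "p_distance")
        tree = nj_tree(dm)
        internal = [
            nd.edge.length
            for nd in tree.preorder_node_iter()
            if nd.parent_node is not None and not nd.is_leaf()
        ]
        assert max(internal, default=0.0) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_entries_rejected(self):
        from plastonoise import DistanceMatrix

        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = np.nan
        dm = DistanceMatrix(("a", "b", "c"), vals, np.ones((3, 3)), "p_distance")
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(dm)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_random_additive_topologies(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        gen = random_additive_tree(rng, n)
        assert rf_distance(nj_tree(path_distance_matrix(gen)), gen) == 0


def planted_split_alignment(n_cols_signal=50, n_cols_bg=60):
    """Alignment where one split (ab|cdef) is fixed by many binary columns."""
    taxa = list("abcdef")
    cols = []
    for _ in range(n_cols_signal):
        cols.append({t: ("A" if t in "ab" else "C") for t in taxa})
    for i in range(n_cols_bg):
        cols.append({t: "ACGT"[i % 4] for t in taxa})
    return Alignment.from_sequences(
        (t, "".join(c[t] for c in cols)) for t in taxa
    )


class TestBootstrap:
    def test_planted_split_high_support(self):
        aln = planted_split_alignment()
        res = bootstrap_support(aln, replicates=200, seed=11)
        table = split_table(res.tree)
        key = [s for s in table.supports if s == frozenset("cdef") or s == frozenset("ab")]
        assert key, "planted split missing from point tree"
        assert table.supports[key[0]] >= 99

    def test_single_replicate_supports_are_binary(self):
        aln = planted_split_alignment(10, 10)
        res = bootstrap_support(aln, replicates=1, seed=0)
        sups = [s for s in split_table(res.tree).supports.values() if s is not None]
        assert set(sups) <= {0.0, 100.0}

    def test_same_seed_reproducible(self):
        aln = planted_split_alignment(20, 30)
        from plastonoise import tree_to_newick

        t1 = bootstrap_support(aln, 50, seed=5).tree
        t2 = bootstrap_support(aln, 50, seed=5).tree
        assert tree_to_newick(t1) == tree_to_newick(t2)

    def test_disjoint_seeds_converge_within_five_points(self):
        from plastonoise import simulate_alignment
        from plastonoise.synthetic_data import SimConfig

        cfg = SimConfig(
            true_tree="((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05,(e:0.1,f:0.1):0.05);",
            n_cols=300, gamma_shape=1.0, n_rate_categories=4,
            category_fractions={"exon": 1.0}, category_rates={"exon": 1.0},
            gap_prob=0.0, mask_prob=0.0, seed=17,
        )
        aln, _, _ = simulate_alignment(cfg)
        s1 = bootstrap_support(aln, 500, seed=101, keep_replicates=False)
        s2 = bootstrap_support(aln, 500, seed=202, keep_replicates=False)
        t1, t2 = split_table(s1.tree), split_table(s2.tree)
        shared = t1.splits & t2.splits
        assert shared
        for split in shared:
            assert abs(t1.supports[split] - t2.supports[split]) <= 5

    def test_saturation_ceiling_keeps_partition_inferable(self):
        aln = Alignment.from_sequences(
            [("a", "ACGTACGTAC"), ("b", "CATCGTACGA"), ("c", "GTACGATCGT"), ("d", "TACGCTAGCA")]
        )
        with pytest.raises(ValueError):
            bootstrap_support(aln, replicates=10, seed=1, correction="jc")
        res = bootstrap_support(
            aln, replicates=10, seed=1, correction="jc", saturation_ceiling=3.0
        )
        assert res.tree is not None


class TestNewickAndAdapter:
    def test_supports_parsed_from_internal_labels(self):
        tree = read_tree("((a,b)95,(c,d)87);")
        labels = sorted(
            nd.label
            for nd in tree.preorder_node_iter()
            if nd.label is not None and not nd.is_leaf()
        )
        assert labels == ["87", "95"]
        table = split_table(tree)
        assert table.supports[frozenset({"c", "d"})] == 95.0 or \
            table.supports[frozenset({"c", "d"})] == 87.0

    def test_malformed_newick_raises(self):
        with pytest.raises(ValueError):
            read_tree("((a,b,;")

    def test_adapter_echoes_fixed_tree(self, tmp_path):
        fixed = tmp_path / "fixed.nwk"
        fixed.write_text("((a:1,b:1)90:1,(c:1,d:1)80:1);\n")
        aln = Alignment.from_sequences(
            [(t, "ACGT") for t in "abcd"]
        )
        tree = external_tree_adapter(aln, f"cp {fixed} {{out}}")
        assert sorted(lf.taxon.label for lf in tree.leaf_node_iter()) == list("abcd")

    def test_adapter_nonzero_exit_raises(self, tmp_path):
        aln = Alignment.from_sequences([(t, "ACGT") for t in "abcd"])
        with pytest.raises(RuntimeError, match="exit"):
            external_tree_adapter(aln, f"{sys.executable} -c import_sys_fail")
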