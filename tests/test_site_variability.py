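import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plastonoise import (
    Alignment,
    compute_ov,
    rank_sites,
    tree_dependent_rates,
    category_summary,
    read_tree,
)
from plastonoise.alignment_io import ColumnAnnotation, N_DETERMINATE

from conftest import random_alignment


def brute_force_ov(aln):
    """Pair-enumeration oracle for observed variability."""
    ov = np.zeros(aln.n_cols)
    k = np.zeros(aln.n_cols, dtype=int)
    for c in range(aln.n_cols):
        col = aln.codes[:, c]
        mism = valid = 0
        for i, j in itertools.combinations(range(aln.n_taxa), 2):
            if col[i] < N_DETERMINATE and col[j] < N_DETERMINATE:
                valid += 1
                mism += int(col[i] != col[j])
        k[c] = valid
        ov[c] = mism / valid if valid else 0.0
    return ov, k


def column(*chars):
    """Single-column alignment from per-taxon characters."""
    return Alignment.from_sequences((f"t{i}", ch) for i, ch in enumerate(chars))


class TestObservedVariability:
    @pytest.mark.parametrize(
        "chars, exp_ov, exp_k",
        [
            (("A", "A", "A", "A"), 0.0, 6),
            (("A", "A", "C", "G"), 5 / 6, 6),
            (("A", "A", "-", "C"), 2 / 3, 3),
            (("-", "-", "-", "N"), 0.0, 0),
        ],
    )
    def test_single_column_values(self, chars, exp_ov, exp_k):
        sv = compute_ov(column(*chars))
        assert sv.ov[0] == pytest.approx(exp_ov)
        assert sv.k[0] == exp_k
        assert bool(sv.defined[0]) == (exp_k > 0)

    def test_ambiguity_codes_excluded_from_pairs(self):
        # R is indeterminate for OV: pairs restricted to the three called bases
        sv = compute_ov(column("A", "R", "A", "C"))
        assert sv.k[0] == 3
        assert sv.ov[0] == pytest.approx(2 / 3)

    @given(st.integers(0, 2**16))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, int(rng.integers(2, 9)), 50)
        sv = compute_ov(aln)
        ov, k = brute_force_ov(aln)
        np.testing.assert_allclose(sv.ov, ov, atol=1e-12)
        assert np.array_equal(sv.k, k)

    def test_invariant_under_taxon_order_and_state_relabel(self):
        rng = np.random.default_rng(5)
        aln = random_alignment(rng, 6, 30)
        perm = rng.permutation(aln.n_taxa)
        reordered = Alignment(
            tuple(aln.taxa[i] for i in perm), aln.codes[perm].copy()
        )
        np.testing.assert_allclose(compute_ov(aln).ov, compute_ov(reordered).ov)
        # relabel nucleotide states by a permutation of A,C,G,T
        relabel = np.arange(16, dtype=np.uint8)
        relabel[:4] = [2, 3, 1, 0]
        relabeled = Alignment(aln.taxa, relabel[aln.codes])
        np.testing.assert_allclose(compute_ov(aln).ov, compute_ov(relabeled).ov)

    def test_removing_taxon_never_increases_k(self):
        rng = np.random.default_rng(9)
        aln = random_alignment(rng, 7, 40)
        k_full = compute_ov(aln).k
        sub = aln.select_taxa(list(aln.taxa[1:]))
        assert (compute_ov(sub).k <= k_full).all()


class TestRanking:
    def test_descending_with_index_tiebreak(self):
        r = rank_sites(np.array([0.2, 0.9, 0.2]))
        assert list(r.order) == [1, 0, 2]

    def test_all_ties_keep_identity_order(self):
        r = rank_sites(np.array([0.5, 0.5, 0.5]))
        assert list(r.order) == [0, 1, 2]

    def test_single_column(self):
        assert list(rank_sites(np.array([0.3])).order) == [0]

    def test_undefined_columns_sort_last(self):
        sv = compute_ov(
            Alignment.from_sequences(
                [("a", "A-C"), ("b", "C-C"), ("c", "A-C")]
            )
        )
        r = rank_sites(sv)
        assert r.order[-1] == 1  # the k=0 column

    def test_all_undefined_is_error(self):
        sv = compute_ov(Alignment.from_sequences([("a", "-"), ("b", "-")]))
        with pytest.raises(ValueError):
            rank_sites(sv)


class TestTreeDependentRates:
    def grid_oracle(self, aln, tree, col, n_grid=1000):
        from plastonoise.site_variability import (
            _column_loglik,
            _postorder_edges,
            _PARTIALS,
        )

        plan, leaf_rows, n_slots = _postorder_edges(
            tree, {t: i for i, t in enumerate(aln.taxa)}
        )
        grid = np.logspace(np.log10(1e-4), np.log10(64.0), n_grid)
        partials = _PARTIALS[aln.codes[:, col]]
        ll = [_column_loglik(r, partials, plan, leaf_rows, n_slots) for r in grid]
        return grid, grid[int(np.argmax(ll))]

    def test_invariant_column_hits_lower_bound(self):
        aln = Alignment.from_sequences([(t, "A") for t in "abcd"])
        tree = read_tree("((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05);")
        r = tree_dependent_rates(aln, tree)
        assert r[0] < 0.01

    def test_conflicting_column_on_star_is_fast(self):
        aln = Alignment.from_sequences(
            [("a", "A"), ("b", "C"), ("c", "G"), ("d", "T")]
        )
        tree = read_tree("(a:0.05,b:0.05,c:0.05,d:0.05);")
        r = tree_dependent_rates(aln, tree)
        assert r[0] > 32.0

    def test_undefined_for_sparse_columns(self):
        aln = Alignment.from_sequences(
            [("a", "A"), ("b", "-"), ("c", "-"), ("d", "N")]
        )
        tree = read_tree("((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05);")
        assert np.isnan(tree_dependent_rates(aln, tree)[0])

    def test_agrees_with_log_grid_oracle(self):
        from conftest import random_additive_tree

        rng = np.random.default_rng(21)
        for rep in range(4):
            tree = random_additive_tree(rng, 6, 0.02, 0.3)
            aln = random_alignment(rng, 6, 6, alphabet="ACGT")
            rates = tree_dependent_rates(aln, tree)
            for c in range(aln.n_cols):
                grid, opt = self.grid_oracle(aln, tree, c)
                step = np.log(grid[1]) - np.log(grid[0])
                assert abs(np.log(rates[c]) - np.log(opt)) <= step + 1e-9


class TestCategorySummary:
    def make(self, values, categories):
        sv = np.asarray(values, dtype=float)
        ann = ColumnAnnotation(
            np.asarray(categories, dtype=object),
            np.full(len(categories), "", dtype=object),
        )
        return sv, ann

    def test_means(self):
        sv, ann = self.make(
            [0, 1, 1, 1], ["noncoding", "noncoding", "exon", "exon"]
        )
        res = category_summary(sv, ann)
        assert res.table.loc["noncoding", "mean"] == pytest.approx(0.5)
        assert res.table.loc["exon", "mean"] == pytest.approx(1.0)
        assert res.table["n"].sum() == 4

    def test_identical_distributions_share_letter(self):
        rng = np.random.default_rng(0)
        vals = np.tile(rng.random(50), 2)
        _, ann = self.make(vals, ["noncoding"] * 50 + ["exon"] * 50)
        res = category_summary(vals, ann)
        letters = set(res.table["letters"])
        assert len(letters) == 1

    def test_separated_distributions_get_distinct_letters(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(0.1, 0.01, 60), rng.normal(0.8, 0.01, 60)])
        _, ann = self.make(vals, ["noncoding"] * 60 + ["exon"] * 60)
        res = category_summary(vals, ann)
        a = set(res.table.loc["noncoding", "letters"])
        b = set(res.table.loc["exon", "letters"])
        assert not (a & b)
        assert res.anova_p < 1e-6

    def test_locus_exclusion_recomputes_exon_mean(self):
        vals = np.array([0.1, 0.9, 0.5, 0.5, 0.2, 0.3])
        ann = ColumnAnnotation(
            np.asarray(
                ["exon", "exon", "noncoding", "noncoding", "intron", "intron"],
                dtype=object,
            ),
            np.asarray(["", "ycf1", "", "", "", ""], dtype=object),
        )
        res = category_summary(vals, ann, exclude_loci=["ycf1"])
        assert res.table.loc["exon_without_ycf1", "mean"] == pytest.approx(0.1)
        assert res.table.loc["exon", "mean"] == pytest.approx(0.5)
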