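"""Per-site variability: observed variability (OV), likelihood site rates, rankings.

Observed variability of an alignment column is the fraction of mismatching
pairs among all pairs of taxa that both carry a determinate base at that
column:

    OV = sum_{i<j} d_ij / k

where d_ij is 0 for a match and 1 for a mismatch, and k counts only pairs in
which neither taxon has a gap, a mask, or an ambiguity code.  Columns with
k = 0 carry no signal; they are assigned OV 0 and flagged undefined, and a
ranking sorts them last.

The tree-dependent alternative scores each column by the rate multiplier r
that maximizes the column's likelihood under the Jukes–Cantor model on a
fixed tree whose branch lengths are scaled by r (indeterminate states are
marginalized).  It plays the role that per-site ML rate estimation (baseml
style) plays in tree-aware noise ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .alignment_io import (
    Alignment,
    ColumnAnnotation,
    IUPAC_SETS,
    N_DETERMINATE,
)

__all__ = [
    "SiteVariability",
    "SiteRanking",
    "CategorySummary",
    "compute_ov",
    "rank_sites",
    "tree_dependent_rates",
    "category_summary",
    "ov_report",
]


@dataclass(frozen=True)
class SiteVariability:
    ov: np.ndarray        # float, per column, 0 where undefined
    k: np.ndarray         # int, number of valid pairwise comparisons
    defined: np.ndarray   # bool, k > 0

    @property
    def n_cols(self) -> int:
        return len(self.ov)


def compute_ov(aln: Alignment) -> SiteVariability:
    """Observed variability per column (pairs of determinate bases only)."""
    if aln.n_taxa < 2:
        raise ValueError("OV needs at least 2 taxa")
    codes = aln.codes
    # per-column counts of each determinate base, shape (4, n_cols)
    counts = np.stack([(codes == b).sum(axis=0) for b in range(N_DETERMINATE)])
    det = counts.sum(axis=0)
    k = det * (det - 1) // 2
    matches = (counts * (counts - 1) // 2).sum(axis=0)
    mismatches = k - matches
    with np.errstate(divide="ignore", invalid="ignore"):
        ov = np.where(k > 0, mismatches / np.maximum(k, 1), 0.0)
    return SiteVariability(ov.astype(float), k.astype(np.int64), k > 0)


@dataclass(frozen=True)
class SiteRanking:
    """Total order over columns, most variable first.

    ``order[i]`` is the column index of rank i.  Ties are broken by ascending
    column index (stable), and undefined columns (no valid pairwise
    comparison) sort after every defined column.
    """

    order: np.ndarray
    scores: np.ndarray   # score per column (alignment order, not rank order)
    source: str          # "ov" or "tree_dependent"

    def top(self, m: int) -> np.ndarray:
        """Column indices of the m most variable sites."""
        return self.order[:m]


def rank_sites(
    sv: SiteVariability | np.ndarray,
    source: str = "ov",
    defined: np.ndarray | None = None,
) -> SiteRanking:
    """Rank columns by descending score; ties by ascending column index."""
    if isinstance(sv, SiteVariability):
        scores, defined = sv.ov, sv.defined
    else:
        scores = np.asarray(sv, dtype=float)
        if defined is None:
            defined = np.isfinite(scores)
        scores = np.where(defined, scores, 0.0)
    if not defined.any():
        raise ValueError("cannot rank: no column has a defined score")
    idx = np.arange(len(scores))
    # lexsort: last key is primary
    order = np.lexsort((idx, ~np.asarray(defined, bool), -scores))
    return SiteRanking(order, np.asarray(scores, dtype=float), source)


# ---------------------------------------------------------------------------
# Tree-dependent per-site rates (JC likelihood on a fixed tree)
# ---------------------------------------------------------------------------

# partial-likelihood row per character code, aligned with alignment_io codes
_PARTIALS = np.zeros((len("ACGT-NRYSWKMBDHV"), 4))
for _i, _ch in enumerate("ACGT-NRYSWKMBDHV"):
    for _b in IUPAC_SETS[_ch]:
        _PARTIALS[_i, "ACGT".index(_b)] = 1.0


def _postorder_edges(tree, taxon_to_row: Mapping[str, int]):
    """Flatten a dendropy tree into (node_id, parent_partial-slot) structure.

    Returns (nodes, leaf_rows) where nodes is a postorder list of
    (child_slot_list_with_lengths, own_slot) and leaf slots map to rows.
    """
    nodes = list(tree.postorder_node_iter())
    slot = {id(n): i for i, n in enumerate(nodes)}
    plan = []
    leaf_rows = {}
    for n in nodes:
        if n.is_leaf():
            label = n.taxon.label if n.taxon is not None else n.label
            if label not in taxon_to_row:
                raise ValueError(f"tree leaf {label!r} not in alignment")
            leaf_rows[slot[id(n)]] = taxon_to_row[label]
        else:
            children = []
            for c in n.child_nodes():
                b = c.edge.length
                if b is None:
                    b = 0.0
                if b < 0:
                    raise ValueError("negative branch length in rate tree")
                children.append((slot[id(c)], float(b)))
            plan.append((slot[id(n)], children))
    return plan, leaf_rows, len(nodes)


def _column_loglik(r, col_partials, plan, leaf_rows, n_slots):
    """log-likelihood of one column under JC with branch lengths scaled by r."""
    partials = np.empty((n_slots, 4))
    for s, row in leaf_rows.items():
        partials[s] = col_partials[row]
    log_scale = 0.0
    for s, children in plan:
        acc = np.ones(4)
        for cs, b in children:
            e = np.exp(-4.0 / 3.0 * b * r)
            x = partials[cs]
            tot = x.sum()
            # JC: sum_t P_st x_t = 0.25 (1-e) sum(x) + e x_s
            acc = acc * (0.25 * (1.0 - e) * tot + e * x)
        m = acc.max()
        if m <= 0:
            return -np.inf
        partials[s] = acc / m
        log_scale += np.log(m)
    root = partials[plan[-1][0]] if plan else partials[0]
    return float(np.log(0.25 * root.sum()) + log_scale)


def tree_dependent_rates(
    aln: Alignment,
    tree,
    r_min: float = 1e-4,
    r_max: float = 64.0,
    tol: float = 1e-6,
) -> np.ndarray:
    """Per-column ML rate multipliers on a fixed tree (JC model).

    Returns an array of length ``n_cols``; columns with at most one
    determinate leaf get ``nan`` (rate undefined).  The optimum of the
    bounded one-dimensional likelihood in r is found by Brent search on
    [r_min, r_max].
    """
    taxon_to_row = {t: i for i, t in enumerate(aln.taxa)}
    plan, leaf_rows, n_slots = _postorder_edges(tree, taxon_to_row)
    col_partials_all = _PARTIALS[aln.codes]  # (n_taxa, n_cols, 4)
    det_leaves = (aln.codes[[leaf_rows[s] for s in leaf_rows]] < N_DETERMINATE).sum(axis=0)
    rates = np.full(aln.n_cols, np.nan)
    # coarse log-grid pre-search brackets the global optimum before the
    # bounded Brent refinement (the column likelihood in r need not be
    # unimodal once several branch lengths interact)
    coarse = np.logspace(np.log10(r_min), np.log10(r_max), 40)
    for c in range(aln.n_cols):
        if det_leaves[c] <= 1:
            continue
        col = col_partials_all[:, c, :]

        def nll(r):
            return -_column_loglik(r, col, plan, leaf_rows, n_slots)

        vals = [nll(r) for r in coarse]
        best = int(np.argmin(vals))
        lo = coarse[max(best - 1, 0)]
        hi = coarse[min(best + 1, len(coarse) - 1)]
        res = minimize_scalar(
            nll, bounds=(lo, hi), method="bounded", options={"xatol": tol}
        )
        rates[c] = float(res.x) if res.fun <= vals[best] else float(coarse[best])
    return rates


# ---------------------------------------------------------------------------
# Category summaries (per-region OV averages, ANOVA + Tukey HSD letters)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategorySummary:
    """Per-category mean/SD/n of per-site scores with significance letters.

    ``table`` has one row per group (categories, plus optional exon
    recomputations excluding named loci) with columns mean, sd, n, letters.
    Groups sharing no letter differ at alpha = 0.05 by Tukey's HSD following
    a one-way ANOVA.
    """

    table: pd.DataFrame
    anova_p: float
    alpha: float = 0.05


def _significance_letters(names, means, pairwise_ns: np.ndarray) -> dict[str, str]:
    """Compact letter display: one letter per maximal clique of the
    'not significantly different' graph; a group's letters are the cliques
    containing it."""
    g = nx.Graph()
    g.add_nodes_from(range(len(names)))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if pairwise_ns[i, j]:
                g.add_edge(i, j)
    cliques = list(nx.find_cliques(g))
    # order cliques by the best (highest) mean they contain, for stable letters
    cliques.sort(key=lambda cl: (-max(means[i] for i in cl), sorted(cl)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {i: "" for i in range(len(names))}
    for li, cl in enumerate(cliques):
        for i in cl:
            letters[i] += alphabet[li % len(alphabet)]
    return {names[i]: "".join(sorted(letters[i])) for i in range(len(names))}


def category_summary(
    sv: SiteVariability | np.ndarray,
    ann: ColumnAnnotation,
    exclude_loci: Sequence[str] = (),
    alpha: float = 0.05,
) -> CategorySummary:
    """Per-category mean per-site score, ANOVA across categories, Tukey letters.

    All columns contribute (zero-score columns included).  If
    ``exclude_loci`` is given, extra exon groups are added that drop the
    named loci cumulatively (e.g. ycf1, then ycf1+ycf2), mirroring how
    hyper-variable loci are commonly quarantined before region comparisons.
    Empty categories are omitted.
    """
    scores = sv.ov if isinstance(sv, SiteVariability) else np.asarray(sv, float)
    if len(scores) != ann.n_cols:
        raise ValueError("annotation does not cover the alignment")
    groups: list[tuple[str, np.ndarray]] = []
    for cat in ("noncoding", "exon", "intron", "tRNA", "rRNA"):
        sel = ann.categories == cat
        if sel.any():
            groups.append((cat, scores[sel]))
    dropped: list[str] = []
    for locus in exclude_loci:
        dropped.append(locus)
        sel = (ann.categories == "exon") & ~np.isin(ann.loci, dropped)
        if sel.any():
            groups.append((f"exon_without_{'_'.join(dropped)}", scores[sel]))
    if len(groups) < 2:
        raise ValueError("need at least two non-empty categories")
    names = [n for n, _ in groups]
    values = [v for _, v in groups]
    means = np.array([float(v.mean()) for v in values])
    # ANOVA and Tukey need >= 2 observations per group; singletons are
    # reported (mean only) but sit outside the significance comparison
    testable = [i for i, v in enumerate(values) if len(v) >= 2]
    letters = {n: "" for n in names}
    anova_p = float("nan")
    if len(testable) >= 2:
        tvals = [values[i] for i in testable]
        anova_p = float(stats.f_oneway(*tvals).pvalue)
        hsd = stats.tukey_hsd(*tvals)
        ns = hsd.pvalue >= alpha  # not significantly different
        sub = _significance_letters(
            [names[i] for i in testable], means[testable], ns
        )
        letters.update(sub)
    table = pd.DataFrame(
        {
            "mean": means,
            "sd": [float(v.std(ddof=1)) if len(v) > 1 else 0.0 for v in values],
            "n": [len(v) for v in values],
            "letters": [letters[n] for n in names],
        },
        index=pd.Index(names, name="category"),
    )
    return CategorySummary(table, anova_p, alpha)


def ov_report(sv: SiteVariability, rates: np.ndarray | None = None) -> str:
    """Tab-separated per-site table: column (1-based), OV, k, optional rate."""
    lines = ["column\tov\tk" + ("\trate" if rates is not None else "")]
    for c in range(sv.n_cols):
        row = f"{c + 1}\t{sv.ov[c]:.6g}\t{sv.k[c]}"
        if rates is not None:
            row += f"\t{rates[c]:.6g}"
        lines.append(row)
    return "\n".join(lines) + "\n"
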