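"""Tree comparison and clade-placement classification on split (bipartition) sets.

Trees are compared unrooted through their non-trivial bipartitions.  Each
split is canonicalized as the frozenset of leaf labels on the side *not*
containing a fixed reference taxon (the lexicographically smallest label),
so two independently parsed trees over the same leaf set are directly
comparable.

Metrics follow the treedist conventions: the partition (Robinson–Foulds)
metric is the size of the symmetric difference of the two split sets, and
the branch score is the sum over the union of splits of squared
branch-length differences, a split absent from one tree contributing its
length in the other squared (no square root taken).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import dendropy
import numpy as np

__all__ = [
    "SplitTable",
    "CladeQuery",
    "PlacementResult",
    "iter_splits",
    "split_table",
    "rf_distance",
    "branch_score",
    "support_summary",
    "clade_placement",
]


def _leaf_labels(tree: dendropy.Tree) -> frozenset:
    return frozenset(
        (lf.taxon.label if lf.taxon is not None else lf.label)
        for lf in tree.leaf_node_iter()
    )


def iter_splits(
    tree: dendropy.Tree,
) -> Iterator[tuple[frozenset, float | None, dendropy.Node]]:
    """Yield (canonical split, branch length, node) for non-trivial splits.

    The canonical form of a split is the leaf-label side not containing the
    reference taxon (smallest leaf label in the tree).  A degree-2 root
    yields the same split from both child edges; consumers that need a
    set/dict view should go through :func:`split_table`, which merges them.
    """
    all_leaves = _leaf_labels(tree)
    if len(all_leaves) < 4:
        return
    ref = min(all_leaves)
    below: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset(
                [node.taxon.label if node.taxon is not None else node.label]
            )
        else:
            acc: frozenset = frozenset()
            for c in node.child_nodes():
                acc = acc | below[id(c)]
            below[id(node)] = acc
            if node.parent_node is None:
                continue  # seed node: no subtending edge
            side = acc
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue
            if ref in side:
                side = all_leaves - side
            yield frozenset(side), node.edge.length, node


@dataclass
class SplitTable:
    """Deduplicated view of a tree's non-trivial splits.

    ``lengths`` maps split -> branch length (summed over the two halves of a
    degree-2 root edge; None if any contributing edge lacks a length);
    ``supports`` maps split -> support in [0, 100] or None.
    """

    leaves: frozenset
    lengths: dict = field(default_factory=dict)
    supports: dict = field(default_factory=dict)

    @property
    def splits(self) -> frozenset:
        return frozenset(self.lengths)


def _node_support(node: dendropy.Node) -> float | None:
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def split_table(tree: dendropy.Tree) -> SplitTable:
    table = SplitTable(_leaf_labels(tree))
    for split, length, node in iter_splits(tree):
        sup = _node_support(node)
        if split in table.lengths:
            prev = table.lengths[split]
            table.lengths[split] = (
                None if (prev is None or length is None) else prev + length
            )
            prev_sup = table.supports[split]
            if sup is not None:
                table.supports[split] = sup if prev_sup is None else max(prev_sup, sup)
        else:
            table.lengths[split] = length
            table.supports[split] = sup
    return table


def _common_tables(t1, t2, prune: bool):
    s1, s2 = split_table(t1), split_table(t2)
    if s1.leaves != s2.leaves:
        if not prune:
            only1 = sorted(s1.leaves - s2.leaves)[:5]
            only2 = sorted(s2.leaves - s1.leaves)[:5]
            raise ValueError(
                f"leaf sets differ (e.g. {only1} vs {only2}); "
                "pass prune=True to compare on the intersection"
            )
        common = s1.leaves & s2.leaves
        if len(common) < 4:
            raise ValueError("fewer than 4 shared leaves after pruning")
        c1, c2 = t1.clone(depth=1), t2.clone(depth=1)
        c1.retain_taxa_with_labels(common)
        c2.retain_taxa_with_labels(common)
        s1, s2 = split_table(c1), split_table(c2)
    return s1, s2


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree, prune: bool = False) -> int:
    """Partition metric: splits present in exactly one of the two trees."""
    s1, s2 = _common_tables(t1, t2, prune)
    return len(s1.splits ^ s2.splits)


def branch_score(t1: dendropy.Tree, t2: dendropy.Tree, prune: bool = False) -> float:
    """Branch score: sum of squared length differences over the split union."""
    s1, s2 = _common_tables(t1, t2, prune)
    total = 0.0
    for split in s1.splits | s2.splits:
        l1 = s1.lengths.get(split, 0.0)
        l2 = s2.lengths.get(split, 0.0)
        if l1 is None or l2 is None:
            raise ValueError(f"missing branch length on split {sorted(split)[:4]}...")
        total += (l1 - l2) ** 2
    return total


@dataclass(frozen=True)
class SupportSummary:
    median: float
    mean: float
    sd: float
    values: tuple[float, ...]


def support_summary(tree: dendropy.Tree) -> SupportSummary:
    """Summary of internal-edge support values (non-trivial splits only)."""
    table = split_table(tree)
    vals = [s for s in table.supports.values() if s is not None]
    if not vals:
        raise ValueError("tree has no internal-edge support values")
    arr = np.asarray(vals, dtype=float)
    return SupportSummary(
        float(np.median(arr)),
        float(arr.mean()),
        float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        tuple(sorted(arr)),
    )


# ---------------------------------------------------------------------------
# Clade placement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CladeQuery:
    """A focal clade and its named candidate sister groups.

    ``outgroup`` supplies the rooting context: the sister group of the focal
    clade is read off the tree rooted away from the outgroup taxa.  Focal
    and alternative sets must be disjoint.
    """

    name: str
    focal: frozenset
    alternatives: Mapping[str, frozenset]
    outgroup: frozenset

    def __post_init__(self):
        for alt_name, alt in self.alternatives.items():
            if self.focal & frozenset(alt):
                raise ValueError(f"alternative {alt_name!r} overlaps the focal set")


@dataclass(frozen=True)
class PlacementResult:
    monophyly: bool
    monophyly_support: float
    placement_label: str          # matched alternative name, or "other"
    ancestral_support: float      # support of smallest clade containing focal+sister
    sister: frozenset = frozenset()
    alternative_supports: Mapping[str, float] = field(default_factory=dict)


def clade_placement(tree: dendropy.Tree, query: CladeQuery) -> PlacementResult:
    """Classify where the focal clade sits relative to the named alternatives.

    Works on the split set: for each split, the 'clade side' is the side
    disjoint from the outgroup taxa; the focal clade's sister is the smallest
    clade side strictly containing the focal set, minus the focal set.
    ``alternative_supports`` reports, for every named alternative, the
    support of the clade (focal ∪ alternative) if that exact clade is in the
    tree, else 0 — the per-step quantity a placement trajectory tracks.
    """
    leaves = _leaf_labels(tree)
    focal = frozenset(query.focal)
    if not focal <= leaves:
        raise ValueError(f"focal taxa missing from tree: {sorted(focal - leaves)}")
    table = split_table(tree)

    def _support(split_key) -> float:
        s = table.supports.get(split_key)
        return 0.0 if s is None else float(s)

    # clade-side view: sides disjoint from the outgroup
    clades: dict[frozenset, float] = {}
    for split in table.splits:
        for side in (split, leaves - split):
            if side and not (side & query.outgroup):
                clades[frozenset(side)] = _support(split)
    # the whole ingroup is trivially a clade when a single outgroup taxon
    # roots the tree (the split is trivial, hence in every replicate)
    ingroup = frozenset(leaves - query.outgroup)
    if len(query.outgroup) == 1 and len(ingroup) >= 2 and ingroup not in clades:
        clades[ingroup] = 100.0

    # monophyly of the focal set
    if len(focal) == 1:
        monophyly, mono_support = True, 100.0
    elif focal in clades:
        monophyly, mono_support = True, clades[focal]
    elif len(focal) == len(leaves - query.outgroup) and len(focal) >= 2:
        # focal = entire ingroup: monophyletic iff outgroup side is a clade
        key = frozenset(leaves - focal)
        monophyly = focal in {frozenset(leaves - s) for s in table.splits} or focal in clades
        mono_support = clades.get(focal, 0.0)
    else:
        monophyly, mono_support = False, 0.0

    alt_supports = {
        name: clades.get(focal | frozenset(alt), 0.0)
        for name, alt in query.alternatives.items()
    }

    if not monophyly:
        return PlacementResult(False, 0.0, "other", 0.0, frozenset(), alt_supports)

    containing = [c for c in clades if focal < c]
    if not containing:
        return PlacementResult(monophyly, mono_support, "other", 0.0, frozenset(), alt_supports)
    smallest = min(containing, key=lambda c: (len(c), sorted(c)))
    sister = smallest - focal
    label = "other"
    for name, alt in query.alternatives.items():
        if sister == frozenset(alt):
            label = name
            break
    return PlacementResult(
        monophyly, mono_support, label, clades[smallest], sister, alt_supports
    )
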