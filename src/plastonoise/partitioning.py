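"""Complementary site-removal series (A_n/B_n) and long-branch taxon exclusion.

Given a ranking of columns by variability, the series removes the top
``step, 2*step, ...`` ranked sites.  At each step the retained partition
A_n holds every column except the removed top-m, and the complementary
partition B_n holds exactly those m columns; ``n`` in the label is the size
of the retained partition, and B is subscripted by the size of the
corresponding A partition.

Taxon exclusion composes orthogonally with site removal: an exclusion
scheme restricts the alignment to a kept taxon set (columns untouched), so
divergent lineages can be dropped before inference.  Schemes are data-driven
from named taxon groups rather than any fixed taxonomy.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment_io import Alignment
from .site_variability import SiteRanking

__all__ = [
    "PartitionStep",
    "PartitionSeries",
    "ExclusionScheme",
    "build_series",
    "apply_exclusion",
    "long_branch_report",
]


@dataclass(frozen=True)
class PartitionStep:
    removed: int          # m, number of top-ranked sites removed
    label: str            # "A_{n_cols - m}"
    a_cols: np.ndarray    # retained column indices, ascending
    b_cols: np.ndarray    # removed column indices, ascending

    @property
    def a_size(self) -> int:
        return len(self.a_cols)


@dataclass(frozen=True)
class PartitionSeries:
    n_cols: int
    step: int
    steps: tuple[PartitionStep, ...]

    def __iter__(self):
        return iter(self.steps)

    def __len__(self):
        return len(self.steps)


def build_series(
    ranking: SiteRanking,
    n_cols: int,
    step: int = 100,
    max_removed: int = 20000,
) -> PartitionSeries:
    """Build the A/B series removing ``step, 2*step, ... , max_removed`` sites."""
    if step < 1:
        raise ValueError("step must be >= 1")
    n_ranked = len(ranking.order)
    if max_removed > n_ranked:
        raise ValueError(
            f"max_removed ({max_removed}) exceeds ranked columns ({n_ranked})"
        )
    all_cols = np.arange(n_cols)
    steps = []
    for m in range(step, max_removed + 1, step):
        b = np.sort(ranking.top(m))
        mask = np.ones(n_cols, dtype=bool)
        mask[b] = False
        a = all_cols[mask]
        steps.append(PartitionStep(m, f"A_{n_cols - m}", a, b))
    return PartitionSeries(n_cols, step, tuple(steps))


@dataclass(frozen=True)
class ExclusionScheme:
    """A named long-branch exclusion strategy over taxon groups.

    ``keep`` (if given) wins over ``drop``; ``outgroup`` designates the
    single retained outgroup taxon for the most exclusive strategy.  The
    canonical strategies are: ``none`` (identity), ``no_outgroups`` (drop
    the outgroup clade), ``subgroup_only`` (keep one subgenus), and
    ``section_plus_single_outgroup`` (keep one section plus one sister-section
    member as outgroup).
    """

    name: str
    keep: frozenset = frozenset()
    drop: frozenset = frozenset()
    outgroup: str | None = None

    @classmethod
    def none(cls) -> "ExclusionScheme":
        return cls("none")

    @classmethod
    def no_outgroups(cls, outgroups: Sequence[str]) -> "ExclusionScheme":
        return cls("no_outgroups", drop=frozenset(outgroups))

    @classmethod
    def subgroup_only(cls, subgroup: Sequence[str]) -> "ExclusionScheme":
        return cls("subgroup_only", keep=frozenset(subgroup))

    @classmethod
    def section_plus_single_outgroup(
        cls, section: Sequence[str], outgroup: str
    ) -> "ExclusionScheme":
        return cls(
            "section_plus_single_outgroup",
            keep=frozenset(section) | {outgroup},
            outgroup=outgroup,
        )


def apply_exclusion(aln: Alignment, scheme: ExclusionScheme) -> Alignment:
    """Restrict the alignment to the scheme's kept taxa (columns unchanged)."""
    named = (scheme.keep | scheme.drop) | (
        {scheme.outgroup} if scheme.outgroup else set()
    )
    unknown = named - set(aln.taxa)
    if unknown:
        hints = {
            t: difflib.get_close_matches(t, aln.taxa, n=2) for t in sorted(unknown)
        }
        raise ValueError(f"unknown taxa in scheme {scheme.name!r}: {hints}")
    if scheme.keep:
        kept = [t for t in aln.taxa if t in scheme.keep]
    else:
        kept = [t for t in aln.taxa if t not in scheme.drop]
    if len(kept) < 4:
        raise ValueError(
            f"scheme {scheme.name!r} keeps only {len(kept)} taxa; "
            "at least 4 are needed for an informative unrooted tree"
        )
    if len(kept) == aln.n_taxa:
        return aln
    return aln.select_taxa(kept)


def long_branch_report(
    tree,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Rank leaves (and optional groups) by stem length and root-to-tip length.

    Per-leaf rows carry the terminal branch length (stem) and the path
    length from the tree's root/seed node.  When ``groups`` is supplied,
    one row per group is appended with the group MRCA's stem length and the
    mean root-to-tip length over members.  Sorted by stem length descending.
    """
    rows = []
    depths = {}
    for node in tree.preorder_node_iter():
        b = node.edge.length
        if node.parent_node is not None and b is None:
            raise ValueError("tree has missing branch lengths")
        parent_depth = depths.get(id(node.parent_node), 0.0)
        depths[id(node)] = parent_depth + (b or 0.0)
        if node.is_leaf():
            rows.append(
                {
                    "name": node.taxon.label if node.taxon else node.label,
                    "kind": "leaf",
                    "stem_length": float(b or 0.0),
                    "root_to_tip": float(depths[id(node)]),
                }
            )
    if groups:
        leaf_rows = {r["name"]: r for r in rows}
        # leaf-label sets per node; smallest superset of a group is its MRCA
        # (computed locally: dendropy's mrca() restructures unrooted trees)
        below: dict[int, frozenset] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                below[id(node)] = frozenset([node.taxon.label if node.taxon else node.label])
            else:
                acc = frozenset()
                for c in node.child_nodes():
                    acc = acc | below[id(c)]
                below[id(node)] = acc
        node_by_id = {id(n): n for n in tree.preorder_node_iter()}
        for gname, members in groups.items():
            want = frozenset(members)
            candidates = [nid for nid, s in below.items() if want <= s]
            mrca = node_by_id[min(candidates, key=lambda nid: len(below[nid]))]
            stem = mrca.edge.length if mrca.parent_node is not None else 0.0
            rtt = float(np.mean([leaf_rows[m]["root_to_tip"] for m in members]))
            rows.append(
                {
                    "name": gname,
                    "kind": "group",
                    "stem_length": float(stem or 0.0),
                    "root_to_tip": rtt,
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["stem_length", "root_to_tip"], ascending=False, kind="stable"
    ).reset_index(drop=True)
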