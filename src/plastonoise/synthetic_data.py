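"""Synthetic alignments with planted noise for exercising the whole pipeline.

The generator emulates the statistical structure a site-stripping analysis
assumes about a concatenated organellar alignment: most columns evolve on a
single true tree under Jukes–Cantor with gamma-distributed rate variation
structured by functional category (noncoding faster than coding, RNA genes
slowest), while a small planted fraction of fast columns evolves on a
*conflicting* topology — the minimal mechanism by which highly variable
sites carry misleading signal.  Gap and masked-base cells, and optional
fully indeterminate columns, reproduce the bookkeeping hazards of real
assemblies.  Everything is reproducible from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import dendropy
import numpy as np
from scipy import stats

from .alignment_io import Alignment, ColumnAnnotation, GAP_CODE, MASK_CODE
from .tree_metrics import CladeQuery

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_alignment",
    "planted_conflict_scenario",
    "scenario_clade_query",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings; defaults document the neutral choices.

    Category rate multipliers mirror the empirical ordering of plastome
    region variability (noncoding > exon > intron > tRNA ≈ rRNA).
    ``conflict_fraction`` of columns evolve on ``conflict_tree`` with their
    rate further multiplied by ``conflict_rate_multiplier``.
    """

    true_tree: str                    # newick with branch lengths
    conflict_tree: str | None = None  # same leaf set; None disables conflict
    n_cols: int = 5000
    conflict_fraction: float = 0.0
    gamma_shape: float = 0.8
    n_rate_categories: int = 8
    category_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "noncoding": 0.35, "exon": 0.40, "intron": 0.10,
            "tRNA": 0.075, "rRNA": 0.075,
        }
    )
    category_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "noncoding": 3.0, "exon": 1.0, "intron": 0.8,
            "tRNA": 0.3, "rRNA": 0.3,
        }
    )
    conflict_rate_multiplier: float = 8.0
    gap_prob: float = 0.01
    mask_prob: float = 0.01
    conflict_indeterminate_prob: float = 0.0  # extra gap/mask rate on planted columns
    # "junk" columns emulate assembly-artifact positions where most taxa are
    # gaps or masked bases and the few called ones are effectively random
    # (ultra-fast); real gappy alignments are dominated by such columns at
    # the top of any variability ranking
    junk_fraction: float = 0.0
    junk_rate_multiplier: float = 30.0
    junk_indeterminate_prob: float = 0.8
    n_indeterminate_cols: int = 0     # whole columns forced to gaps/masks
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.conflict_fraction < 1.0:
            raise ValueError("conflict_fraction must be in [0, 1)")
        for p in (self.gap_prob, self.mask_prob):
            if not 0.0 <= p < 1.0:
                raise ValueError("gap/mask probabilities must be in [0, 1)")
        if any(r <= 0 for r in self.category_rates.values()):
            raise ValueError("category rate multipliers must be > 0")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth per column: generating tree, rate and category."""

    true_topology: str
    generating_tree: np.ndarray      # "true" | "conflict" per column
    rates: np.ndarray                # total rate multiplier per column
    categories: np.ndarray
    conflict_indices: np.ndarray     # planted conflict columns, ascending
    indeterminate_indices: np.ndarray
    junk_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def planted_indices(self) -> np.ndarray:
        """All planted noise columns (conflict history + junk)."""
        return np.union1d(self.conflict_indices, self.junk_indices)


def _discrete_gamma_rates(shape: float, ncat: int) -> np.ndarray:
    """Mean rate of each equal-probability category of a mean-1 gamma."""
    if ncat == 1:
        return np.ones(1)
    d = stats.gamma(a=shape, scale=1.0 / shape)
    bounds = d.ppf(np.linspace(0, 1, ncat + 1))
    d2 = stats.gamma(a=shape + 1.0, scale=1.0 / shape)
    mass = d2.cdf(bounds)
    return ncat * np.diff(mass)


def _simulate_on_tree(tree: dendropy.Tree, rates: np.ndarray, rng) -> dict[str, np.ndarray]:
    """JC simulation of len(rates) sites down a tree; returns leaf states."""
    n = len(rates)
    states: dict[int, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[id(node)] = rng.integers(0, 4, size=n, dtype=np.uint8)
        else:
            b = node.edge.length or 0.0
            parent = states[id(node.parent_node)]
            p_change = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * b * rates))
            hit = rng.random(n) < p_change
            child = parent.copy()
            if hit.any():
                shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
                child[hit] = (child[hit] + shift) % 4
            states[id(node)] = child
        if node.is_leaf():
            out[node.taxon.label if node.taxon else node.label] = states[id(node)]
    return out


def simulate_alignment(cfg: SimConfig):
    """Generate (Alignment, ColumnAnnotation, SimTruth) from a SimConfig."""
    true_tree = dendropy.Tree.get(data=cfg.true_tree, schema="newick")
    leaf_labels = sorted(
        lf.taxon.label for lf in true_tree.leaf_node_iter()
    )
    conflict_tree = None
    if cfg.conflict_tree is not None:
        conflict_tree = dendropy.Tree.get(data=cfg.conflict_tree, schema="newick")
        conflict_leaves = sorted(lf.taxon.label for lf in conflict_tree.leaf_node_iter())
        if conflict_leaves != leaf_labels:
            raise ValueError("true and conflict trees have different leaf sets")

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cols

    cats = list(cfg.category_fractions)
    probs = np.asarray([cfg.category_fractions[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    categories = np.asarray(cats, dtype=object)[rng.choice(len(cats), size=n, p=probs)]

    gamma_cat_rates = _discrete_gamma_rates(cfg.gamma_shape, cfg.n_rate_categories)
    gamma_rates = gamma_cat_rates[rng.integers(0, cfg.n_rate_categories, size=n)]
    cat_mult = np.asarray([cfg.category_rates[c] for c in categories], dtype=float)
    rates = gamma_rates * cat_mult

    n_conflict = int(round(cfg.conflict_fraction * n))
    if n_conflict and conflict_tree is None:
        raise ValueError("conflict_fraction > 0 requires a conflict tree")
    n_junk = int(round(cfg.junk_fraction * n))
    noise_idx = (
        rng.choice(n, size=n_conflict + n_junk, replace=False)
        if n_conflict + n_junk
        else np.empty(0, dtype=np.int64)
    )
    conflict_idx = np.sort(noise_idx[:n_conflict]).astype(np.int64)
    junk_idx = np.sort(noise_idx[n_conflict:]).astype(np.int64)
    generating = np.full(n, "true", dtype=object)
    generating[conflict_idx] = "conflict"
    rates = rates.copy()
    rates[conflict_idx] *= cfg.conflict_rate_multiplier
    rates[junk_idx] *= cfg.junk_rate_multiplier

    is_conflict = np.zeros(n, dtype=bool)
    is_conflict[conflict_idx] = True
    matrix = np.empty((len(leaf_labels), n), dtype=np.uint8)
    row = {t: i for i, t in enumerate(leaf_labels)}
    true_cols = np.flatnonzero(~is_conflict)
    leaf_states = _simulate_on_tree(true_tree, rates[true_cols], rng)
    for t, s in leaf_states.items():
        matrix[row[t], true_cols] = s
    if n_conflict:
        leaf_states = _simulate_on_tree(conflict_tree, rates[conflict_idx], rng)
        for t, s in leaf_states.items():
            matrix[row[t], conflict_idx] = s

    # indeterminate cells: gaps first, then masks on the remainder
    for idx, prob in (
        (conflict_idx, cfg.conflict_indeterminate_prob),
        (junk_idx, cfg.junk_indeterminate_prob),
    ):
        if prob > 0 and len(idx):
            # the noisiest columns in real assemblies are also the gappiest;
            # enrich planted columns with indeterminate cells
            sub = matrix[:, idx]
            hit = rng.random(sub.shape) < prob
            fill = rng.random(sub.shape) < 0.5
            sub[hit] = np.where(fill, GAP_CODE, MASK_CODE).astype(np.uint8)[hit]
            matrix[:, idx] = sub
    if cfg.gap_prob > 0:
        matrix[rng.random(matrix.shape) < cfg.gap_prob] = GAP_CODE
    if cfg.mask_prob > 0:
        hit = (rng.random(matrix.shape) < cfg.mask_prob) & (matrix != GAP_CODE)
        matrix[hit] = MASK_CODE

    if cfg.n_indeterminate_cols:
        ind_idx = np.sort(
            rng.choice(n, size=cfg.n_indeterminate_cols, replace=False)
        )
        fill = rng.random((len(leaf_labels), cfg.n_indeterminate_cols)) < 0.5
        matrix[:, ind_idx] = np.where(fill, GAP_CODE, MASK_CODE).astype(np.uint8)
    else:
        ind_idx = np.empty(0, dtype=np.int64)

    aln = Alignment(tuple(leaf_labels), matrix)
    ann = ColumnAnnotation(categories, np.full(n, "", dtype=object))
    truth = SimTruth(
        cfg.true_tree, generating, rates, categories, conflict_idx, ind_idx, junk_idx
    )
    return aln, ann, truth


# ---------------------------------------------------------------------------
# Planted-conflict preset
# ---------------------------------------------------------------------------


def _caterpillar(labels, tip_len, internal_len):
    """Binary ladder subtree over labels, as a newick fragment without stem."""
    if len(labels) == 1:
        return f"{labels[0]}:{tip_len:.6g}"
    inner = f"({labels[-2]}:{tip_len:.6g},{labels[-1]}:{tip_len:.6g})"
    for lab in reversed(labels[:-2]):
        inner = f"({lab}:{tip_len:.6g},{inner}:{internal_len:.6g})"
    return inner


def _scenario_groups(n_taxa: int):
    """Taxon groups for the conflict scenario: X and Y pairs, Z/W the rest."""
    if n_taxa < 8:
        raise ValueError("planted-conflict scenario needs at least 8 taxa")
    rest = n_taxa - 7  # minus FOC, X1..2, Y1..2, OUT1..2
    nz = min(2, rest)
    nw = rest - nz
    x = ["X1", "X2"]
    y = ["Y1", "Y2"]
    z = [f"Z{i + 1}" for i in range(nz)]
    w = [f"W{i + 1}" for i in range(nw)]
    return x, y, z, w


def planted_conflict_scenario(
    n_taxa: int = 12, seed: int = 0, n_cols: int = 5000
) -> SimConfig:
    """Preset emulating a plastome-like alignment with planted noise.

    The focal taxon FOC is sister to group X on the true tree, attached by a
    short internal edge (weak true signal), while two planted noise classes
    mimic what dominates the top of a real variability ranking:

    * ~5% *conflict* columns evolve on a tree that places FOC sister to
      group Y, at 16x the base rate on branches 4.5x longer — fast sites
      whose alternative history is largely scrambled by saturation but
      which carry misleading distance signal into every partition that
      contains them;
    * ~5% *junk* columns are ultra-fast and 75% gap/masked — the
      assembly-artifact positions that make the smallest stripped-site
      partitions wildly unstable.

    Expected scan behavior (the point of the preset): the tree distance
    between retained (A) and removed (B) partitions starts very high while
    B is noise-dominated, collapses once the planted sites are diluted by
    genuinely informative fast sites, and the A-tree holds full support
    until far into the stripping series, so the detected window brackets
    the steps where the focal placement is recovered at maximal support
    and the A/B topologies coincide.
    """
    x, y, z, w = _scenario_groups(n_taxa)
    tip, stem, backbone, foc_edge = 0.030, 0.036, 0.024, 0.015
    og_tip, og_stem, w_int = 0.045, 0.090, 0.018
    cs = 4.5  # conflict-tree ingroup branch scale
    c_foc_edge, c_og_tip, c_og_stem = 0.18, 0.036, 0.036

    def pair(a, b, tl, sl):
        return f"({a}:{tl:.6g},{b}:{tl:.6g}):{sl:.6g}"

    def wclade(tl, sl, il):
        frag = _caterpillar(w, tl, il) if len(w) > 1 else f"{w[0]}:{tl:.6g}"
        return f"{frag}:{sl:.6g}" if len(w) > 1 else frag

    def zw(tl, sl, il):
        zc = pair(z[0], z[1], tl, sl) if len(z) > 1 else f"{z[0]}:{tl:.6g}"
        if w:
            return f"({zc},{wclade(tl, sl, il)})"
        return f"({zc})"

    true_tree = (
        f"((((FOC:{tip:.6g},{pair(*x, tip, stem)}):{foc_edge:.6g},"
        f"{pair(*y, tip, stem)}):{backbone:.6g},"
        f"{zw(tip, stem, w_int)}:{backbone:.6g}):{backbone:.6g},"
        f"(OUT1:{og_tip:.6g},OUT2:{og_tip:.6g}):{og_stem:.6g});"
    )
    t2, st2, bb2 = tip * cs, stem * cs, backbone * cs
    conflict_tree = (
        f"((({pair(*x, t2, st2)},(FOC:{t2:.6g},"
        f"{pair(*y, t2, st2)}):{c_foc_edge:.6g}):{bb2:.6g},"
        f"{zw(t2, st2, w_int * cs)}:{bb2:.6g}):{bb2:.6g},"
        f"(OUT1:{c_og_tip:.6g},OUT2:{c_og_tip:.6g}):{c_og_stem:.6g});"
    )
    return SimConfig(
        true_tree=true_tree,
        conflict_tree=conflict_tree,
        n_cols=n_cols,
        conflict_fraction=0.05,
        conflict_rate_multiplier=16.0,
        conflict_indeterminate_prob=0.35,
        junk_fraction=0.05,
        junk_rate_multiplier=40.0,
        junk_indeterminate_prob=0.75,
        gamma_shape=1.2,
        n_rate_categories=8,
        category_fractions={
            "noncoding": 0.40, "exon": 0.372, "intron": 0.09,
            "tRNA": 0.069, "rRNA": 0.069,
        },
        category_rates={
            "noncoding": 4.0, "exon": 1.0, "intron": 0.8,
            "tRNA": 0.3, "rRNA": 0.3,
        },
        seed=seed,
    )


def scenario_clade_query(n_taxa: int = 12) -> CladeQuery:
    """The clade query matching :func:`planted_conflict_scenario`."""
    x, y, _z, _w = _scenario_groups(n_taxa)
    return CladeQuery(
        name="FOC_placement",
        focal=frozenset({"FOC"}),
        alternatives={"X": frozenset(x), "Y": frozenset(y)},
        outgroup=frozenset({"OUT1", "OUT2"}),
    )


def scenario_scan_config(seed: int = 0, replicates: int = 100):
    """Scan settings matched to :func:`planted_conflict_scenario` (5000 cols).

    Steps of 100 sites up to 2000 removed span all three regimes the preset
    plants: noise-dominated B partitions, the converged window, and the
    onset of signal erosion in A.
    """
    from .noise_scan import ScanConfig

    return ScanConfig(
        step=100,
        max_removed=2000,
        replicates=replicates,
        seed=seed,
        clade_queries=(scenario_clade_query(),),
        saturation_ceiling=8.0,
    )
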