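"""Distance-based tree inference: p/JC distances, neighbor-joining, bootstrap.

The engine is deliberately distance-based: a noise-removal scan performs
hundreds of tree inferences (one per partition per bootstrap replicate), and
neighbor-joining on Jukes–Cantor distances keeps that tractable at desk
scale while preserving the scan's comparative quantities (support
trajectories, topological convergence).  An adapter contract lets users
substitute any external program that emits Newick (e.g. an ML package) for
the internal builder.

Gap handling follows pairwise deletion ("gaps treated as missing data"):
each pairwise distance is computed only over columns where both sequences
carry a determinate base.  The Jukes–Cantor correction is

    d = -(3/4) * ln(1 - (4/3) p)

and is undefined for p >= 3/4.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .alignment_io import Alignment, N_DETERMINATE, write_alignment

__all__ = [
    "DistanceMatrix",
    "BootstrapResult",
    "ColumnPairData",
    "jc_correct",
    "pairwise_distances",
    "nj_tree",
    "bootstrap_support",
    "external_tree_adapter",
    "read_tree",
    "write_tree",
    "tree_to_newick",
    "write_phylip_matrix",
]


def jc_correct(p):
    """Jukes–Cantor correction; nan where p >= 0.75 (out of the model's range)."""
    p = np.asarray(p, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(p < 0.75, -0.75 * np.log(1.0 - 4.0 * p / 3.0), np.nan)
    return d if d.ndim else float(d)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-pair comparison counts.

    ``undefined`` flags pairs with no compared sites, or (for JC) pairs with
    p >= 0.75; the corresponding ``values`` entries are nan.
    """

    taxa: tuple[str, ...]
    values: np.ndarray       # (n, n) float, nan where undefined
    n_compared: np.ndarray   # (n, n) int
    kind: str                # "p_distance" | "jc_corrected"
    undefined: np.ndarray = field(default=None)  # (n, n) bool

    def __post_init__(self):
        if self.undefined is None:
            object.__setattr__(self, "undefined", np.isnan(self.values))


def _pair_counts(codes: np.ndarray, weights: np.ndarray | None = None):
    """Mismatch and valid-site counts for all i<j pairs (pairwise deletion)."""
    n = codes.shape[0]
    det = codes < N_DETERMINATE
    mism = np.zeros((n, n))
    valid = np.zeros((n, n))
    for i in range(n):
        vi = det[i]
        for j in range(i + 1, n):
            both = vi & det[j]
            diff = both & (codes[i] != codes[j])
            if weights is None:
                nv, nm = both.sum(), diff.sum()
            else:
                nv, nm = weights[both].sum(), weights[diff].sum()
            valid[i, j] = valid[j, i] = nv
            mism[i, j] = mism[j, i] = nm
    return mism, valid


def pairwise_distances(
    aln: Alignment,
    correction: str = "none",
    deletion: str = "pairwise",
) -> DistanceMatrix:
    """p-distances (or JC-corrected) under pairwise or complete deletion."""
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    codes = aln.codes
    if deletion == "complete":
        keep = (codes < N_DETERMINATE).all(axis=0)
        codes = codes[:, keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    mism, valid = _pair_counts(codes)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(valid > 0, mism / np.maximum(valid, 1), np.nan)
    np.fill_diagonal(p, 0.0)
    if correction == "jc":
        values, kind = jc_correct(p), "jc_corrected"
        np.fill_diagonal(values, 0.0)
    elif correction == "none":
        values, kind = p, "p_distance"
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return DistanceMatrix(aln.taxa, values, valid.astype(np.int64), kind)


class ColumnPairData:
    """Precomputed per-pair column indicators for fast reweighted distances.

    Stores, for every unordered taxon pair, boolean mismatch and validity
    vectors over columns.  Distances under any non-negative column weight
    vector (e.g. bootstrap resampling counts, or a 0/1 partition indicator)
    are then two matrix products.
    """

    def __init__(self, aln: Alignment):
        self.taxa = aln.taxa
        n = aln.n_taxa
        det = aln.codes < N_DETERMINATE
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        self.pairs = pairs
        self.valid = np.empty((len(pairs), aln.n_cols), dtype=np.float64)
        self.mism = np.empty_like(self.valid)
        for k, (i, j) in enumerate(pairs):
            both = det[i] & det[j]
            self.valid[k] = both
            self.mism[k] = both & (aln.codes[i] != aln.codes[j])

    def distances(
        self,
        weights: np.ndarray,
        correction: str = "jc",
        saturation_ceiling: float | None = None,
    ) -> DistanceMatrix:
        """Distances under a column weight vector.

        ``saturation_ceiling`` (JC only) maps pairs whose p-distance is
        outside the correctable range (p >= 0.75) to a fixed large distance
        instead of flagging them undefined — the behavior of likelihood
        branch estimates on saturated partitions, where such pairs come out
        as very long branches rather than as missing data.  Pairs with no
        compared sites remain undefined regardless.
        """
        w = np.asarray(weights, dtype=np.float64)
        nv = self.valid @ w
        nm = self.mism @ w
        n = len(self.taxa)
        p = np.zeros((n, n))
        valid = np.zeros((n, n))
        with np.errstate(invalid="ignore", divide="ignore"):
            pv = np.where(nv > 0, nm / np.maximum(nv, 1), np.nan)
        for k, (i, j) in enumerate(self.pairs):
            p[i, j] = p[j, i] = pv[k]
            valid[i, j] = valid[j, i] = nv[k]
        if correction == "jc":
            values = jc_correct(p)
            np.fill_diagonal(values, 0.0)
            if saturation_ceiling is not None:
                saturated = np.isnan(values) & ~np.isnan(p)
                values[saturated] = saturation_ceiling
            kind = "jc_corrected"
        else:
            values, kind = p, "p_distance"
        return DistanceMatrix(self.taxa, values, valid.astype(np.int64), kind)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; returns an unrooted dendropy tree.

    Negative branch-length estimates are clamped to zero with the deficit
    moved to the adjacent branch so the joined pair's distance is preserved.
    Ties in the Q criterion break deterministically on the first (row-major)
    minimal entry.
    """
    if dm.undefined.any():
        bad = np.argwhere(dm.undefined & ~np.eye(len(dm.taxa), dtype=bool))
        pair = (dm.taxa[bad[0][0]], dm.taxa[bad[0][1]]) if len(bad) else None
        raise ValueError(
            f"distance matrix has undefined entries (e.g. {pair}); "
            "impute or remove taxa before tree building"
        )
    n = len(dm.taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    tns = dendropy.TaxonNamespace([dendropy.Taxon(label=t) for t in dm.taxa])
    nodes = []
    for t in tns:
        node = dendropy.Node(taxon=t)
        nodes.append(node)
    D = dm.values.astype(float).copy()

    if n == 2:
        root = dendropy.Node()
        for node, half in zip(nodes, (D[0, 1] / 2, D[0, 1] / 2)):
            root.add_child(node)
            node.edge.length = float(half)
        tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
        tree.is_rooted = False
        return tree

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        if lj < 0:
            lj, li = 0.0, dij
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = float(li)
        parent.add_child(nodes[j])
        nodes[j].edge.length = float(lj)
        # reuse slot i for the new node
        for a in active:
            if a in (i, j):
                continue
            dnew = 0.5 * (D[i, a] + D[j, a] - dij)
            D[i, a] = D[a, i] = max(dnew, 0.0)
        nodes[i] = parent
        active.remove(j)

    # join the last three at a single internal node (three-point formulas)
    i, j, k = active
    center = dendropy.Node()
    lens = {
        i: 0.5 * (D[i, j] + D[i, k] - D[j, k]),
        j: 0.5 * (D[i, j] + D[j, k] - D[i, k]),
        k: 0.5 * (D[i, k] + D[j, k] - D[i, j]),
    }
    for a in (i, j, k):
        center.add_child(nodes[a])
        nodes[a].edge.length = float(max(lens[a], 0.0))
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    tree: dendropy.Tree                  # point-estimate tree with supports
    replicate_trees: list[dendropy.Tree]
    n_dropped: int                       # replicates lost to undefined distances


def bootstrap_support(
    aln: Alignment,
    replicates: int = 100,
    seed: int = 0,
    correction: str = "jc",
    pair_data: ColumnPairData | None = None,
    column_weights: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    keep_replicates: bool = True,
    max_dropped_fraction: float = 0.10,
    saturation_ceiling: float | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap over alignment columns with NJ trees.

    Columns are resampled with replacement per replicate; the support of
    each internal edge of the point-estimate tree is the percentage of
    replicate trees containing its bipartition.  ``column_weights`` (0/1)
    restricts the analysis to a sub-partition without copying the alignment.
    Replicates whose distance matrix has an undefined entry are dropped and
    counted; more than ``max_dropped_fraction`` dropped is an error.
    """
    from .tree_metrics import iter_splits  # local import, avoids cycle

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    pd_ = pair_data if pair_data is not None else ColumnPairData(aln)
    n_cols_total = pd_.mism.shape[1]
    if column_weights is None:
        column_weights = np.ones(n_cols_total)
    col_idx = np.flatnonzero(column_weights)
    n_cols = len(col_idx)
    if n_cols == 0:
        raise ValueError("empty partition")

    point_dm = pd_.distances(column_weights, correction, saturation_ceiling)
    if point_dm.undefined.any():
        raise ValueError("undefined distances in point estimate for this partition")
    point_tree = nj_tree(point_dm)

    counts: dict[frozenset, int] = {}
    reps: list[dendropy.Tree] = []
    dropped = 0
    for _ in range(replicates):
        sampled = rng.integers(0, n_cols, size=n_cols)
        w = np.bincount(col_idx[sampled], minlength=n_cols_total).astype(float)
        dm = pd_.distances(w, correction, saturation_ceiling)
        if dm.undefined.any():
            dropped += 1
            continue
        t = nj_tree(dm)
        for split, _len, _node in iter_splits(t):
            counts[split] = counts.get(split, 0) + 1
        if keep_replicates:
            reps.append(t)
    used = replicates - dropped
    if dropped > max_dropped_fraction * replicates or used == 0:
        raise ValueError(
            f"{dropped}/{replicates} bootstrap replicates dropped "
            "(undefined distances); partition too saturated or sparse"
        )
    for split, _len, node in iter_splits(point_tree):
        support = 100.0 * counts.get(split, 0) / used
        node.label = f"{support:.10g}"
    return BootstrapResult(point_tree, reps, dropped)


# ---------------------------------------------------------------------------
# Newick I/O and the external-tool adapter
# ---------------------------------------------------------------------------


def read_tree(source: str | Path, schema: str = "newick") -> dendropy.Tree:
    """Read a Newick tree; internal-node labels are kept as support labels."""
    src = str(source)
    try:
        if "(" in src and ";" in src:  # looks like newick data, not a path
            tree = dendropy.Tree.get(
                data=src, schema=schema, suppress_internal_node_taxa=True
            )
        else:
            tree = dendropy.Tree.get(
                path=src, schema=schema, suppress_internal_node_taxa=True
            )
    except Exception as exc:
        raise ValueError(f"cannot parse tree: {exc}") from exc
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Canonical Newick with branch lengths (%.6g) and support labels."""
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".6g",
        ).strip()
        + "\n"
    )


def write_tree(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(tree_to_newick(tree))


def write_phylip_matrix(dm: DistanceMatrix, path) -> None:
    """Square PHYLIP distance matrix (treedist/neighbor-compatible)."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.taxa)}\n")
        for i, t in enumerate(dm.taxa):
            row = " ".join(f"{v:.6f}" for v in np.nan_to_num(dm.values[i]))
            fh.write(f"{t[:10]:<10} {row}\n")


def external_tree_adapter(
    aln: Alignment | str | Path,
    command_template: str,
    workdir: str | Path | None = None,
) -> dendropy.Tree:
    """Run an external tree program and parse its Newick output.

    ``command_template`` contains ``{aln}`` and ``{out}`` placeholders; the
    command must write a Newick tree to ``{out}``.  Internal-node labels are
    interpreted as support values of the subtending edge.
    """
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        tmp = Path(tmp)
        if isinstance(aln, Alignment):
            aln_path = tmp / "input.fasta"
            write_alignment(aln, aln_path, "fasta")
        else:
            aln_path = Path(aln)
        out_path = tmp / "out.nwk"
        cmd = [
            part.format(aln=str(aln_path), out=str(out_path))
            for part in shlex.split(command_template)
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"external tree command failed (exit {proc.returncode}): {proc.stderr[:500]}"
            )
        text = out_path.read_text() if out_path.exists() else proc.stdout
        if not text.strip():
            raise RuntimeError("external tree command produced no output")
        return read_tree(text)
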