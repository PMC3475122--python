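"""Orchestrate the site-stripping scan: per-partition trees, metrics, window.

For every step of the A/B series the scan infers bootstrap-supported trees
for both the retained partition (A) and the removed most-variable sites
(B), records the Robinson–Foulds and branch-score distances between the two
point-estimate trees, the distribution of A-tree supports, and the
placement of any focal clades of interest.  The signature expected of a
noisy alignment is an initial regime where A and B trees disagree (B is
noise-dominated) followed by convergence once B accumulates genuinely
informative fast sites, with overall A-tree support staying high until too
much signal has been stripped; the "window" between the final collapse of
the between-tree distance and the decline of support marks the highest
signal-to-noise partitions.

All randomness flows from one seed through a per-step stream
(``default_rng([seed, step_index, partition])``), so skipping a step does
not shift the draws of any other step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .alignment_io import Alignment
from .partitioning import ExclusionScheme, apply_exclusion, build_series
from .phylo_engine import (
    BootstrapResult,
    ColumnPairData,
    bootstrap_support,
    read_tree,
    tree_to_newick,
)
from .site_variability import compute_ov, rank_sites, tree_dependent_rates
from .tree_metrics import (
    CladeQuery,
    PlacementResult,
    branch_score,
    clade_placement,
    rf_distance,
    support_summary,
)

log = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "StepRecord",
    "ScanResult",
    "CladeTrajectory",
    "run_scan",
    "detect_window",
    "clade_trajectory",
]


@dataclass(frozen=True)
class ScanConfig:
    step: int = 100
    max_removed: int = 2000
    replicates: int = 100
    seed: int = 0
    ranking_source: str = "ov"            # "ov" | "tree_dependent"
    guide_tree: str | None = None         # newick, required for tree_dependent
    correction: str = "jc"
    # saturated pairs (p >= 0.75) in a partition get this fixed large JC
    # distance, mimicking the very long branch estimates likelihood methods
    # return on saturated data; None restores skip-on-undefined behavior
    saturation_ceiling: float | None = 3.0
    exclusion: ExclusionScheme | None = None
    clade_queries: tuple[CladeQuery, ...] = ()
    support_floor: float = 98.0
    distance_fraction: float = 0.25

    def __post_init__(self):
        if self.step < 1 or self.replicates < 1:
            raise ValueError("step and replicates must be >= 1")
        if self.ranking_source == "tree_dependent" and self.guide_tree is None:
            raise ValueError("tree_dependent ranking needs a guide tree")


@dataclass
class StepRecord:
    removed: int
    label: str
    a_size: int
    b_size: int
    a_tree: dendropy.Tree
    b_tree: dendropy.Tree
    support_median: float
    support_mean: float
    support_sd: float
    rf: int
    branch_score: float
    placements: dict[str, PlacementResult] = field(default_factory=dict)


@dataclass
class ScanResult:
    config: ScanConfig
    n_cols: int
    steps: list[StepRecord]
    skipped: list[tuple[int, str]] = field(default_factory=list)

    def serialize(self) -> str:
        """Deterministic text serialization (provenance + per-step records)."""
        cfg = self.config
        lines = [
            f"# plastonoise scan seed={cfg.seed} step={cfg.step} "
            f"max_removed={cfg.max_removed} replicates={cfg.replicates} "
            f"ranking={cfg.ranking_source} correction={cfg.correction} "
            f"n_cols={self.n_cols}"
        ]
        for s in self.steps:
            fieldsv = [
                s.label, str(s.removed), str(s.a_size), str(s.b_size),
                f"{s.support_median:.10g}", f"{s.support_mean:.10g}",
                f"{s.support_sd:.10g}", str(s.rf), f"{s.branch_score:.10g}",
            ]
            for name in sorted(s.placements):
                p = s.placements[name]
                fieldsv += [
                    name, str(int(p.monophyly)), f"{p.monophyly_support:.10g}",
                    p.placement_label, f"{p.ancestral_support:.10g}",
                ] + [
                    f"{alt}={sup:.10g}"
                    for alt, sup in sorted(p.alternative_supports.items())
                ]
            lines.append("\t".join(fieldsv))
            lines.append(tree_to_newick(s.a_tree).strip())
            lines.append(tree_to_newick(s.b_tree).strip())
        for removed, reason in self.skipped:
            lines.append(f"# skipped m={removed}: {reason}")
        return "\n".join(lines) + "\n"

    def trajectory_table(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            row = {
                "label": s.label, "removed": s.removed, "a_size": s.a_size,
                "support_median": s.support_median, "support_mean": s.support_mean,
                "support_sd": s.support_sd, "rf": s.rf,
                "branch_score": s.branch_score,
            }
            for name, p in s.placements.items():
                row[f"{name}:label"] = p.placement_label
                row[f"{name}:monophyly_support"] = p.monophyly_support
                row[f"{name}:ancestral_support"] = p.ancestral_support
                for alt, sup in p.alternative_supports.items():
                    row[f"{name}:support_{alt}"] = sup
            rows.append(row)
        return pd.DataFrame(rows)

    def write_outputs(self, outdir) -> None:
        outdir = Path(outdir)
        (outdir / "trees").mkdir(parents=True, exist_ok=True)
        self.trajectory_table().to_csv(outdir / "trajectory.tsv", sep="\t", index=False)
        for s in self.steps:
            (outdir / "trees" / f"{s.label}_A.nwk").write_text(tree_to_newick(s.a_tree))
            (outdir / "trees" / f"{s.label}_B.nwk").write_text(tree_to_newick(s.b_tree))
        (outdir / "scan.log").write_text(self.serialize())


def _collapse_zero_edges(tree: dendropy.Tree, eps: float = 1e-12) -> dendropy.Tree:
    """Clone with effectively-zero-length internal edges collapsed.

    NJ emits exact zeros for unresolvable (star-like) structure after
    clamping; collapsing keeps such edges out of the topological metrics.
    """
    clone = tree.clone(depth=1)
    for node in list(clone.postorder_node_iter()):
        if (
            node.parent_node is not None
            and not node.is_leaf()
            and (node.edge.length is None or node.edge.length <= eps)
        ):
            node.edge.collapse()
    return clone


def run_scan(aln: Alignment, cfg: ScanConfig) -> ScanResult:
    """Run the full site-stripping scan; deterministic given ``cfg.seed``."""
    if cfg.ranking_source == "ov":
        ranking = rank_sites(compute_ov(aln))
    elif cfg.ranking_source == "tree_dependent":
        rates = tree_dependent_rates(aln, read_tree(cfg.guide_tree))
        ranking = rank_sites(rates, source="tree_dependent")
    else:
        raise ValueError(f"unknown ranking source {cfg.ranking_source!r}")

    # sites are ranked once, on the full alignment; exclusion applies after
    aln_inf = apply_exclusion(aln, cfg.exclusion) if cfg.exclusion else aln
    pair_data = ColumnPairData(aln_inf)
    series = build_series(ranking, aln.n_cols, cfg.step, cfg.max_removed)

    steps: list[StepRecord] = []
    skipped: list[tuple[int, str]] = []
    for idx, part in enumerate(series):
        w_a = np.zeros(aln.n_cols)
        w_a[part.a_cols] = 1.0
        w_b = np.zeros(aln.n_cols)
        w_b[part.b_cols] = 1.0
        try:
            boot_a = bootstrap_support(
                aln_inf, cfg.replicates, correction=cfg.correction,
                pair_data=pair_data, column_weights=w_a,
                rng=np.random.default_rng([cfg.seed, idx, 0]),
                keep_replicates=False,
                saturation_ceiling=cfg.saturation_ceiling,
            )
            boot_b = bootstrap_support(
                aln_inf, cfg.replicates, correction=cfg.correction,
                pair_data=pair_data, column_weights=w_b,
                rng=np.random.default_rng([cfg.seed, idx, 1]),
                keep_replicates=False,
                saturation_ceiling=cfg.saturation_ceiling,
            )
            t_a = _collapse_zero_edges(boot_a.tree)
            t_b = _collapse_zero_edges(boot_b.tree)
            summ = support_summary(t_a)
        except ValueError as exc:
            log.warning("step m=%d skipped: %s", part.removed, exc)
            skipped.append((part.removed, str(exc)))
            continue
        record = StepRecord(
            removed=part.removed,
            label=part.label,
            a_size=part.a_size,
            b_size=len(part.b_cols),
            a_tree=t_a,
            b_tree=t_b,
            support_median=summ.median,
            support_mean=summ.mean,
            support_sd=summ.sd,
            rf=rf_distance(t_a, t_b),
            branch_score=branch_score(t_a, t_b),
            placements={
                q.name: clade_placement(t_a, q) for q in cfg.clade_queries
            },
        )
        steps.append(record)
    if not steps:
        raise ValueError("all scan steps were skipped (undefined distances)")
    return ScanResult(cfg, aln.n_cols, steps, skipped)


def detect_window(
    result: ScanResult,
    support_floor: float | None = None,
    distance_fraction: float | None = None,
) -> tuple[int, int] | None:
    """Locate the high signal-to-noise window of the scan.

    A step qualifies when (a) its branch score has fallen to at most
    ``distance_fraction`` of the running maximum branch score up to and
    including that step — i.e. the A/B distance is past its major decline —
    and (b) the median A-tree support is at least ``support_floor``.  The
    window is the *last* maximal contiguous run of qualifying steps
    (the run after the final major decline), returned as inclusive step
    indices into ``result.steps``; None if no step qualifies.
    """
    floor = result.config.support_floor if support_floor is None else support_floor
    frac = (
        result.config.distance_fraction
        if distance_fraction is None
        else distance_fraction
    )
    if len(result.steps) < 5:
        raise ValueError("window detection needs at least 5 scan steps")
    bs = np.array([s.branch_score for s in result.steps])
    med = np.array([s.support_median for s in result.steps])
    run_max = np.maximum.accumulate(bs)
    qualifies = (bs <= frac * run_max) & (med >= floor)
    if not qualifies.any():
        return None
    # last maximal contiguous run
    end = int(np.flatnonzero(qualifies)[-1])
    start = end
    while start > 0 and qualifies[start - 1]:
        start -= 1
    return start, end


@dataclass(frozen=True)
class CladeTrajectory:
    """Per-step placement series for one clade query.

    ``arrow_removed`` is the removed-site count at which monophyly support
    first drops below 100% (None if it never does).
    """

    name: str
    table: pd.DataFrame
    arrow_removed: int | None


def clade_trajectory(result: ScanResult, name: str) -> CladeTrajectory:
    if not result.steps:
        raise ValueError("empty scan result")
    if name not in result.steps[0].placements:
        known = sorted(result.steps[0].placements)
        raise KeyError(f"unknown clade query {name!r}; scan evaluated {known}")
    rows = []
    arrow = None
    for s in result.steps:
        p = s.placements[name]
        row = {
            "removed": s.removed,
            "label": s.label,
            "monophyly_support": p.monophyly_support,
            "placement_label": p.placement_label,
            "ancestral_support": p.ancestral_support,
        }
        for alt, sup in p.alternative_supports.items():
            row[f"support_{alt}"] = sup
        rows.append(row)
        if arrow is None and p.monophyly_support < 100.0:
            arrow = s.removed
    return CladeTrajectory(name, pd.DataFrame(rows), arrow)
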