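"""Substitution-saturation diagnosis from corrected vs. uncorrected distances.

Multiple substitutions at a site make the observed (uncorrected) p-distance
grow more slowly than the model-corrected distance.  Regressing the
uncorrected distance (response) on the Jukes–Cantor corrected distance
(predictor) over all taxon pairs therefore gives a slope <= 1, and the
further the slope falls below 1 the more saturated the data: at small
distances JC is close to the identity and the slope approaches 1, while
saturating datasets pull the largest corrected distances away from the
diagonal.  This orientation (uncorrected on corrected) is the module's
central convention — it is the one under which reported slopes below one
mean "more saturation".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .alignment_io import Alignment, slice_columns
from .phylo_engine import pairwise_distances

__all__ = ["SaturationResult", "regress_saturation", "saturation_slope"]


@dataclass(frozen=True)
class SaturationResult:
    slope: float
    ci_low: float
    ci_high: float
    intercept: float
    n_pairs: int
    n_excluded: int      # pairs dropped because JC was undefined (p >= 0.75)
    degenerate: bool = False  # all predictor values identical; slope not estimable


def regress_saturation(
    corrected: Sequence[float],
    uncorrected: Sequence[float],
    through_origin: bool = False,
    n_excluded: int = 0,
) -> SaturationResult:
    """OLS of uncorrected on corrected distances with an analytic 95% CI."""
    x = np.asarray(corrected, dtype=float)
    y = np.asarray(uncorrected, dtype=float)
    if len(x) != len(y):
        raise ValueError("corrected/uncorrected lengths differ")
    if len(x) < 3:
        raise ValueError(f"need at least 3 usable pairs, got {len(x)}")
    if np.ptp(x) == 0.0:
        return SaturationResult(
            np.nan, np.nan, np.nan, np.nan, len(x), n_excluded, degenerate=True
        )
    if through_origin:
        slope = float((x @ y) / (x @ x))
        resid = y - slope * x
        dof = len(x) - 1
        se = float(np.sqrt((resid @ resid) / dof / (x @ x)))
        intercept = 0.0
    else:
        fit = stats.linregress(x, y)
        slope, intercept, se = float(fit.slope), float(fit.intercept), float(fit.stderr)
        dof = len(x) - 2
    t = float(stats.t.ppf(0.975, dof))
    return SaturationResult(
        slope, slope - t * se, slope + t * se, intercept, len(x), n_excluded
    )


def saturation_slope(
    aln: Alignment,
    taxa_subset: Sequence[str] | None = None,
    cols_subset: Sequence[int] | None = None,
    through_origin: bool = False,
) -> SaturationResult:
    """Saturation slope for an alignment (optionally taxon/column subsets).

    p and JC distances are computed under pairwise deletion; pairs with
    undefined JC (p >= 0.75) or no compared sites are excluded and counted.
    """
    if taxa_subset is not None:
        aln = aln.select_taxa(list(taxa_subset))
    if cols_subset is not None:
        aln = slice_columns(aln, cols_subset)
    if aln.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    p_dm = pairwise_distances(aln, correction="none")
    jc_dm = pairwise_distances(aln, correction="jc")
    iu = np.triu_indices(aln.n_taxa, k=1)
    p = p_dm.values[iu]
    jc = jc_dm.values[iu]
    usable = ~np.isnan(p) & ~np.isnan(jc)
    n_excluded = int((~usable).sum())
    return regress_saturation(
        jc[usable], p[usable], through_origin=through_origin, n_excluded=n_excluded
    )


def pair_table(aln: Alignment) -> str:
    """Tab-separated per-pair table: taxon1, taxon2, p, jc."""
    p_dm = pairwise_distances(aln, correction="none")
    jc_dm = pairwise_distances(aln, correction="jc")
    lines = ["taxon1\ttaxon2\tp\tjc"]
    for i in range(aln.n_taxa):
        for j in range(i + 1, aln.n_taxa):
            lines.append(
                f"{aln.taxa[i]}\t{aln.taxa[j]}\t"
                f"{p_dm.values[i, j]:.6g}\t{jc_dm.values[i, j]:.6g}"
            )
    return "\n".join(lines) + "\n"
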