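# Methods

This note documents the models, numerical conventions and design choices
behind `plastonoise`, in the order the pipeline applies them.

## Observed variability (OV)

For an alignment column, OV is the fraction of mismatching taxon pairs
among the k pairs in which both taxa carry a determinate base (A/C/G/T):

    OV = (number of mismatching valid pairs) / k .

Gaps (`-`), masks (`N`/`?`) and the other IUPAC ambiguity codes are all
indeterminate for this purpose: the statistic is defined over called bases
only. Columns with k = 0 carry no pairwise information; they are assigned
OV 0, flagged undefined, and sorted after every defined column in a
ranking. Ties in OV break by ascending column index, which makes the
boundaries of fixed-size removal blocks deterministic.

Computation is by per-column base counts (mismatching pairs =
(d² − Σ<sub>b</sub> c<sub>b</sub>²)/2 for d determinate bases of counts
c<sub>b</sub>), verified in the test suite against explicit pair
enumeration.

A consequence worth knowing when interpreting rankings: for a column whose
variation stems from a single substitution on one internal edge, OV is
fixed by the edge's split sizes (s·(n−s)/C(n,2) for a side of s taxa).
Columns diagnostic of deep divisions therefore have systematically high OV
and are stripped earlier than tip-level variation — the stripping series
removes deep-signal sites along with noise, which is exactly why support
eventually collapses as removal proceeds.

## Tree-dependent site rates

The tree-aware alternative scores each column by the rate multiplier
r ∈ [10⁻⁴, 64] that maximizes the column's likelihood under Jukes–Cantor
on a fixed reference tree with all branch lengths scaled by r. Felsenstein
pruning uses the JC identity Σ<sub>t</sub> P<sub>st</sub>(b) x<sub>t</sub>
= ¼(1−e^(−4b/3)) Σx + e^(−4b/3) x<sub>s</sub>; indeterminate and partially
determinate (IUPAC) leaves are marginalized through partial state vectors.
Because several branch lengths interact, the profile likelihood in r is
not always unimodal; a 40-point log-grid pre-search brackets the global
optimum before bounded Brent refinement (tolerance 10⁻⁶). Columns with at
most one determinate leaf have no rate (NaN). Invariant columns optimize
to the lower bound; columns conflicting with the tree run to the upper
bound.

## Per-region summaries

Per-category means of per-site scores are taken over **all** columns of a
category (zero-score columns included), mirroring "average per-site"
region tables. A one-way ANOVA across categories is followed by Tukey's
HSD at α = 0.05; compact letter display assigns one letter per maximal
clique of the "not significantly different" graph, so categories sharing
no letter differ significantly. Optional exon recomputations excluding
named hyper-variable loci (e.g. ycf1-like giants) enter the comparison as
additional groups. Groups with fewer than two columns are reported but
excluded from the significance machinery.

## Partition series and taxon exclusion

Removing the top m = step, 2·step, … ranked sites yields complementary
partitions A (retained, labelled A_n with n = n_cols − m) and B (the
removed m). Sites are ranked once, on the full alignment; taxon exclusion
(outgroup removal, subgroup-only, section plus a single designated
outgroup) then restricts rows without re-ranking, matching the convention
of ranking on the complete matrix. Exclusion schemes are data-driven taxon
sets, not hard-coded taxonomy; a kept set below four taxa is rejected.

## Distances, neighbor joining, bootstrap

Pairwise distances use pairwise deletion ("gaps treated as missing"):
p = mismatches / compared sites over columns where both taxa are
determinate. The Jukes–Cantor correction d = −¾·ln(1 − 4p/3) is undefined
at p ≥ ¾ and such pairs are flagged, not silently altered, in the general
API. Neighbor joining follows Saitou–Nei with the standard Q criterion;
negative branch estimates are clamped to zero with the deficit moved to
the adjacent branch so the joined pair's distance is preserved; Q ties
break on the first row-major minimum, making inference deterministic. The
final three lineages join at an internal node via the three-point
formulas, so trees are genuinely unrooted.

Bootstrap support resamples columns with replacement (implemented as
multinomial column weights over precomputed per-pair mismatch/validity
indicators, so a replicate costs two matrix products); the support of each
internal edge of the point tree is the percentage of replicate trees
containing its bipartition. All randomness flows from
`numpy.random.default_rng([seed, step, partition])`, so skipping a step
never shifts another step's draws.

### Saturated pairs inside the scan

Small B partitions — the few hundred most variable sites — are routinely
saturated: pooled p-distances at or beyond ¾ would make JC undefined and
force the scan to drop exactly the steps that display the noise regime.
The scan therefore maps correctable-range violations to a fixed ceiling
distance (`ScanConfig.saturation_ceiling`, default 3.0 substitutions/site;
the planted-conflict preset uses 8.0). This mirrors how likelihood
programs behave on saturated partitions — they return very long branches,
not missing data — and restores the diagnostic early-scan behavior: tiny
noise-dominated B partitions produce trees with enormous, unstable
branches, so the A/B branch score starts high and collapses as B
accumulates genuine signal. Pairs with zero compared sites remain
undefined; a replicate containing one is dropped (more than 10% dropped
fails the partition), and a partition whose point estimate contains one is
skipped with a log entry.

## Tree comparison

Trees are compared unrooted through canonicalized non-trivial
bipartitions. The partition (Robinson–Foulds) metric is the size of the
symmetric difference of split sets. The branch score is the sum over the
split union of squared branch-length differences, an absent split
contributing its length squared; no square root is taken (conventions
differ between implementations — this is the squared-sum form). A degree-2
root contributes its two half-edges as one split with summed length.
Before the scan compares trees, internal edges of effectively zero length
(NJ's unresolved structure after clamping) are collapsed, so RF reflects
resolved splits only.

Clade placement works on the split set rather than by explicit rerooting:
for each split, the "clade side" is the side disjoint from the query's
outgroup taxa; the focal group's sister is the smallest clade side
strictly containing it, minus the focal set. With a single outgroup taxon
the whole ingroup counts as a (trivially present) clade, support 100. The
per-alternative supports a trajectory tracks are the supports of the exact
clades (focal ∪ alternative), zero when absent from the tree.

## Window detection

A scan step qualifies when (a) its A/B branch score is at most
`distance_fraction` (default 0.25) of the running maximum branch score up
to and including that step — i.e. the distance is past its major decline —
and (b) the A-tree's median internal-edge support is at least
`support_floor` (default 98, the level sustained by high-signal
partitions). The window is the **last** maximal contiguous run of
qualifying steps, the run after the final decline. Both thresholds are
configuration, not constants; at least five steps are required for the
notion to be meaningful.

## Saturation slope

Saturation is quantified as the OLS slope of uncorrected p-distances
(response) on JC-corrected distances (predictor) over all usable taxon
pairs, intercept included; a `through_origin` variant exists for
sensitivity. This orientation makes slopes ≤ 1 with lower values meaning
more saturation (the corrected axis stretches as multiple hits
accumulate). Pairs with undefined JC are excluded and counted. The 95% CI
is the analytic t-based interval. Note the finite-distance bias: even
without noise the slope is ≈ 1/(1 + 4p̄/3) < 1, so "slope → 1" holds only
in the genuinely small-distance limit. A degenerate predictor (all
corrected distances equal) is flagged rather than fitted.

## The synthetic-data generator

Columns evolve independently under JC down a generating tree, site-wise:
per column, branch lengths are scaled by (discrete-gamma draw ×
annotation-category multiplier × planted-class multiplier). Discrete gamma
uses equal-probability categories with exact per-category means. Category
fractions and multipliers default to a plastome-like profile: noncoding
40% of columns at 4× exon rate, then exon (1.0), intron (0.8), tRNA and
rRNA (0.3 each) — reproducing the empirical variability ordering of
plastome regions. Gap and mask cells are injected i.i.d. (1% each by
default); whole-column indeterminate blocks are available to emulate
fully masked alignment positions.

Two planted noise classes model what dominates the top of a real
variability ranking:

* **conflict** columns (fraction 0.05) evolve on a second topology in
  which the focal taxon has a different sister group, at 16× rate on
  branches 4.5× longer, with 35% of their cells indeterminate — fast
  sites carrying a largely saturation-scrambled alternative history;
* **junk** columns (fraction 0.05) evolve on the true tree at 40× rate
  with 75% of cells indeterminate — assembly-artifact positions in which
  most taxa are gaps or masked bases and the called bases are nearly
  random.

The junk class is what drives the early branch-score spike: the smallest
B partitions consist almost entirely of such columns, their pooled
distances saturate, and the ceiling mapping turns them into wildly long
branches, exactly the regime observed on real gap-dominated top-variability
blocks.

### What the preset can and cannot show

A single planted class cannot simultaneously (i) overturn the focal
placement on the full alignment and (ii) let the removed-site partitions
converge to the true topology: the conflicting pull and the true focal
signal dilute identically between the full matrix and any B partition
containing all planted sites, so if the pull beats the signal at step 0 it
beats it inside every B. The shipped preset therefore realizes the
stripping dynamics — noise-dominated early B trees, branch-score collapse,
a detectable window bracketing maximal focal support, A/B convergence to
RF 0 — while full-alignment support for the true placement stays high
rather than being overturned. The support-depression mechanism itself
(planted coherent conflict lowering bootstrap support for the true
placement) is real and is demonstrated by a separate shallow,
unsaturated-conflict configuration in the test suite.

Passing tests on this generator show the pipeline's operations and their
interplay are correct under the model's assumptions (independent sites,
JC, rate multipliers, i.i.d. indeterminacy). They do not certify behavior
under real-data features the generator omits: indel evolution and
alignment error, base-composition bias, within-column rate change
(heterotachy), recombination, or model misspecification of the inference
engine.

## Problem sizes

The default verification conditions are 12 taxa × 5000 columns with scans
of 20 steps of 100 sites and 100 bootstrap replicates, repeated over 20
seeds — chosen as the smallest configuration in which all three scan
regimes (noise-dominated, window, over-stripped) are visible and stable
across seeds. Oracle checks run on ≤ 8-taxon random alignments and 4–12
leaf random additive trees. The structural statistics of the real
113-taxon, 141,265-column plastome matrix (column/taxon counts,
all-indeterminate columns, distinct patterns, full-alignment saturation
slope) are asserted by a test that requires that matrix to be present
locally under `data/`; it is too large to distribute with the package.

## Known limitations

* The internal engine is distance-based (NJ + bootstrap). Scan-level
  trends (support trajectories, A/B convergence, window location) are
  method-portable, but absolute bootstrap values will differ from ML
  programs; the external-tool adapter exists for exact reproduction
  workflows.
* The saturation ceiling is a pragmatic stand-in for ML's long-branch
  behavior; branch scores involving ceilinged pairs are interpretable only
  relatively (their scale is set by the ceiling).
* OV's split-size dependence (above) means single-substitution support for
  deep edges is stripped in discrete blocks; rankings on few-taxon
  alignments are coarser than on many-taxon ones.
* Tukey letters use maximal cliques of the non-significance graph; with
  heavily overlapping groups the display can assign several letters per
  group (standard compact-letter-display behavior).
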