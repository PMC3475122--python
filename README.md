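# plastonoise

Site-stripping noise mitigation for plastome-scale phylogenetics.

Concatenated organellar alignments (100+ taxa, >100 kbp) mix slowly evolving
positions carrying clean phylogenetic signal with a minority of highly
variable positions — saturated sites, alignment/assembly artifacts, regions
with conflicting evolutionary histories — whose noise can inflate or
overturn the placement of difficult clades. `plastonoise` implements the
classic diagnostic workflow for this problem:

1. **Rank** every alignment column by *observed variability*
   (OV = Σ<sub>i<j</sub> d<sub>ij</sub> / k, the fraction of mismatching
   pairs among the k taxon pairs with determinate bases at the column), or
   by a tree-dependent per-site rate (the ML rate multiplier r̂ maximizing
   the column's Jukes–Cantor likelihood on a fixed reference tree).
2. **Strip** the top-ranked sites serially (100, 200, …), producing
   complementary partitions A<sub>n</sub> (retained, n columns kept) and
   B<sub>n</sub> (the removed most-variable sites).
3. **Infer** bootstrap-supported trees for every partition (internal
   neighbor-joining engine on JC distances, or any external program through
   an adapter) and **compare** A/B trees with the partition metric
   (Robinson–Foulds) and the branch score
   (Σ over the split union of squared branch-length differences).
4. **Detect the high signal-to-noise window**: the run of partitions where
   the A/B tree distance has collapsed (noise exhausted) while the A-tree's
   median bootstrap support is still at its ceiling (signal intact), and
   track focal-clade placements across it.
5. **Quantify saturation** as the OLS slope of uncorrected p-distances on
   JC-corrected distances over all taxon pairs (slope 1 = no saturation;
   lower = more saturated), and apply long-branch taxon-exclusion schemes.

A planted-noise simulator generates alignments with category-structured
rate variation (noncoding > exon > intron > tRNA/rRNA), a conflicting-
history site class, and gap/mask structure, so the entire pipeline is
testable end to end without any external data.

## Worked example

```python
import plastonoise as pn
from plastonoise.synthetic_data import (
    planted_conflict_scenario, scenario_scan_config,
)

# 12 taxa x 5000 columns; 5% of columns evolve on a conflicting topology
# (focal taxon FOC sister to Y instead of its true sister group X) and 5%
# are ultra-gappy junk, both planted at high rate
cfg = planted_conflict_scenario(n_taxa=12, seed=1)
aln, annotation, truth = pn.simulate_alignment(cfg)

ranking = pn.rank_sites(pn.compute_ov(aln))
planted = set(truth.planted_indices)
top = set(ranking.top(2 * len(planted)))
print(f"planted sites in top ranks: {len(top & planted) / len(planted):.2f}")

result = pn.run_scan(aln, scenario_scan_config(seed=1))
window = pn.detect_window(result)
lo, hi = window
print(f"window: {result.steps[lo].label} .. {result.steps[hi].label}")
for s in result.steps[:3] + result.steps[lo : lo + 1]:
    print(f"{s.label}: rf={s.rf} branch_score={s.branch_score:.2f} "
          f"median_support={s.support_median:.0f}")
```

prints (seed 1):

```
planted sites in top ranks: 0.75
window: A_3900 .. A_3000
A_4900: rf=14 branch_score=37.54 median_support=100
A_4800: rf=4 branch_score=43.03 median_support=100
A_4700: rf=2 branch_score=38.39 median_support=100
A_3900: rf=4 branch_score=10.85 median_support=100
```

Reading the output: 75% of the planted noise sites sit in the top of the OV
ranking, so serial stripping removes them early. The branch score between
retained (A) and removed (B) partition trees starts very high — the
smallest B partitions are dominated by near-saturated, gap-riddled sites
and produce wildly long, unstable branches — and collapses by roughly an
order of magnitude once the planted sites are diluted by genuinely
informative fast sites; the detected window (here partitions A_3800 to
A_3000) is where that collapse coexists with ceiling-level median bootstrap
informative fast sites (here to about a quarter of its early maximum by
A_3900); the detected window (partitions A_3900 to A_3000) is where that
collapse coexists with ceiling-level median bootstrap support in the
retained tree. Focal-clade placements queried during the scan
(`pn.clade_trajectory(result, "FOC_placement")`) show the true FOC-with-X
placement held at maximal support inside the window.

The same steps are available from the shell:

```bash
plastonoise simulate --taxa 12 --cols 5000 --seed 1 --out sim.fasta
plastonoise ov --aln sim.fasta --out ov.tsv
plastonoise scan --aln sim.fasta --max-removed 2000 --seed 1 --out scan_out/
plastonoise saturation --aln sim.fasta
plastonoise treedist scan_out/trees/A_3000_A.nwk scan_out/trees/A_3000_B.nwk
```

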