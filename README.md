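# barseq-popdyn

Population-dynamics analysis for pooled barcoded deletion libraries profiled
by Bar-seq, aimed at studies that track a mutant pool through a simulated
industrial scale-up: seed-train shake flasks feeding batch and fed-batch
bioreactors, with samples sequenced over the course of fermentation. The
package takes raw amplicon reads (or pre-made count tables) and answers the
questions such an experiment poses: how diverse is the pool at each
timepoint, when does diversity collapse, how do populations diverge between
cultivation regimes, and which mutants (and biological processes) are being
selected against.

It ships with a pooled-competition simulator that plants known per-mutant
selection coefficients, so every stage of the analysis can be validated
against ground truth at desk scale.

## What it computes

**Quantification.** A read counts toward a gene only when the barcode
immediately following the upstream flanking sequence matches a catalog
barcode perfectly at full length; barcodes shared by several genes are
discarded, strains with fewer than 10 counts in the starting pool (t0) are
dropped, and counts are pseudocounted (+10) before normalization to relative
abundances *x* with Σ*x* = 1 per sample.

**Diversity.** Richness is the number of mutants detected at a count
threshold *n* (default 10); "mass extinction" windows are the
consecutive-timepoint intervals maximizing the number of detection losses,
scanned over thresholds {1, 5, 10, 20}. Sample similarity is the Pearson *r*
of raw counts.

**Beta diversity.** Bray–Curtis dissimilarity
`d(x, y) = 1 − 2 Σ min(xᵢ, yᵢ) / (Σ xᵢ + Σ yᵢ)`, ordinated by PCoA and by
NMDS (Kruskal stress-1 with isotonic disparities, multi-restart);
one-factor PERMANOVA with pseudo-F from Anderson's distance-based
sums of squares and permutations restricted by strata for repeated-measures
designs (whole-reactor label exchange when testing a per-reactor factor,
within-reactor shuffling when testing time); beta dispersion as distance to
the group centroid in full PCoA space with imaginary-axis correction,
tested by ANOVA plus permutation with BH-adjusted pairwise comparisons.

**Selection and enrichment.** Between two timepoints a mutant is *lost*
(final count < 10), *depleted* (≥ 50% relative-abundance drop), *enriched*
(≥ 2-fold rise) or *retained*; gene lists are intersected across conditions
(full Venn partition) and tested for term enrichment with the upper-tail
hypergeometric distribution and Benjamini–Hochberg FDR control against the
post-filter gene universe.

**Simulation.** Relative abundances evolve as
`xᵢ ← xᵢ (1 + sᵢ)^g` per phase of *g* generations (renormalized), with
optional multinomial bottlenecks at serial transfers; sequencing is a
multinomial draw at configurable depth, optionally emitted as FASTQ with
per-base substitution errors.

## Worked example

Simulate the preset scale-up design (two seed stages, then SF1/SF2/BR and
fed-batch CF4/CF6/DF4/DF6 with a stress window planted at 48–72 h in the
constant-feed reactors), sequence it at depth 2×10⁶, and analyze:

```python
from barseq_popdyn import (preset_scaleup_design, simulate_trajectory, sample_all,
                           filter_t0, normalize, loss_windows, bray_curtis,
                           permanova)

landscape, schedule = preset_scaleup_design(seed=17, n_genes=3000)
truth = simulate_trajectory(landscape, schedule, seed=18)
table = sample_all(truth, depth=2_000_000, seed=19)

filtered = filter_t0(table, "CF4_t0", threshold=10)
_, argmax = loss_windows(filtered, "CF4", thresholds=(10,))
w = argmax[10]
print(f"CF4 maximal diversity loss: {w.n_lost} mutants "
      f"({100*w.fraction_lost:.1f}%) in the {w.window[0]:g}-{w.window[1]:g} h window")

ab = normalize(filtered, pseudocount=10)
fed = filtered.meta["condition"].isin(["CF4", "CF6", "DF4", "DF6"])
ids = list(filtered.meta.index[fed])
dm = bray_curtis(ab.abundance.loc[ids])
meta = filtered.meta.loc[ids]
res = permanova(dm, meta["time_h"].to_numpy(),
                strata=meta["condition"].to_numpy(),
                n_permutations=999, seed=20, term="time")
print(f"PERMANOVA (time, strata=reactor): R2 = {res.R2:.2f}, p = {res.p_value:.3f}")
```

prints

```
CF4 maximal diversity loss: 360 mutants (12.0%) in the 48-72 h window
PERMANOVA (time, strata=reactor): R2 = 0.20, p = 0.004
```

The loss window coincides with the planted stress phase, and elapsed
fermentation time explains a significant fraction of the Bray–Curtis
variance (testing the feeding regime the same way on this design gives
R² ≈ 0.10 at p ≈ 0.32 — four reactors allow only six whole-block
permutations, so per-reactor factors have little power).

A CLI mirrors the library (`barseq-popdyn simulate|count|filter|normalize|
diversity|correlate|ordinate|permanova|select|venn|enrich|run`); `run`
executes the whole pipeline from a YAML config and writes TSVs plus a
machine-readable report with checksums and the recorded seed.

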