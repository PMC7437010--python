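# Methods

## Quantification model

A sample's reads are assigned by exact string matching: the barcode is the
L-mer (default L = 20) immediately after the first occurrence of a
configurable upstream flank, and it must equal a retained catalog barcode
at full length. There is no fuzzy matching, no quality filtering and no
UMI logic — the perfect-match rule already discards errored reads, and the
simulator shows the cost: with per-base substitution rate *e* the expected
recovered fraction is (1 − e)^L. Barcodes listed for more than one gene are
removed from the catalog before counting because a read carrying one cannot
be attributed. The amplicon layout (flank sequence, barcode position) is
protocol-dependent and therefore configurable; reverse-complement search is
available behind a flag (default off).

Filtering and normalization follow the counting conventions of pooled
fitness assays: strains with fewer than `t0_threshold` (default 10) counts
in the designated starting sample are dropped from every sample, fixing the
gene universe for all downstream statistics (genes absent later count as 0,
they are not re-dropped). Counts are then increased by a pseudocount
(default 10) and divided by the sample's **adjusted** total. The raw-total
denominator would be equally defensible, but dividing by the adjusted total
makes each row an exact composition (sums to 1), which Bray–Curtis assumes;
the pseudocount also keeps every abundance strictly positive so fold
changes are always defined.

## Diversity and similarity

Richness is defined operationally: a mutant is "detected" when its count is
at or above a threshold (boundary inclusive). Loss windows count
detection-state transitions between consecutive timepoints of one
condition; a gene re-appearing later is counted as a gain, not resurrected
silently, because near-threshold flips are sampling noise rather than
extinction and the telescoping identity
Σ(lost − gained) = detected(first) − detected(last) should hold exactly.
The maximal-loss window per threshold breaks ties toward the earliest
window. The default threshold grid {1, 5, 10, 20} interprets "more than
0 / 5 / 10 / 20 counts"-style robustness scans as minimum-count thresholds.

Pearson correlation between samples is computed on raw counts over the
post-filter universe (an abundance-based mode exists for comparison).
Zero-variance samples yield NaN rows/columns plus a warning rather than an
arbitrary value.

## Beta diversity

Bray–Curtis is computed directly from the definition on abundance rows.
Because it is non-Euclidean, the Gower-centered eigendecomposition of
−½D² has negative eigenvalues; PCoA coordinates use the top-k non-negative
axes, while beta dispersion keeps *all* axes: a sample's squared distance
to its group centroid is the real-axis squared distance minus the
imaginary-axis squared distance, floored at zero before the square root.
Dispersion differences are tested three ways — classical one-way ANOVA F,
a permutation p for the same F (labels shuffled over the fixed distances,
999 by default), and pairwise permutation tests on group-mean differences
with BH adjustment. Pairwise permutation replaces Tukey HSD deliberately:
it is distribution-free and reuses the package's permutation machinery.
Groups of size one are excluded from tests but their distances are
reported. Group centroids (not spatial medians) are used.

NMDS minimizes Kruskal stress-1,
`sqrt(Σ(d − d̂)² / Σ d²)`, where d are configuration distances and d̂ the
isotonic (pool-adjacent-violators) regression of d on the rank order of
the observed dissimilarities; ties in the dissimilarities are handled by
the primary approach (tied blocks ordered by current configuration
distance). Each iteration takes a Guttman majorization step and accepts it
only if stress-1 does not increase, backtracking toward the current
configuration otherwise, so the per-restart stress trace is non-increasing
by construction and convergence is declared when the improvement falls
below 1e-7. One start is the k-dimensional PCoA configuration (for
Euclidean-embeddable inputs this start already bounds the result); the
remaining n_restarts − 1 (default 19) starts are seeded Gaussian
configurations. Non-convergence returns the best configuration with a
logged warning, never silently. The final configuration is centered and
rescaled to the data's mean dissimilarity (stress-1 is scale-invariant).

PERMANOVA uses Anderson's distance-based decomposition
(SS_total = Σ_{i<j} d²ᵢⱼ / n, SS_within summed per group, pseudo-F with
(a − 1, n − a) degrees of freedom) and the permutation p-value
(1 + #{F* ≥ F}) / (1 + n_perm). One factor is tested at a time. The
repeated-measures correction is a restricted-permutation scheme: when the
tested labels are constant within each stratum (e.g. feeding regime per
reactor) the reactors themselves are the exchangeable units and their
whole-block labels are shuffled; otherwise (e.g. time within reactor)
labels shuffle only within strata. Either way a reactor's samples are
never split. An exhaustive mode enumerates all distinct label arrangements
for small designs, making the p-value exact. Note the attainable
granularity: four reactors in two feeding groups admit only six distinct
block arrangements, so p ≥ 1/6 regardless of effect size.

## Selection classification and enrichment

The `lost` call (final count below the loss threshold, default 10) takes
precedence over abundance-based calls because a count below the detection
floor carries no reliable abundance information — a mutant can be "lost"
even if its pseudocounted abundance ratio looks flat. `depleted` requires
the relative abundance to drop by at least `depletion_fraction` (default
0.5) while still detected; `enriched` requires at least `enrichment_fold`
(default 2.0) increase. The fold thresholds are interpretations — an
"appreciably more/less fit over the whole run" criterion is not uniquely
defined — and are exposed as parameters. Abundances, not raw counts, are
compared, since depth varies between samples.

Enrichment uses the upper-tail hypergeometric test per term with at least
one hit, BH-adjusted across exactly the tested terms, sorted by (q, p).
The background is the post-filter gene universe — the genes the experiment
could have observed — rather than a whole genome, which would inflate
enrichment of anything detectable. GO-DAG ancestor propagation is out of
scope; the annotation is a flat local gene→term table.

## Simulator

Selection acts multiplicatively per generation within phases; hours are
the observable clock but generations drive selection, and true
per-phase generation counts in scale-up runs are rarely reported, so they
are configuration inputs. Defaults: 5 generations per 24 h seed stage, 7
for the glucose batch phase (split across sampling intervals
proportionally to duration), 6 per fed-batch interval, and 2 then 1 for
the post-glucose intervals of non-fed vessels (stationary phase). Serial
transfers optionally bottleneck the pool by a multinomial draw of
`bottleneck_cells` (default 10⁶) cells; recorded truth at a boundary is
pre-bottleneck, since samples are taken from the outgoing culture.
Coefficients with 1 + s ≤ 0 are rejected; lethality is encoded as
s = −1 + ε.

Initial abundances are normalized log-normal draws (σ = 1.0 by default),
giving the heavy-tailed, uneven pool characteristic of colony-scraped
deletion collections; how many strains fall below a detection threshold is
then an emergent property of sequencing depth rather than a dial.

The preset study layout mirrors a two-set scale-up design: a shared
two-stage seed train, two shake flasks and a batch bioreactor sampled to
72 h, and four fed-batch bioreactors (constant feed CF4/CF6, DO-signal
feed DF4/DF6) sampled at 0/5/24/33/48/72/119 h. Default planted stresses
put severe per-generation deficits (s ≈ −0.85 … −0.92) on random gene
subsets during the late fed-batch windows of the constant-feed reactors —
strongest and earliest in CF6, milder in CF4 and DF4, none in DF6 — so
that the planted windows produce extinction-scale diversity loss and the
final-richness ordering CF6 < CF4 ≈ DF4 < DF6. These are qualitative
emulations of an ethanol-stress collapse, not a fermentation model: there
is no ODE for glucose, ethanol, DO or biomass, and drift beyond the
transfer bottleneck (e.g. Wright–Fisher noise during growth) is not
modeled.

FASTQ emission writes one single-end read per count: random prefix, flank,
barcode, random suffix to the read length, constant quality. Substitution
errors hit barcode bases independently (optionally also the flank, to
exercise flank-miss dropout; default off so the recovered fraction follows
(1 − e)^L exactly). The prefix is redrawn when it would create a spurious
earlier flank occurrence, so an error-free emission round-trips exactly
through the counter.

## What the simulations do and do not show

Passing tests demonstrate that the analysis recovers what the generative
model plants: multinomial sampling noise, heavy-tailed pools, transfer
drift, and phase-wise selection. Real Bar-seq data additionally contain
PCR amplification bias, barcode-specific primer efficiencies, index
hopping, chimeric reads, cross-contamination between timepoints, and
biological effects (mutation, clonal interference) that the simulator
deliberately omits; recall/precision measured here are upper bounds on
real-data performance. Reported variance fractions and p-values from any
particular wet-lab study depend on its unpublished count tables and are
not reproduced numerically — only the procedures and their qualitative
behavior are.

## Numerical choices and problem sizes

- Eigenvalues within 1e-9 (relative) of zero are treated as zero in PCoA.
- Permutation p-values use the add-one formula; F ties count as exceeding
  (tolerance 1e-12) so the test is valid, if slightly conservative.
- Degenerate inputs fail loudly: empty gene universes cannot be
  normalized, distance rows summing to zero are rejected, single-group
  PERMANOVA and k ≥ n ordination are errors.
- Default problem sizes in tests and the acceptance script — 2000–3000
  genes, depth 1–2 ×10⁶, 199–999 permutations, 500 calibration
  replicates — were chosen as the smallest sizes at which the statistical
  properties under test (binomial tolerances, type-I error intervals,
  recall/precision bounds) are comfortably resolvable.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; per-sample seeds are spawned from a `SeedSequence` so adding a
  sample does not shift the others.

## Known limitations

- One factor per PERMANOVA call; no interactions, no Mantel/CCA/RDA.
- The block-exchange permutation regime requires exchangeable strata; with
  unequal reactor designs its p-values are approximate.
- NMDS local minima are handled by restarts, not by guarantees; the stress
  surface of small non-Euclidean matrices can retain a worse basin for any
  finite restart count.
- Enrichment treats terms independently (no DAG closure), and the
  hypergeometric model assumes exchangeable genes, ignoring barcode-depth
  detection bias within the filtered universe.
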