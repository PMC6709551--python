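# Methods

This note documents the statistical procedures implemented in `circpanel`,
the choices made where the methods literature leaves the design open, and
what the synthetic data generator does and does not emulate.

## Consensus backsplice-junction calling

Detectors for circRNA backsplice junctions disagree on both sensitivity
and coordinate conventions.  The pipeline therefore (a) converts every
input dialect to a single internal convention — 0-based, half-open
`[start, end)` — on ingest, and (b) merges calls by exact key equality on
`(chrom, start, end, strand)`.  No ±1 bp tolerance window is applied:
fuzzy merging would make "same circRNA" order-dependent, and any residual
off-by-one disagreement between upstream tools is better fixed by
declaring the right dialect.  Strand `.` is a legal value and matches only
itself, since some detectors omit strand.

The ensemble rule accepts a junction in a cell line when at least
`min_tools = 2` detectors report it, each with at least `min_reads = 2`
backsplice-spanning reads.  The read threshold is interpreted **per
tool**: a tool with 1 read does not count as detecting, and the reported
abundance is the arithmetic mean over detecting tools only.  The
alternative reading — count every reporting tool and threshold the mean —
is implemented behind `threshold="mean"` because the defining sentence is
genuinely ambiguous; the per-tool reading is the default since the
threshold is attached to "detected" in the rule's own wording.

Abundance is normalized to sequencing depth:
`norm_reads = mean_reads / library_size × 10⁶` (reads per million mapped
reads).  The per-million scale is a convention choice — only "normalized
by total reads" is prescribed — and is configurable via `scale`.

## Lineage specificity

For gene *j* and lineage *l*,

```
s_j^(l) = ( med(e_j^(l)) − med(e_j^(all)) ) / IQR(e_j^(all))
```

with the IQR computed as Q3 − Q1 using **linear interpolation between
order statistics** (the numpy/pandas default).  The quantile convention is
declared because s is sensitive to it near the calling cutoff.  A gene is
specific to *l* when s > 0.5.  The score is undefined (and no call is
made) when the panel-wide IQR is zero.  s is invariant under panel-wide
affine maps x → a·x + b (a > 0) of one gene's expression — a property the
tests exercise — but not under log transform, so the score is computed on
whatever scale the input matrix carries and the caller must be consistent.
An optional calibration routine (`calibrate_cutoff`) scans cutoffs and
reports the fraction of genes specific in ≥ 1 lineage, supporting the
"choose a cutoff such that about half the genes are specific somewhere"
style of tuning; the fixed 0.5 remains the default because it is the
reproducible anchor.

circRNA detection breadth counts lineages containing ≥ 1 cell line with a
nonzero consensus-matrix entry (i.e., already past the ensemble filter):
exactly 1 lineage → lineage-specific; ≥ `ubiquity_min = 15` lineages →
ubiquitous; otherwise intermediate.  The parental-gene overlap fraction
divides, per lineage, the number of lineage-specific circRNAs whose
parental gene is specific to the same lineage by the number of
lineage-specific circRNAs with any parental-gene assignment; 0/0 is
reported as undefined rather than 0.

## Biogenesis regulator screen

Candidate genes are screened by Spearman rank correlation (tie-corrected,
two-sided p) between expression and the per-line total normalized
backsplice load.  Significance requires both |Rs| > 0.3 and BH-adjusted
q < 0.05.  BH is applied **within each analysis stratum** — the panel-wide
candidate list, or each lineage separately — never pooled across strata;
pooling would let a well-powered stratum distort another stratum's
threshold.  Per-lineage screens only run in lineages with ≥ `min_lines =
10` cell lines.  Genes missing from the expression matrix are carried
through as `status="missing"` records rather than silently dropped.

The EMT score is the mean z-score of mesenchymal markers minus the mean
z-score of epithelial markers, per cell line.  The default marker lists
(mesenchymal: VIM, FN1, CDH2, ZEB1, ZEB2, SNAI1, SNAI2, TWIST1;
epithelial: CDH1, CLDN3, CLDN4, CLDN7) are a documented reconstruction of
a canonical-marker panel and are plain configuration values — any marker
sets present in the z-score matrix can be supplied.

The circRNA-high/low split assigns cell lines strictly above the panel
median load to "circRNA-high"; ties at the median go low.  The
between-condition load comparison is a two-sided equal-variance Student's
t test; the degenerate case (zero variance in both groups) returns p = 1
when the means agree and is an explicit error otherwise.  The GCT/CLS
export writes the standard text formats consumed by external gene-set
enrichment tools; the enrichment statistic itself is deliberately out of
scope.

## Matched-covariate permutation test

The observed set statistic (fraction of genes forming a circRNA, or the
median RBP peak count) is compared against `n_perm = 10,000` random gene
sets of the focal size drawn uniformly **without replacement** from a
background pool matched on one covariate: background genes whose covariate
lies within the focal set's [min, max] range, inclusive.  One covariate is
matched per run; a combined mode (range intersection) exists but is off by
default, mirroring the one-panel-per-covariate presentation style of this
analysis family.

The empirical p uses the add-one convention
`p = (1 + #{permuted ≥ observed}) / (1 + n_perm)` so p is never 0 and the
minimum attainable value at 10,000 permutations is exactly 1/10,001 —
consistent with reporting enrichment as p < 1 × 10⁻⁴.  The enrichment
tail (≥) is the default; a ≤ tail is available.  Reproducibility is
absolute given the seed: the pool is sorted before sampling and a single
`numpy` generator drives all draws.

Two background conventions are exposed.  For the RBP-peak statistic the
natural background is protein-coding genes with a circRNA expressed in at
least 5 cell lines (`background: circ_min_samples`, threshold
configurable).  For the circRNA-forming-**rate** statistic that background
is degenerate — every such gene forms a circRNA by construction, so the
permuted rate is identically 1 — and the pipeline therefore defaults to
all annotated genes minus the focal set for the rate test.  The companion
2×2 comparison uses Pearson's chi-squared with 1 df and no continuity
correction; a zero row or column margin is an explicit error.

## circRNA–feature association screen

For each circRNA, cell lines are split into positive/negative groups
either at the row median of normalized reads (zeros included; strictly
above the median is positive) or by presence.  The two rules coincide
whenever the circRNA is detected in fewer than half of the cell lines —
then the row median is 0 — which is the typical sparse case; the tests
check this identity.

Continuous features (drug AUC, mRNA, protein) are compared with the
two-sided Wilcoxon rank-sum test and a mean-difference effect.  The
single-pair function uses scipy's `method="auto"`, which computes the
exact null for small untied samples and otherwise the tie-corrected,
continuity-corrected normal approximation.  The screen evaluates the
normal approximation for every pair: because the cell-line universe is
identical across features (pairwise dropping applies only to features
with missing values), the rank sum of the positive group is a matrix
product of per-feature global ranks with the group-mask matrix, which
makes screens over thousands of circRNAs run in well under a second; a
test verifies the vectorized p-values match scipy's asymptotic path to
9 decimal digits.  Mutation features use Fisher's exact test with an
odds-ratio effect (reported as `inf` with a flag for perfect
association); no test is prescribed for binary features in the source
methods, so Fisher is a documented reconstruction.

circRNAs enter the screen only when detected in ≥ `min_prevalence = 5`
cell lines (reusing the ≥5-samples convention from the background-gene
definition; the association methods themselves are silent, so this is
configurable).  Pairs whose positive or negative group falls below
`min_group = 3` after intersecting available cell lines are recorded as
skipped, not tested.  BH correction is applied jointly across the whole
screen (per-feature correction by flag), and records with q < 0.05 are
flagged; per-feature summaries count significant associations by effect
sign.

## Synthetic panel generator

The generator provides study conditions for every test; its defaults are
chosen once and documented here.

* **Panel shape**: 5 lineages × 40 cell lines, 2,000 genes, 5,000
  circRNAs, 4 tools, 20 drugs, 50 mutation features.
* **Lineage structure**: 75% of circRNAs are restricted to one lineage
  (mirroring the dominance of lineage-specific circRNAs in real panels);
  restricted circRNAs are present in an allowed line with probability
  0.15, broad circRNAs anywhere with probability 0.05.
* **Reads**: true backsplice read counts are negative binomial (mean 8,
  dispersion 2), scaled by a per-line depth factor (library size over the
  geometric mean of the 20–60 M range) and by exp(0.25 × EMT), where EMT
  is a standard-normal latent factor per cell line that also loads (±0.8)
  on the mesenchymal/epithelial marker z-scores.  Setting the dispersion
  to infinity makes reads deterministic at the rounded mean, giving the
  noise-free limit used by the exact-recovery test.
* **Tools**: sensitivities 0.90/0.85/0.80/0.70 with false-call rate 0.002
  per true junction per line; false calls carry 1 + Poisson(0.6) reads
  and are drawn from per-tool decoy junction universes disjoint from the
  true circRNAs, so tool agreement on a false call is impossible at the
  default overlap of 0 (an overlap knob exists to stress the filter).
* **Planted regulators**: 5 genes whose expression is
  ρ·z(load) + √(1−ρ²)·ε with ρ = 0.6, giving a Spearman correlation of
  roughly 0.55–0.60 against the normalized load.
* **Actionable genes**: 5% of genes, receiving a 4× weight in
  circRNA-to-gene assignment and RBP peak counts with mean 900 versus 230
  for background (negative binomial, dispersion 3) — the same order as
  the published medians (853 vs 210).
* **Drug effects**: 5 planted (circRNA, drug) pairs; the planted circRNAs
  are broad with presence 0.5 so the median split yields balanced groups,
  and the AUC of affected lines is shifted by 1.0 × the noise SD (1.0).
* **Determinism**: one seeded `numpy.random.Generator`, fixed draw order;
  identical config + seed reproduces every table and every written file
  byte for byte.

What the generator does **not** emulate: read-level data (FASTQ/BAM),
correlated tool errors (real detectors share failure modes on specific
junction classes), expression covariance structure between genes, dosage
effects linking parental-gene expression to circRNA abundance, and
batch/site effects.  Passing tests therefore demonstrate correctness of
the statistical machinery and recoverability of planted effects under a
clean generative model — not performance on real sequencing data.

## Test and acceptance problem sizes

The multi-seed recovery experiments run at sizes chosen to keep the whole
suite fast on one CPU: the association-recovery experiment runs the full
default panel (200 lines × 5,000 circRNAs × 20 drugs) for 100 seeds,
which the vectorized screen completes in under two minutes; the regulator
recovery experiment uses 200 seeds of a reduced panel (200 lines, 800
circRNAs, 300 genes, 1 planted regulator + 99 null candidates); the
permutation null calibration uses 500 seeds at 1,000 permutations with a
400-gene background universe, proportioned (40× the focal size) like the
real 3,693-vs-135 analysis so that removing the focal genes barely
perturbs the background distribution.

A power note on planted drug effects: with 1-SD shifts, ~100-line groups
and BH across ~70,000 tests, the planted pairs' z-statistics are
approximately N(6, 1) against a BH threshold near 4.6, so per-pair
recovery is ~90% per seed — all five pairs are recovered on the default
panel, and the averaged false-discovery proportion stays at the BH level,
but occasional single-pair misses on other seeds are expected behaviour,
not a defect.

## Known limitations

* Exact-match junction keying may undercount relative to pipelines that
  harmonize near-identical coordinates across tools; the matching
  tolerance is deliberately fixed at 0 with dialects doing the
  harmonizing.
* The specificity score is quantile-convention- and scale-dependent near
  the cutoff; both are documented rather than hidden.
* Fisher's exact test for mutations and the EMT marker panel are
  reconstructions where the source methods name no procedure.
* The mutation screen runs through the per-pair path (no vectorization),
  so genome-scale mutation matrices are slower than continuous screens.
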