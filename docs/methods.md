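# Methods

This note documents the statistical models behind `baitcall`, the choices
made where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## AP-MS enrichment model

Label-free AP-MS quantifies each prey protein by its spectral count — the
number of MS/MS spectra assigned to it in a capture run. Counts from a
tagged-bait capture are compared against mock captures (beads incubated
with untransfected lysate). Four statistics are computed per prey:

**Fold change** — mean bait-run count over mean control-run count, both
plus a pseudocount (default 0.5). The pseudocount keeps preys absent from
controls finite; 0.5 is common spectral-counting practice and is
configurable.

**Welch t-test** — one-sided (bait > control) unequal-variance t-test on
raw replicate counts. One-sided is the natural direction for an
enrichment screen; a two-sided alternative is available via the
`alternative` argument. When both groups have zero variance the
deterministic limit is returned (0.5 at equal means) rather than NaN.

**Per-run G-test** — for each bait run, the 2×2 likelihood-ratio test
G = 2·Σ O·ln(O/E) on (this prey vs all other spectra) × (bait run vs
pooled controls), with p from χ²(1). Zero cells contribute 0 (the
x·ln x → 0 limit). No Williams correction is applied by default — the
plain G statistic is the one compared against the independent oracle in
the tests. A run counts as *significant* only when p ≤ α **and** the
prey's share of spectra in the bait run exceeds its share in the pooled
controls, making the call one-sided (over-representation).

Each bait run is tested against the **pooled** controls (summed counts
and totals). The experimental design does not pair bait runs with
individual controls; pooling maximizes control depth and is
deterministic. This is a package choice, and the pooling function is
exposed separately so other pairings can be built.

**Bait-level correction** — different constructs capture different
amounts of bait. factor(construct) = mean bait self-counts in the
reference construct / mean bait self-counts in that construct. Factors
are reported rounded to one decimal (the granularity at which such
factors are usually quoted) but applied at full precision to all prey
rows of that construct; the bait's own row is left unscaled. Controls
are mock captures with no bait and get factor 1.

## SAINT-style interaction score

The published SAINT method fits a Bayesian mixture by MCMC; `baitcall`
implements a deterministic SAINT-*style* score, because only the
thresholded score (≥ 0.90) enters the calling rule and determinism makes
the score testable. The model is a two-component negative-binomial
mixture:

* background component: NB with the prey's control mean (floored at 0.1
  so never-seen preys still have a likelihood) and a single dispersion α
  shared across preys, estimated by method of moments pooled over preys
  (α = Σ(v−m)/Σm²; var = μ + αμ²);
* true component: the same NB with mean multiplied by one enrichment
  factor shared across preys, fitted by EM on the bait runs, bounded to
  [2, 100], initialized at 4, tolerance 1e-6, at most 500 iterations.
  Bound violations are clamped and logged.

Per replicate, posterior = π·f_true / (π·f_true + (1−π)·f_bg) with prior
π = 0.1; the score is the mean posterior over a prey's bait replicates
(averaging over replicates first, then thresholding per prey). The score
is monotone in each replicate count and always in [0, 1].

## Consensus calling and domain dependence

A prey is called an interactor iff **all four** criteria hold: fold
change ≥ 2, t-test p ≤ 0.05, G-test significant in ≥ 2 runs, score
≥ 0.90. The call table records each criterion separately so single-point
failures are visible.

Domain dependence compares each called prey's capture-corrected counts
under each domain-deletion construct with its counts under the full-length
bait: ratio = corrected deletion mean / reference mean. *Reduced* requires
ratio ≤ 0.5 plus G-test under-representation (deletion run vs pooled
reference runs) in at least one deletion run; *enhanced* mirrors this at
ratio ≥ 2; otherwise *unchanged*. A reduction is *selective* for the set S
of reduced constructs when every construct outside S shows no >2-fold
downward trend (ratio > 0.5); selective enhancement is symmetric
(ratio < 2 outside S). Allowing S to contain more than one construct
covers joint losses (e.g. a prey reduced by either of two domains). The
significance rule for this comparison (per-run G-test against the pooled
reference runs) is a package choice and configurable.

Network export writes SIF, GraphML and a node-attribute TSV, ordered by
protein id for byte-reproducibility. Node shading is a monotone map of
log2 fold change min–max scaled to [0.1, 1.0] over the called preys.

## RNA-seq filters

**RPKM** = count / (gene length in kb × library size in millions). The
library size is the total mapped reads, which may legitimately exceed the
column sum of a table restricted to a gene subset.

**DE stand-in** — a deliberately lightweight replacement for a full count
modeling package: per-gene NB likelihood-ratio test (null: one rate for
both conditions; alternative: one per condition; library sizes as
offsets) with a single moment-matched common dispersion, plus
Benjamini–Hochberg adjustment. It is calibrated (null rejection fraction
at BH 0.05 stays below 0.05 in the tests) but has less power and less
per-gene adaptivity than tagwise-dispersion methods. The filter cascade
therefore accepts any externally computed table with `log2FC` and
`adj_p` columns, so output from a dedicated DE package can be plugged in
unchanged.

**Transfection-artifact cascade** — keeps genes that (1) change ≥1.6-fold
(linear, either direction) with adjusted p ≤ 0.05 in the bait-vs-tag
comparison, (2) are not significant in the tag-vs-untransfected
comparison at |log2FC| ≥ 1 and adjusted p ≤ 0.01, and (3) reach 100 RPKM
in at least one condition mean. The expression floor is applied to the
max condition mean; all five thresholds live in `FilterConfig`.

**Endogenous estimator** — a transfected cDNA transgene contributes
reads only to the exons it contains. Restricting the RPKM formula to the
gene's transgene-free exons (summed counts over summed length) estimates
the endogenous transcript level; it is undefined (and rejected) when
every exon is shared. In expectation the estimate is invariant to the
transgene expression level.

**Concordance** — pairwise Pearson correlation of per-sample RPKM
profiles, average-linkage clustering on 1−r with scipy's deterministic
leaf ordering. Zero-variance samples are rejected (correlation
undefined) rather than silently dropped.

## Synthetic data

The AP-MS generator draws NB counts with mean = background mean × batch
multiplier × enrichment factor (for true interactors of that run's
construct), using the emulated study layout: 5 mock captures, 4 full-
length-bait captures, 3 per point mutant, 2 per deletion mutant, in two
batches. Defaults:

* background means: lognormal(μ=1, σ=0.8), floored at 0.3 — most preys
  are low-level bead binders, a few sticky and abundant;
* planted interactors' background means: uniform 1.5–6 spectra/run. The
  strongest observed co-captures sit in this regime (a few control
  spectra per run, bait-run counts in the tens at ~8× enrichment);
* dispersion α = 0.02. Within-batch replicate spectral counts of strong
  preys in the emulated study are tightly reproducible (CVs of a few
  percent to ~0.2, i.e. CV² − 1/μ ≲ 0.02); α = 0.02 is the upper end of
  that range;
* batch multiplier 1.2 on batch B; bait capture level 25× its bead
  background in every bait construct (so correction factors are ≈1
  unless perturbed);
* `enrichment_overrides` plant domain-dependent binding: a prey that
  loses binding under one deletion (0.1× its bound mean) and one
  enhanced 4× under another.

The RNA-seq generator draws exon-level NB counts (gene counts are exon
sums) for four conditions in triplicate: untransfected, tag (YFP) alone,
and two bait-expressing conditions. Defaults: 2000 genes (a downsample
of a transcriptome — chosen for test runtime, with effects planted at
realistic expression levels), 5M mapped reads/sample, dispersion
α = 0.01 (BCV 0.1, the standard figure for replicates of one cultured
cell line), 40 tag-responsive genes (|log2FC| 1–2), 23 bait-specific
genes (|log2FC| 1–1.8 at 150–600 RPKM), and one highly expressed host
gene (800 RPKM, 4 exons) whose first three exons are shared with a
30×-expressed cDNA transgene; the host gene also carries a planted
1.4-fold suppression upon transfection.

What the generators do **not** emulate: peptide-to-protein inference and
shared peptides, run-to-run identification dropout, compositional
competition for MS sampling between preys, per-gene dispersion
heterogeneity, GC/length biases, splice-isoform structure, and
correlated (gene-level) overdispersion across exons. Passing tests
therefore demonstrate correctness of the statistics and operating
characteristics under the stated count model, not performance on raw
instrument data.

## Numerical notes and limitations

* NB log-density uses the Γ-function form, continuous in the count, so
  capture-corrected (real-valued) counts remain scoreable; the Poisson
  limit is used below α = 1e-10.
* G on real-valued corrected tables is the same O·ln(O/E) expression;
  its χ² calibration is asymptotic, as for integer counts.
* The EM factor is shared across preys; heterogeneous true enrichments
  are absorbed imperfectly, which lowers scores for preys far from the
  fitted factor. This mirrors the score's intended use as a consensus
  filter, not an effect-size estimate.
* Problem sizes used by the tests and the acceptance script (200
  proteins, 2000 genes, 10 simulation seeds) were chosen to make the
  operating characteristics measurable while keeping a full run in the
  order of seconds.
* The phenotype validator checks that category counts partition the
  total and that any printed percentage matches the recomputed one; one
  published row (47% printed vs 45.7% computed) fails the latter check
  and is reported, not corrected.
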