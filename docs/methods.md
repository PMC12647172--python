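# Methods

This note documents the statistical models implemented in `splicestate`,
the defaults and why they were chosen, what the synthetic-data generators
do and do not emulate, and the numerical conventions that matter when
interpreting output.

## Gene activity calling (`activity`)

**Model.** The accessibility read count k over a gene interval is tested
against a Poisson background. Expected counts are estimated in windows of
1 kb, 10 kb, and 100 kb centered on the gene midpoint (clipped at contig
ends) plus the whole genome; each window contributes λ = (window count /
effective window width) × gene length, and the test uses λmax, the most
conservative of the four. The p-value is the strict upper tail P(X > k).
This mirrors the local-λ logic of accessibility peak callers while staying
analytic for very short genes.

**Gene reads in the background.** By default the gene's own footprint and
reads are excluded from the windowed background (`include_gene=True`
restores the inclusive variant). For a short gene whose own signal is
several-fold above background, an inclusive 1 kb window nearly doubles the
local λ estimate and correspondingly halves the caller's power; excluding
the interval makes the windows estimates of *background*, which is what
the test conditions on.

**Multiple testing and states.** BH runs once over all gene × sample pairs
("global" adjustment; a per-sample flag exists). Per-sample states:
`confident_ON` iff adjusted p < 0.05, `confident_OFF` iff raw p > 0.5,
otherwise `indeterminate`. These two thresholds are exposed because they
are operating-point choices, not model quantities. Gene-level classes use
raw-p medians: genes < 1000 bp with global median p < 0.05 are
`always_ON`; remaining genes with a median p < 0.05 in at least one
subtype are `ON_OFF`; otherwise `OFF`.

**A note on per-sample recall.** At the default study conditions
(gene λ ≈ 2, activity fold 5) the per-sample problem is
Poisson(10)-vs-Poisson(2); even a threshold oracle cannot exceed ~93%
per-sample recall at a 1% false-ON rate, and BH at 5% prevalence sits
lower. Gene-level recovery through the median-p classification is the
caller's reliable deliverable, and it is what the acceptance checks
measure.

**Depth normalization.** `downsample_track` thins bin counts binomially to
a target depth (default 250,000,000 reads) so p-values are comparable
across samples of unequal sequencing depth. Thinning acts on binned counts
because the pipeline operates on coverage tracks, not alignments; for
Poisson-distributed bin counts binomial thinning is distributionally exact.

## Transcript-centric intron retention (`ir`)

**Filtering.** Introns enter scoring only if gene CPM > 1 in every sample
and both flanking-exon read supports are > 10 in every sample individually
(strict inequalities); the rejection log names the first failed criterion.

**Per-intron Q-test.** One control IR ratio is compared with three
treatment ratios by a Dixon-style gap-to-range statistic with the control
as the *designated suspect*: Q = |control − nearest treatment| / range of
all four values if the control is an extreme of the four, else Q = 0 (a
control inside the treatment distribution cannot separate from it; the
classic data-chosen-extreme variant is selectable). The null is Monte
Carlo: i.i.d. standard Gaussians at the same arity with the same
fixed-position suspect convention, 100,000 draws by default, cached per
arity, with add-one smoothing so p ∈ (0, 1]. Q is location/scale
invariant, which makes the Gaussian a canonical null; the intron score is
−log10(p), and a degenerate (zero-range) input scores 0.

**Nested introns.** Overlapping intron annotations of the same transcript
are grouped into connected components and collapsed to one entity scored
by the member median. Collapsing is per transcript: merging across
transcripts would leave entities without a well-defined transcript for the
downstream grouping.

**Transcript significance.** Per transcript the statistic is the mean
entity score, in framework 1 over positive-score introns only and in
framework 2 over all introns. The null draws B (default 10,000) same-size
subsets, without replacement, from the framework-matched global score
pool; empirical p = (1 + #{null mean ≥ observed}) / (B + 1), BH-adjusted
across transcripts per framework; `sensitive` requires both adjusted
p < 0.05. Mean was chosen as the distribution summary (median and a KS
distance are natural alternatives and would slot into the same permutation
scheme). Because the pool is the data itself, the test is self-calibrating
regardless of the intron-score distribution; the framework-2 p retains a
discrete, conservative atom at p = 1 from all-zero-score transcripts
(probability 2^−n under the null), which is inherent to permutation p's on
a statistic with an atom — the framework-1 p is tie-free.

**Delta-IR z.** Per intron Δ = log2((IR_t + ε)/(IR_c + ε)) with
pseudocount ε = 0.01 (ratios can be exactly 0); Δ is standardized against
the global distribution, transcripts are summarized by the mean
standardized Δ, and z compares it to same-size random draws. A global sd
of zero is refused as degenerate.

## Junction residency (`junctions`)

Coverage around each 3′ splice site is binned into 100 × 10 bp bins
oriented 5′→3′ in transcript direction (minus-strand windows reversed), so
bins 0–49 are intron-side. The per-bin expectation is
λ = max(intron-side mean, exon-side mean, global all-junction mean); the
residency score is −log10(min P(X > k)) over the five intron-side bins
adjacent to the junction (bins 45–49). "Five bins into the intron" is read
as the five nearest the splice site. λup/λdown are per-junction and
λwhole global, matching the one global number a cohort-level survey
supplies. No multiple-testing correction is applied inside the score (it
is a ranking statistic, not a test). With λ = 0 a zero count is defined as
p = 1 (no signal is unremarkable) and a positive count is floored to the
smallest representable p with the score capped.

Quantile normalization is classic rank-mean with tie blocks receiving the
mean reference value of their ranks. Fold enrichment divides by
max(matched control, mean of all controls) + pseudocount (default 1) —
the conservative denominator avoids inflated ratios from a single quiet
control.

## Randomization engine (`permnull`)

All empirical nulls draw B uniform same-size subsets without replacement;
p = (1 + #{null at least as extreme}) / (B + 1) on the declared sidedness,
so p is never 0 and floors at 1/(B+1). z = (observed − null mean)/null sd;
a zero null sd (e.g. subset = universe) is flagged degenerate with p = 1.

The splicing-event overlap test partitions events by (type, direction of
ΔPSI; zeros dropped), ranks within partitions by −log10(FDR) × |ΔPSI|,
and for each depth k compares the observed triple top-k intersection with
B independent random rankings. k\* is the *largest* depth with p < 0.05
(the alternative "smallest depth where significance is lost" is a config
switch); the final event set is the triple intersection at k\* filtered to
FDR < 0.05 in all three lists and a PSI spread across samples > 0.1. Note
that at depth k = N the intersection is deterministically N, so the last
depth of a partition is never significant; with identical rankings every
testable depth sits at the smoothed floor.

## Survival (`survival`)

Per gene, eligible samples are the confident-ON/OFF calls within subtypes
that contain both states; subtypes uniform in predicted state are excluded
(they contribute no within-subtype contrast and would import
tissue-specific hazard differences), and analyses are restricted to genes
< 400 bp. Multi-copy families are analyzed as one unit whose per-sample
state derives from the median member p-values. The Cox model is fit
stratified by subtype (Efron ties; stratification is the standard device
for "restricted to subtypes", with pooled fitting available), and the
reported Wald statistic is signed (β/SE) because downstream type ranking
distinguishes adverse from protective genes. Non-estimable fits (constant
covariate, no events in a state group, non-convergence) are excluded from
rankings. RNA-type ranking feeds median Wald statistics through the
randomization engine with same-size draws from all estimable genes.

Partial-likelihood fitting is delegated to `lifelines.CoxPHFitter` with a
tight Newton precision (1e-13) so estimates agree with direct likelihood
maximization to ~1e-6; the test suite cross-checks a 4-observation
instance against an independent brute-force maximizer.

**Precision limitation.** With n = 500 samples and 30% censoring, the
Fisher information of a balanced binary covariate gives se(β) ≈ 0.107, so
single-cohort hazard-ratio estimates around a true HR 1.5 scatter beyond
[1.3, 1.7] in roughly a fifth of cohorts; subtype stratification (with two
uniform subtypes contributing nothing) widens this further. Tighter
recovery needs ≈ 675+ events. This is a property of the estimator, not of
the implementation, and the acceptance suite reports it honestly.

## Sensitivity classifier (`sensitivity`)

Elastic-net logistic regression (scikit-learn saga). Each of B = 100
simulations: bootstrap the rows, oversample the minority class to parity
by random duplication (interpolation-free; a planted-realism choice, since
duplicated minority rows are what resampling a small sensitive set
produces), standardize features on the training set only, select
(l1_ratio, strength) by stratified cross-validated log-loss over the grid
l1_ratio ∈ {0.1, 0.5, 0.9} × strength ∈ 10^{−3..1}, and score AUC on the
out-of-bootstrap rows. The out-of-bootstrap fold is the evaluation set
because leave-one-out alone yields no stable AUC per simulation;
leave-one-out remains the small-sample fallback inside hyperparameter
selection. The reduced model refits the same scheme on a handful of
selected features and reports each row's mean predicted probability over
simulations.

## Proteomics filter (`pulldown`)

Intensities are normalized to each sample's total. A protein is enriched
iff it has ≥ 1 unique peptide in both bait replicates and its minimum log2
ratio — minimum over both controls *and* both bait replicates — exceeds 2.
The min-min reading matches a "minimum log2(intensity ratio)" summary; a
mean-based variant is a flag. Zero control intensities are floored to the
smallest nonzero normalized value of that control column before logs.

## Synthetic data (`sim`)

Each generator draws from an RNG stream sub-seeded by the master seed and
a stable hash of the generator name, so outputs are byte-reproducible and
adding a generator never perturbs the others.

- *Accessibility*: one linear contig, genes of 200 bp every 2 kb between
  100 kb flanks; bin counts Poisson with rate 0.01 reads/bp × a smooth
  log-normal local multiplier (nodes every 50 kb, sd 0.2), ×5 over the 5%
  planted active genes in every sample (8 samples). This makes the
  expected gene count λ ≈ 2 — deliberately marginal, the regime where the
  local-background machinery matters.
- *IR tables*: 1000 transcripts × 5 introns; background base IR ~
  Beta(2, 5); sensitive transcripts (2%, the study-scale prevalence of
  knockdown-responsive transcripts) get base IR uniform in
  [|effect|+0.05, |effect|+0.20] — partially retained introns, the regime
  where an additive −0.3 shift restores near-complete splicing — shifted
  by the effect in all three treatments. Replicate noise is Gaussian on
  the logit scale (sd 0.05), which keeps ratios strictly inside (0, 1) and
  shrinks absolute noise toward the boundaries as deeply sequenced IR
  estimates do. 5% of introns are planted to fail one quality filter.
- *Junctions*: 100-bin Poisson(1.0) backgrounds; 5% of junctions get a
  10× rate in the five junction-adjacent intron bins.
- *Survival*: exponential event times, hazard 0.1 × exp(β·state) with
  β = log 1.5; exponential censoring whose rate is solved numerically so
  the expected censored fraction equals 0.3; 6 subtypes, two of them
  state-uniform to exercise the exclusion rule. Only the first gene's
  state drives the hazard; additional state columns are exchangeable
  nuisance genes.
- *Event lists*: one shared universe (500 events, 5 types); per-list
  latent scores follow a Gaussian copula at rank correlation ρ; within
  each (type, direction) partition rank i maps to FDR = i/(M+1) and |ΔPSI|
  decreasing in rank so the published ranking key reproduces the ranks
  exactly.
- *Proteomics*: log-normal intensities; 2% planted enriched proteins at
  24–64× both controls with guaranteed peptides; decoys with high ratios
  but a missing peptide in one replicate exercise the peptide rule.

**What the generators do not emulate:** alignment artifacts, fragment-length
or GC bias, overdispersion beyond the smooth background multiplier,
correlated introns within a transcript beyond the shared planted shift,
informative censoring, batch effects, or peptide-level proteomics noise.
Passing tests therefore demonstrate that the statistics behave as designed
under their own model assumptions — calibrated nulls, recoverable planted
effects — not that those assumptions hold in any particular real dataset.

## Problem sizes

The test and acceptance runs use 1,000 genes × 8 samples for activity
calling, 1,000 transcripts × 5 introns (B = 2,000 for calibration, 10,000
for power) for IR, 10,000 junctions for the residency null, 100 cohorts of
500 samples for Cox recovery, 200 rows × 100 bootstrap simulations for the
classifier, and 100,000 draws for the Monte-Carlo/hypergeometric
comparison — sizes at which the Monte-Carlo error of each check is small
relative to its tolerance.
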