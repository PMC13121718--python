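# Methods

This note documents the statistical models, the synthetic-data design, the
numerical choices, and the known limitations of the package.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The measurement problem

Vesicle-export transcriptomics samples a cell population's transcripts from
membrane vesicles budded into the supernatant, leaving the cells alive.
Three systematic differences from lysate RNA-seq drive the analysis design:

1. **Positional bias.** The export machinery binds the poly(A) tail, so
   read depth in the exported fraction decays with distance from the
   transcript 3' end; lysate coverage is approximately uniform.
2. **Compartment bias.** Mitochondrial transcripts are largely excluded
   from the exported fraction; most other transcripts are exported near
   parity, giving a sharply peaked log10 export-ratio distribution.
3. **Low input.** Vesicle RNA amounts are small; amplification-heavy
   library preparation produces low-complexity artifacts and PCR
   duplicates that must be filtered before quantification.

## Read-pair filter

For each mate, all overlapping k-mers are tabulated and the *fraction of
k-mer positions whose k-mer occurs exactly once within the read* is
computed.  A pair is retained iff both mates reach the threshold (default
0.8), both carry a consecutive mapped CIGAR stretch (ops M/=/X, broken by
any other op) of at least 80 nt when the CIGAR check is on, and both are
flagged proper pairs.  Both comparisons are inclusive on retention (a
fraction of exactly 0.8 or a stretch of exactly 80 passes); a read shorter
than k scores 0 and is dropped.

*k* is not a sharp parameter: homopolymer and low-complexity artifacts fail
at any reasonable k, so the default k = 21 (a standard short-read k-mer
size) is exposed as a knob but rarely worth changing.  "Unique" is counted
over k-mer *positions* (occurrences), not distinct k-mers; the filter is
idempotent and retention is monotone in the threshold (both are property
tests).  Duplicate removal matches the exact (mate1, mate2) sequence pair
and keeps the first occurrence, making the retained *set* independent of
input order up to choice of representative.

## Coverage model

Per-position depth counts reference-consuming CIGAR ops (M, =, X, D, N);
soft-clips and insertions do not cover.  For transcript j with length L_j,

    C'_ij = C_ij / Σ_m C_mj × L_j ,

i.e. area-under-the-curve normalization followed by a length rescale so the
normalized coverage averages exactly 1 per position (an identity the
acceptance suite checks to 1e-9; the denominator runs over the full
transcript, which is the only reading that makes the identity exact).
Zero-coverage transcripts are excluded with a warning rather than emitting
NaNs.  Metagene profiles anchor each normalized vector at the transcript
3' terminus (distance 0 = last base), average per position across
transcripts and replicates, and bin at 10 nt over a 3 kb window;
transcripts shorter than the window contribute only to the bins they reach,
and the per-position contributing-transcript count is reported.  The
supernatant/lysate per-bin ratio is NaN (undefined), never infinity, where
the lysate mean is 0.

Finite fragments impose an edge effect: within one fragment length of the
transcript ends, coverage ramps up from zero in *both* compartments.  The
supernatant-decay/lysate-flat contrast is therefore evaluated beyond one
fragment length (300 nt by default) from the 3' end, and monotonicity of
the supernatant profile is asserted after smoothing to 250-nt bins (about
half the decay scale), below which bin-level sampling noise dominates.

## Export statistics

CPM divides by the column sum (pseudocounts, e.g. 1e-3 for log display, are
added *after* scaling); TPM divides counts by transcript length before
rescaling columns to 1e6, and any subset can be renormalized back to 1e6.
Export ratios are computed per matched supernatant/lysate replicate pair on
genes with lysate expression ≥ 1, log10-transformed, histogrammed on a
shared 70-bin grid, and summarized as the per-bin mean density ± 1.96×SEM
across pairs.  Detection rates rank genes by mean source-compartment
expression (ties broken by feature id for determinism), split them into 50
equal-size quantiles, and score a gene as detected only when it is > 0 in
*every* target replicate.  Length-binned concordance computes Spearman's ρ
for every supernatant×lysate replicate pairing (9 for triplicates) per
length bin; bins with fewer than 3 transcripts are undefined.  CV uses the
sample standard deviation (ddof = 1) and excludes mean-zero genes.

Spike-in quantification scales the known spiked mass by the ratio of
non-spike to spike fragments; molecule counts use a mean mRNA length
(default 1500 nt) and an average residue mass of 340 Da (the approximate
ribonucleotide-monophosphate residue mass — an explicit approximation
knob).  Per-cell-per-day rates divide by cell-days computed as
n₀ · Σ_{i=0..d} 2^i for d divisions over the culture (7·n₀ for two
divisions over three days); the integration rule is a package choice,
exposed and documented, since only the division count is a biological
assumption.  Particle counts derive from capsid-monomer measurements at
2500 monomers per particle.

## Negative-binomial GLM engine

Counts are modeled as NB(μ, α) with variance μ + αμ² and log link;
library depth enters as the offset log s_j with median-of-ratios size
factors (reported as computed, no renormalization).  Coefficients are
maximized by Newton iteration on the observed Fisher information with step
halving, converging at a 1e-10 coefficient change; standard errors come
from the observed information at the optimum.  For α below 1e-6 the
log-likelihood is evaluated as the Poisson log-likelihood plus its
first-order α correction, avoiding the catastrophic cancellation of the
exact gammaln form at tiny dispersions.

**Dispersion.** Per gene, α is estimated by maximizing the Cox–Reid
adjusted profile likelihood (APL), alternating with mean-model refits; the
CR term −½ log det(XᵀWX) removes most of the downward bias the plain
profile MLE suffers when the mean model absorbs several degrees of freedom
at small n.  For testing, per-gene estimates are additionally pooled by
empirical Bayes: each log-dispersion gets a sampling variance from its APL
curvature, a consensus dispersion is found by maximizing the *summed* APL
across genes (a nearly unbiased common estimate even at a handful of
samples), and the excess of the observed spread over the sampling variance
sets the prior variance τ².  Posterior-mean log-dispersions
w·log α̂_g + (1−w)·log α_common with w = τ²/(τ² + v_g) are plugged into the
tests.  When all genes share one dispersion τ² → 0 and every gene gets the
consensus; heterogeneous dispersions keep most of their per-gene estimate.
This pooling is what makes the χ² reference calibrated at the design sizes
this pipeline targets (3 + 6 samples); with raw per-gene estimates the LRT
rejects 9–11% at nominal 5% because dispersion underestimates correlate
with inflated statistics.  The unmoderated estimator remains available as
`estimate_dispersion`.

**Tests.** The LRT uses Λ = 2(ℓ_F − ℓ_R), clipped at 0, against χ² with df
equal to the parameter difference; the dispersion is estimated once under
the full model and shared by the reduced fit so the likelihoods are
comparable.  Spline designs use a natural cubic spline basis (truncated
power construction, linear beyond boundary knots, knots at quantiles of the
distinct times, K = 4 by default — the spline order is a package choice and
exposed).  The single-course time test gives each replicate line its own
intercept, present in both full and reduced models, so df = K regardless of
replicate count.  Wald tests operate on the log2 scale (natural-log
coefficients divided by ln 2): `standard` is two-sided on β = 0;
`greaterAbs` tests H0 |β| ≤ θ via z = (|β| − θ)/SE with doubled tail;
`lessAbs` is the intersection–union test p = max(Φ((β−θ)/SE), Φ(−(β+θ)/SE)).
BH adjustment is step-up with monotonicity enforcement.  LFC shrinkage uses
a normal prior with variance estimated from the marginal spread of the
estimates (posterior mean β·τ²/(τ² + SE²)); it strictly reduces magnitudes,
is used for effect-size reporting only, and never feeds test decisions.
Exact numerical agreement with any established DE framework is a non-goal;
calibration and power are demonstrated by simulation instead.

## Evaluation layer

Ground truth labels genes positive when the lysate `greaterAbs` test (θ = 1
log2 unit) is significant at FDR < 0.05 and negative when `lessAbs` is;
everything else is unlabeled and excluded from curves.  Supernatant
adjusted p-values are negated to serve as scores (smaller p = more
positive); ROC and PR curves and trapezoidal AUCs come from scikit-learn,
with the PR trapezoid taken along the curve's own point order (re-sorting
tied recalls would mispair points).  The random-classifier precision equals
the positive prevalence and is reported.

Sliding-window DE compares samples in days [t−2, t−1] against [t, t+1] for
each anchor day t (stride 1; non-integer times floored to days; T daily
points yield T − 3 comparisons); windows with fewer than 2 samples on
either side are skipped with a warning.  Preranked GSEA uses the weighted
Kolmogorov–Smirnov running sum with weight exponent 1, a gene-label
permutation null (same-size random sets), NES = ES / mean |null ES| of
matching sign, a +1-corrected permutation p, and BH across sets; a set
covering the whole universe has ES = 0 by convention, and sets with fewer
than 3 members in the ranked universe are skipped.  Time-to-peak ordering
sorts row-centered log2(x + pseudocount) profiles by the time of maximum,
ties broken by gene id.  Contraction frequency detects peaks in the mean
frame-intensity trace with a 0.3 s refractory distance and a prominence of
0.5 trace standard deviations (engineering defaults), and reports
(n_peaks − 1)/span; fewer than 2 peaks is undefined (None).

## Synthetic-data design

The generators emulate the statistical structure the analysis assumes, not
any particular dataset:

* **Paired counts**: lysate gene means log-uniform over four decades,
  scaled to the target library size; supernatant means are the lysate means
  times 10^N(0, σ) (σ = 0.15 by default — the "sharply peaked at parity"
  regime; the lognormal form is a modeling choice, as only the peaked shape
  is established) times a mitochondrial depletion factor (0.02) for the
  mitochondrial gene fraction; counts are NB with dispersion 0.05,
  triplicate per compartment.
* **Aligned reads**: 300-nt fragments with 100-nt mates in transcript
  coordinates; supernatant fragment 3'-ends sit at a truncated-exponential
  distance (scale 500 nt) from the transcript 3' terminus, lysate uniform
  — the simplest monotone-decay model consistent with the positional-bias
  signature.  Configurable fractions of homopolymer pairs, exact-duplicate
  pairs, and spike-in-mapping pairs.
* **Time courses**: three lineages sampled daily over a week in triplicate;
  log means follow the full interaction model (baseline + lineage shift +
  shared spline + lineage×spline), with designated gene fractions carrying
  shift-only or trajectory effects and the truth table emitted alongside.
* **Two-condition counts**: NB with user-specified per-gene log2 fold
  changes; unbalanced designs supported.

All generators are deterministic under a fixed seed.  What they do *not*
model: sequencing errors and base qualities, splicing and isoform
switching, GC/positional quantification bias, batch structure, and
library-preparation chemistry.  Passing tests therefore demonstrate the
*statistical* correctness of the pipeline under its assumed data-generating
process, not robustness to every artifact of real libraries.

Two structural facts about the simulations matter for interpretation:
size-factor normalization absorbs any fold change shared by all (or most)
genes, so effect recovery is only meaningful when effect genes are a
minority; and the export-ratio spread measured from counts includes
counting noise on top of the biological spread, so recovery of the
generator's σ within 10% is asserted at depth and dispersion
(library 5e6, α = 0.02, 5000 genes) where the biological term dominates.

## Problem sizes

The self-contained checks run at: 2000 genes × 9 samples for null LRT
calibration; 1000 genes for spline specificity and 300 (7 time points × 3
replicates × 3 lineages) for spline power; 1000 genes × 30 samples for
coefficient bias and Wald coverage; 5000 genes for export-ratio recovery;
30 000 read pairs per compartment for the coverage contrast; 10⁴ genes for
the null-ROC band; 1000 random cases for each filter oracle.  These sizes
put Monte-Carlo error comfortably inside the asserted bands while keeping
the full suite and the acceptance script each under a minute of CPU.

## Known limitations

* Genome-coordinate (spliced) alignments, BAM/CRAM, and strand-resolved
  depth are out of scope; the pipeline lives in transcript coordinates.
* The LFC shrinkage is a light normal-prior scheme, not a heavy-tailed
  prior; shrunken values are descriptive.
* Dispersion pooling assumes a unimodal log-dispersion distribution across
  genes; strongly multimodal dispersion structure would be over-pooled.
* The GSEA permutation null permutes gene labels, not phenotypes, which is
  the appropriate null for preranked inputs but anticonservative when
  genes are strongly correlated.
* `lessAbs`/`greaterAbs` interval tests rely on the normal approximation of
  the Wald statistic; at very low counts the LRT-based tests are the more
  reliable axis.
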