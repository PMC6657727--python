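# Methods

## The model

The genome is traversed base by base. The hidden state `S_t ∈ {1..n}`
(default n = 5) represents the functional importance of position `t`; the
observed variable `y_t` is the insertion count at `t` transformed as

    y_t = 0                      if count ≤ 1
    y_t = round(log2 count)      otherwise  (round-half-to-even)

so that zero and one insertions share an observed state — with rounded
log2 counts they are indistinguishable anyway, and treating them together
is the better-fitting choice (a `plus_one` variant, rounded log2(count+1),
is implemented behind a flag but non-default). Each state emits from a
zero-inflated Poisson (ZIP) regression

    y_t | S_t = s  ~  ω_s δ₀ + (1 − ω_s) Poisson(λ_st),
    log λ_st = β0_s + β1_s nuc_t + β2_s imss_t

where `nuc_t` is nucleosome density after a rank-based inverse-normal
transform (Blom offset 3/8, average ranks for ties, pooled across
chromosomes; missing values are set to the median of the transformed
series, ≈0) and `imss_t` is the insertion motif similarity score. The
zero-fraction ω_s is one scalar per state, not covariate-dependent. The
hidden chain is first-order Markov with an `n×n` transition matrix; the
observations are conditionally independent given the states.

Assumptions worth stating: insertion biases enter only through the two
covariates; the zero-inflation absorbs both biological intolerance and
undersampling; states are genomically contiguous units, so the
near-diagonal transition matrix does the smoothing.

### Fitting

* Initialisation: uniform initial distribution, transition matrix 0.95 on
  the diagonal and 0.05/(n−1) off it. Emissions are pretrained per state
  on training subsets: the annotation scheme uses essential CDS (S1),
  nonessential CDS (S2), introns+UTRs (S3), unannotated bases (S4) and —
  for the five-state model — the top decile of 100-nt windows by
  unique-insertion density (S5, plain Poisson family, taking precedence
  over the other sets); ncRNA and bare-transcript bases belong to no
  pretraining subset, and S4 uses all unannotated bases (restricting S4 to
  a high-diversity subset was considered and rejected — diversity enters
  this artifact only as a window-level summary track). The quantile scheme instead splits positions into n
  near-equal tiers of window insertion density (rank-based, so ties cannot
  empty a tier).
* EM: scaled forward–backward E-step (numba kernels); M-step updates the
  initial distribution and transitions in closed form and each state's
  (β0, β1, β2, ω) by warm-started L-BFGS-B on the responsibility-weighted
  ZIP log-likelihood with analytic gradients (ω via logit, λ via log
  link). The inner maximisation is capped at 15 L-BFGS iterations per EM
  step — a generalised EM step that preserves monotonicity (each partial
  maximisation starts from the current parameters) while cutting the
  M-step cost several-fold. Stopping: relative log-likelihood change
  below 1e-8 or 150 iterations. A likelihood decrease beyond 1e-6
  (relative) or a non-finite E-step aborts with a diagnostic.
* Decoding: Viterbi in log space, ties broken toward the lower state
  index; posterior marginals by forward–backward.
* Label coherence: after EM, states are relabelled by ascending expected
  observation (1−ω)·exp(β0 + β·x_med) evaluated at the median covariates,
  so S1 is always the most depleted. Evaluating at the median rather than
  averaging exp(Xβ) over positions matters: one large fitted slope can
  otherwise dominate the mean rate and misorder a collapsed state.
* BIC = −2L + k ln T with k = (n−1) + n(n−1) + Σ_s params(s), where a ZIP
  emission has 4 parameters and a Poisson emission 3, and T is the number
  of mappable positions fitted.
* Chromosome-scale fits are chunked: each chunk (≥10·n mappable
  positions) is pretrained, fitted and decoded independently, and
  cross-fit consistency is measured as the fraction of overlap positions
  assigned the same state by independent refits of overlapping chunks.

### Identifiability of the ZIP intercept

When λ → 0 the ZIP likelihood develops a flat ridge: (λ, ω) pairs with
matching zero probability are nearly indistinguishable, because the
probability of observing ≥2 events — the only feature separating "rare
Poisson" from "zero-inflated" — vanishes. The intercept of such a state is
not estimable and EM may park ω at 0 with a compensating β0. The
parameter-recovery experiment (`simulate.recovery_config`) therefore uses
intercepts (−1.0, 0.5, 2.0, 3.5, 5.0) — spaced 1.5 on the log scale with
every rate bounded away from zero — and zero-fractions (0.6, 0.45, 0.3,
0.2, 0.1), so that recovery is a well-posed question. Reported recovery
standard errors come from the observed information of the
posterior-weighted emission likelihood (finite differences of the analytic
gradient). The pipeline's own default intercepts (−3.0 … 3.0) keep the
realistic regime where essential coding regions are almost empty of
insertions; there the most-depleted state's intercept is expected to be
unstable, and only its decoded extent — not its β0 — should be
interpreted.

## Insertion motif similarity score

41-nt windows centred on in-vitro insertion sites give per-position
nucleotide frequencies; the contiguous 20-position window maximising the
number of positions whose composition deviates from the genome-wide
composition by ≥1% for some nucleotide is selected (ties broken toward
the window whose centre is nearest the insertion point, then leftmost).
Probabilities are floored at 1e-4 and renormalised before logs. Scores use
the natural logarithm (any base rescales scores and the IMSS slope
jointly; one choice has to be fixed). The genome scan anchors the score at
position `t` on the 20-mer occupying the motif's offsets relative to a
notional insertion at `t` — the same geometry used in learning — and by
default scores both strands and keeps the maximum (the motif is
near-palindromic; `stranded="plus"` reproduces a single-strand scan).
Windows leaving the chromosome or containing N are missing; missing IMSS
is imputed as 0 (the background score) when building the HMM series.

## Site calling

The deduplication key is (chrom, pos, strand, UMI), with the first record
in input order surviving; keying on the UMI alone (provided as
`umi_only=True`) would erase genuinely independent insertions whose
10-mers collide, which contradicts counting insertions per position.
Records with malformed UMIs are rejected and counted. Mapping quality
< 30 drops a record; insertions at the same position on opposite strands
are distinct sites. The insertion coordinate convention: a record's `pos`
is the first genomic base after the transposon junction on the read
strand. Mappability: a base is kept iff its 500-nt window retained ≥90%
of prefilter reads after quality filtering; zero-read windows count as
fully retained (absence of reads is exactly the signal the HMM models and
must not be masked), and the last partial window is evaluated on its
actual span. Unmappable positions are excised from the series before
fitting rather than treated as missing emissions — the analysis universe
is the mappable genome.

## Segmentation and boundary null

HDEs are maximal runs of one decoded state; unmappable gaps break runs, so
the elements exactly tile the mappable genome. S4/S5 elements (short,
insertion-rich) are dropped before boundary analysis. Each retained edge
is compared to the nearest annotation edge on the same chromosome
(strand-agnostic); at coordinate ties the edge type follows a fixed
priority (5'-UTR, 3'-UTR > transcript > CDS > ncRNA), then the left
neighbour. The null keeps the number and lengths of elements per
chromosome, places them uniformly at random (overlaps permitted,
seed-controlled), repeats `n_null` times and pools the edge distances; the
observed and null distance distributions are compared with a two-sided
Wilcoxon rank-sum test. Calibration was checked by placing the elements
themselves at random: the resulting p-values are uniform.

## Windows, threshold, genes

100-nt non-overlapping windows carry unique strand-resolved insertion
sites, mean count per base (zeros included), mean decoded state (only for
windows ≥95% mappable, so low-mappability windows cannot masquerade as
depleted), mean conservation/diversity, and an annotation class assigned
only when one class covers 100% of the window (precedence eCDS > nCDS >
UTR/intron > ncRNA > unannotated). Window state categories: 1 and 2
require the mean to be exactly 1 or 2 (frequent, because decoded states
come in long constant runs); 3–5 accept means within 0.5. Rank tests are
two-sided Mann–Whitney, exact for small tie-free samples and
normal-approximated otherwise; outlier trimming is never applied to
statistics. The model-free threshold is the 95th percentile
(linear-interpolation definition; the alternative definitions move the
threshold by at most one insertion) of window insertion density over
windows fully inside essential CDS; windows strictly below it are called
insertion-depleted. Gene metrics use the whole gene span by default
(CDS-only behind a flag) with insertions/nt computed over the mappable
span; genes with zero mappable length are excluded and reported.
Correlations are Pearson and Spearman with the shared-gene count.

## The synthetic generator

The generator is the statistical twin of the analysis, not a replica of
any sequencing run. It emulates: annotation-class-dependent insertion
depletion (true states are piecewise-constant by annotation — essential
CDS 1, nonessential CDS 2, UTR/intron/ncRNA 3, unannotated 4, plus planted
sub-100-nt state-5 segments — because states are conceived as functional
units, which lets tests ask directly whether segmentation recovers
annotation boundaries); nucleosome bias (stationary AR(1) with ρ = 0.99
through a softplus, shifted +1 in coding bases — autocorrelation is the
property the normal-score transform must survive — with 5% missing
values); the sequence preference (a planted T···A motif, T two bases
before and A three after the insertion point, echoing the TNNNNA
preference); PCR duplication (Poisson(0.25) extra copies per insertion
unit sharing the UMI); UMI collisions (UMIs uniform over 4^10, collisions
allowed); and low-mappability regions (window-aligned regions whose reads
get sub-threshold mapq with probability 0.5). Layout defaults approximate
a gene-dense yeast genome: 22% essential CDS, 33% nonessential CDS, 15%
UTR/intron, gamma-distributed element lengths (CDS mean 1.4 kb, 5'/3'-UTR
150/250 nt, introns 60 nt in half the genes), a few ncRNAs and planted
state-5 segments per 100 kb.

It does not emulate: read sequences or alignment (records carry only a
mapq flag), donor-plasmid carry-over, chromosome-end repeat structure,
mitochondria, transposon footprint effects on neighbouring bases, or
condition-dependent fitness. Passing tests therefore demonstrate that the
estimator chain is correct and well-calibrated under its own model
assumptions — not that those assumptions hold for any particular real
library.

In-vitro sites are sampled with probability ∝ exp(IMSS) on the plus
strand; on an i.i.d. background genome this makes the sampled 20-mer
distribution exactly ∏ p_i(a_i), so learned frequencies are directly
comparable to the planted motif. Gene knockout fitness is simulated as
0.3 (essential) or 1.0 (nonessential) plus N(0, 0.15) noise — a noisy
monotone function of tolerated disruption.

## Problem sizes and numerical choices

Desk-scale experiments use 50–200-kb genomes (the model-selection
experiment tiles a 1-Mb genome into ten 100-kb subsets; chromosome-scale
fits are chunked into ~100-kb pieces). Coordinates are 0-based half-open
internally, converted only at file boundaries (GFF3 1-based inclusive,
bedGraph half-open). Rates are clipped to exp(±30); optimiser bounds are
β0 ∈ [−12, 12], slopes ∈ [−10, 10], logit ω ∈ [−12, 12]; an all-zero
training subset short-circuits to ω = 1 with β0 at its lower bound,
flagged. The no-covariate ZIP MLE satisfies the zero-truncated-Poisson
identity m₊ = λ/(1−e^{−λ}) (mean of the positive part), which the tests
use as a closed-form oracle. All stochastic components are functions of
(config, seed) only; reruns are byte-identical.

## Known limitations

* The S1 intercept is unidentifiable in deeply depleted data (see above);
  S4/S5 are short and hard to distinguish — both mirror the behaviour
  expected of this model class at scale.
* The quantile training scheme with many states can produce empty decoded
  states on homogeneous subsets; such runs are flagged, not repaired.
* The edge null places elements independently (overlaps allowed); a
  permutation that preserves element adjacency would be stricter.
* Mann–Whitney p-values on heavily tied window counts rely on the
  normal approximation with continuity correction.
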