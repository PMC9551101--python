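# Methods

## The statistical model

### Urn models for gene-set overlap

Every enrichment question in the pipeline is a two-colour urn. For a
universe of N genes of which K belong to a disease list, a miRNA with n
predicted targets and an observed overlap k is scored with the upper
tail P(X ≥ k) — all questions here are enrichment questions, so only
the one-sided upper tail is exposed as the default (lower tails can be
had via the cdf).

Target prediction scores enter through **Fisher's noncentral
hypergeometric distribution**,

    P(X = k) ∝ C(K, k) C(N−K, n−k) ω^k,

normalised over the support. Fisher's variant (the
conditional-independence construction: independent biased Bernoulli
draws conditioned on the total) was chosen over Wallenius' because no
sequential sampling order is implied by the problem; Wallenius' exact
numerics are out of scope. ω = 1 reduces every computation to the
central case, which is enforced pointwise (≤ 1e−12) in the test-suite.

The production path accumulates the unnormalised log-masses with
`gammaln` and normalises with `logsumexp`, which is stable for
populations of at least 25,000 (checked). A second, exact path over
`fractions.Fraction` serves as an independent oracle for N ≤ ~200;
the float path must agree with it to relative error 1e−9. A third,
fully independent Monte-Carlo oracle (conditioned-Bernoulli rejection
sampling) checks the tail at 1e5 accepted samples within 3 standard
errors. A pmf evaluated outside the support returns 0 rather than
raising, so tail sums are total functions.

### The odds parameter from prediction scores

How target scores should weight the urn is a genuine design choice; we
use

    ω = mean(score of targets inside the disease list) /
        mean(score of targets outside it),

with ω = 1 whenever either group is empty. This mapping is
deterministic, reduces to the central test under uniform scores, and is
monotone in the score advantage of disease-listed targets — the three
properties we consider essential. It is a convention of this package,
not an attested reconstruction of any particular study's weighting. A
Monte-Carlo alternative (weighted sampling of target sets without
replacement, selection weight score/100 for predicted targets, baseline
0.5 otherwise) is available behind `method="mc"` as a sensitivity
check; it is slower and stochastic, and is not the default.

The crossover screen applies a raw p < 0.01 rule per miRNA with no
cross-miRNA adjustment by default (BH is available via `adjust=True`).
The gene universe defaults to all genes appearing in the target table
and can be overridden with an explicit background list; analyses should
state which they used, since K and N (and hence p) depend on it.

### The second-level convergence test

The per-disorder convergence test is central hypergeometric: universe =
the upregulated miRNA set, K = the disorder-associated miRNAs, n = the
REST-targeting miRNAs, k = their overlap, significance at p < 0.05.
Using the upregulated set (rather than all expressed miRNAs) as the
universe is the default because the question is posed within the
upregulated cohort; `universe_mode="all_expressed"` switches to the
full matrix. miRNA identifiers are taken literally; no family or arm
collapsing is ever performed implicitly (supply pre-normalised lists if
needed).

## Differential expression

The DE stage is deliberately self-contained rather than a wrapper
around an external engine. Counts are normalised two ways for two
purposes: FPKM (counts / (length in kb × library size in millions),
library size = column sum) feeds the fold-change filter, and
median-of-ratios size factors (all-zero and partially-zero rows
excluded from the geometric-mean reference) feed the test statistic.

The default `nb_wald` engine:

1. per-miRNA method-of-moments dispersion pooled across both
   conditions, α̂ = Σ(nᵍ−1)(vᵍ−μᵍ) / Σ(nᵍ−1)μᵍ², floored at 1e−8;
2. moderation toward the matrix-wide median dispersion with 10 prior
   degrees of freedom — with 3 replicates per group the raw per-miRNA
   estimate (4 residual df) is far too noisy to referee a Wald
   statistic;
3. Wald statistic on the difference of log normalised means with the NB
   variance μ + αμ², offset 0.5 to keep zero means finite, referred to
   a t distribution with residual-plus-prior df (14 at 3 vs 3),
   reflecting the information the moderation borrows.

At the design point the pipeline targets (3 vs 3, dispersion 0.05) this
test's raw type-I rate sits inside the 99% binomial band around 0.05
over 2000 null miRNAs, and miRNAs planted at fold changes of 20.6,
7.95, 6.70 and 4.62 pass the full ≥2.5-FC/BH filter in ≥95% of 200
simulation replicates — both properties are asserted in the test-suite.

Fold change is (mean FPKM treated + ε)/(mean FPKM control + ε) with
ε = 0.25 FPKM so that all-zero controls give a finite ratio; the 2.5
boundary is inclusive (≥). Only upregulation is filtered for;
downregulation analysis is out of scope. Alternative engines:
`log_fpkm_welch` (Welch's t on log2(FPKM+1)) and `fc_only` (no test;
the sole engine usable with single replicates). Whether the fold-change
filter should use FPKM means or a model-based estimate is ambiguous in
general; this package uses the FPKM-mean ratio and says so.

## qPCR quantification

2^−ΔΔCt assumes a per-cycle amplification efficiency of exactly 2;
efficiency-corrected variants are out of scope. Per replicate,
ΔCt = Ct_target − Ct_reference and ΔΔCt subtracts the *mean* calibrator
ΔCt, so the calibrator condition has rq = 1 by construction and adding
a constant to every Ct of a sample cancels exactly. Replicates are
aggregated on the rq scale by default (mean ± SEM, the plotting
convention); `aggregate="log"` averages ΔΔCt first. Dual reference
genes can be combined by arithmetic mean of their Cts (geometric mean
of implied quantities) via `combine_references`; single-reference is
the default.

ChIP enrichment uses the standard percent-of-input convention with
dilution adjustment, %input = 100 · 2^((Ct_input − log2(1/f)) − Ct_IP)
for input fraction f. This formula is a field convention implemented as
such, not a reproduction of any specific study's computation.

## Synthetic data: what it emulates and what it does not

`simulate_counts` draws negative-binomial counts (variance μ + αμ²,
dispersion default 0.05) with log-normal per-miRNA baselines (median
150 normalised counts, σ = 1, clipped to [20, 5000]) and log-normal
library sizes around 5×10⁶ reads — a desk-scale stand-in for deep
small-RNA libraries. Planted miRNAs multiply the treated-condition mean
by their fold change; the default plants four miRNAs at 20.6, 7.95,
6.70 and 4.62. `simulate_targets` draws Poisson-sized target sets
(mean 45) from a 2000-gene universe with Uniform(50, 100) scores;
planted disorder-miRNAs oversample disease genes with selection weight
5 by default.

What the generators do **not** emulate: GC/length biases, miRNA
families and cross-mapping, correlated expression between miRNAs,
batch effects, isomiR ambiguity, or realistic target-score
distributions. Passing calibration and recovery tests on these
simulations demonstrates the statistical machinery behaves as designed
under its stated model; it does not certify performance on real
libraries, where dispersion varies with mean and identifiers are
messy.

### The study fixture

`paper_fixture()` is a constant, not a simulation: a fully synthetic
dataset designed so that the real pipeline recovers a specific
published pattern of cardinalities (56 upregulated; 43/34/15
disorder-associated; 11 REST-targeting with overlaps 11/10/5; a
5-member core). Construction choices that follow from that purpose:

* a 1000-miRNA matrix in which the 56 planted miRNAs are a small share
  of the library mass — FPKM fold changes are compositional (library
  size is the column sum), and planting a large fraction of the matrix
  would compress the realised fold changes below their planted values;
* planted fold changes 6–16 at dispersion 0.02, decisively clear of the
  2.5-fold and adjusted-p thresholds, so the designed survivor set is
  recovered exactly on every run;
* member miRNAs receive 15 targets from each of their disorders'
  disjoint 200-gene lists (plus neutral filler to 45), making member
  overlaps decisive (p ≪ 0.01) and non-member overlaps exactly zero.

Only the five core names (miR-26a, miR-26b, miR-153, miR-181a,
miR-548) are real identifiers; every other miRNA is `mirSIM-`. All
cardinality constraints and the full pipeline recovery are asserted at
construction, which fails loudly if any is violated. Inter-set
freedoms not pinned by the designed overlaps (e.g. |ID∩SCZ| = 24, three
miRNAs in neither set) were fixed once inside the feasible range.

## Numerical and interface choices

* All randomness flows from `numpy.random.default_rng` seeded
  explicitly; generators are pure functions of their config (counts and
  targets use decoupled streams derived from the same seed).
* Degenerate DE rows (identical values in both groups, zero variance)
  get p = 1 rather than NaN.
* Survivor ordering is deterministic: ascending adjusted p, ties by id.
* `bh_adjust` delegates to `statsmodels`' step-up implementation behind
  a validated interface; the test-suite checks it against a direct
  min-over-ranks computation.
* Central hypergeometric pmf/cdf/sf delegate to `scipy.stats.hypergeom`
  with support clamping; the noncentral kernel is implemented here and
  cross-checked against `scipy.stats.nchypergeom_fisher` only in tests.
* Problem sizes in the test-suite (2000 null miRNAs for calibration,
  200 seeds for recovery, 1e5 Monte-Carlo samples for the distribution
  oracle) were chosen to give tight statistical bands while keeping the
  default run in seconds.

## Known limitations

* The NB Wald test is a pragmatic small-m engine; it does not shrink
  log fold changes and its dispersion moderation is a single global
  prior, not a mean-trend fit.
* ω-from-scores is one defensible weighting among several; conclusions
  that depend sensitively on ω should be re-examined with the
  Monte-Carlo route.
* The convergence test conditions on the realised disorder sets; it
  does not propagate uncertainty from the crossover stage.
* No miRNA identifier normalisation (families, arms, species prefixes)
  is performed.
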