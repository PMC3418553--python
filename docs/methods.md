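# Methods

## The screen

The pipeline identifies candidate miRNA→mRNA repressive pairs in a
matched tumor/normal cohort by requiring, for each pair, that

1. both the miRNA and the mRNA are differentially expressed between
   tumor and matched normal tissue (dual gate: paired *t* with BH
   FDR < 0.05 **and** SAM q < 0.05),
2. their expression levels are significantly anti-correlated across the
   pooled samples (Pearson r < −0.5, two-sided p < 0.05, family-wide BH
   FDR < 0.3), with opposite differential directions, and
3. the mRNA is a predicted target of the miRNA in **both** of two
   independent prediction sources.

The anti-correlation criterion means only repression acting through mRNA
degradation is detectable; targets regulated purely by translational
inhibition are invisible to the screen by construction.

## Differential expression

**Paired t.** Per feature, t = mean(d)/(sd(d)/√n) on the per-patient
tumor − normal log2 differences d, two-sided p from the t distribution
with n−1 df. An unpaired (equal-variance two-sample) mode is available
for unmatched designs. BH adjustment is the standard step-up procedure
(via statsmodels), applied once per matrix.

**SAM (paired design).** The moderated statistic is d = r̄/(s + s₀) with
r̄ the mean difference and s its standard error. With s₀ = 0, d equals
the paired t statistic exactly.

* **s₀ selection** (`s0="auto"`): candidates are percentiles
  0, 5, …, 100 of the s distribution. Features are binned into
  s-quantile windows (min(100, m/10) windows); for each candidate the
  coefficient of variation of the per-window MAD of d is computed, and
  the candidate with the smallest CV wins, ties (within 1e-12) going to
  the smallest candidate. If every window degenerates the fallback is
  median(s), with a warning. When some features have s = 0 (possible
  after quantile normalization of small matrices, see below), zero
  candidates are dropped so d stays defined.
* **Null distribution**: sign flips of the per-patient difference
  vectors — exhaustive (all 2ⁿ flips) when 2ⁿ ≤ 4096, otherwise 1000
  flips sampled with the run seed. Sampled mode refuses fewer than 10
  permutations.
* **Calling and q-values**: order statistics d₍ᵢ₎ are compared with
  their permutation expectation d̄₍ᵢ₎. For each δ in a grid (default 60
  points spanning [0, max|d|]) the upper cut is the smallest d₍ᵢ₎ with
  displacement ≥ δ and the lower cut the largest d₍ᵢ₎ with displacement
  ≤ −δ; features beyond the cuts are called. The FDR estimate at δ is
  the median count of permutation statistics beyond the cuts divided by
  the observed call count, with the null proportion π₀ fixed at 1
  (conservative). A feature's q is the minimum FDR over all δ at which
  it is called; never-called features get q = 1. The exhaustive-mode
  q-values are verified against an independent brute-force enumeration
  oracle in the test suite.
* The permutation count and δ grid are defaults of this implementation;
  they are configurable via `SamParams`.

**Degenerate inputs.** In matrix-wide calling, a feature whose paired
differences are constant gets t = ±∞, p = 0 (or t = 0, p = 1 when the
constant is zero) instead of aborting the run; the single-feature
`paired_t`/`sam_statistic` operations raise instead, since for a single
feature a zero-SD difference is more likely a data error. Constant rows
are a hard error in `zscore_rows`, as are missing values everywhere
(they are not imputed; the expected input is complete log2 matrices).

## Preprocessing

Detection-flag filtering keeps a feature when ≥ `min_fraction` (default
0.75) of samples carry **all** required flags (miRNA arrays:
IsGeneDetected, WellAboveNeg; mRNA arrays: IsFound, IsWellAboveBG,
IsSaturated). The fraction is this package's choice; the flag names come
from the array platform. Probe-level summarization is out of scope; the
between-array step — quantile normalization — is implemented directly:
each column's sorted values are replaced by the across-column mean of
sorted values, ties within a column receiving the mean of the quantile
values their ranks span (the common dialect; dialects differ, hence the
explicit statement). The transform is idempotent and makes all column
distributions identical, which the tests assert on random matrices.

Quantile normalization of *small* matrices can leave a feature with
identical values in every tumor column and every normal column (its rank
never changes), producing constant paired differences; the degenerate
handling above exists for exactly this case.

## Anti-correlation screen

Correlation is computed across all samples, tumor and normal pooled (16
columns in the default design): with 8 pairs this is the only family
size at which |r| ≈ 0.5 can reach p < 0.05 (at n = 16, r = −0.5 gives
p ≈ 0.048; tumor-only n = 8 would need |r| > 0.7). A tumor-only mode is
available via the matrices passed in. p is two-sided via
t = r·√((n−2)/(1−r²)) with n−2 df; exactly collinear vectors (|r| = 1 up
to 1e-12 round-off) are snapped to ±1 with p = 0. The
opposite-direction constraint is an explicit pre-filter (default on):
same-direction pairs are not evaluated, so the BH family is the set of
direction-consistent candidate pairs. BH is computed once over that
whole family, never per-miRNA.

## Target prediction

Database lookups are replaced by two algorithmic stand-ins so the
dual-source criterion works offline; external 2-column tables are
equally accepted and the pipeline's contract is only "supported by two
named sources".

* **Seed matcher**: the seed is miRNA positions 2–8 (1-based, 5' end).
  On the UTR sense strand the 6mer core is the reverse complement of
  positions 2–7; an additional match to the complement of position 8 on
  the 5' side and/or an A on the 3' side upgrades the site to 7mer-m8,
  7mer-A1 or 8mer. Each locus is reported once with its strongest type;
  coordinates are 0-based half-open. 6mer sites are detected but
  excluded from prediction by default (weak sites inflate false
  positives). U/T are interconverted at the I/O boundary.
* **Complementarity aligner**: Gotoh local alignment of the miRNA
  (3'→5') against UTR windows with Watson–Crick match +5, G:U wobble
  +1, mismatch −3, gap open −9, gap extend −4, substitution scores at
  seed positions ×2; a pair is predicted at score ≥ 100 (so perfect
  seed pairing plus modest 3' support suffices: a full 22-nt complement
  scores 145). No thermodynamic free-energy term is computed; the
  score-only criterion keeps the stage dependency-free.

## Enrichment

One result per GMT term overlapping the study set (the final target
genes): fold enrichment (m/n)/(M/N), hypergeometric upper-tail p — by
default the conservative EASE variant, computed with one gene removed
from the overlap — BH FDR reported in percent, and Bonferroni over the
tested family. The universe defaults to the genes measured on the
platform after flag filtering, matching the measured background rather
than the genome. Whether a published table's p is EASE or plain
hypergeometric is often unstated; both are available and labeled.

## qPCR validation

ΔCT = CT − CT(reference gene); the calibrator is the sample whose ΔCT is
closest to the median ΔCT (lower ΔCT means higher expression, so this is
monotone-equivalent to "median expression"), ties broken by
lexicographic sample id; −ΔΔCT = −(ΔCT − ΔCT(calibrator)). The
calibrator is chosen per assay, which is what makes −ΔΔCT exactly
invariant under a constant CT shift of an assay, and the calibrator's
−ΔΔCT is identically 0. Samples with CT missing or above 35 cycles are
excluded from statistics; an assay failing in more than half its samples
is excluded as non-amplifying ("most of the samples" operationalized as
fraction > 0.5). Group comparison is the paired t on per-patient
tumor/normal −ΔΔCT; pair validation is Pearson r/p between −ΔΔCT
vectors over shared samples (matched on patient and group), significant
at r < 0 and p < 0.05. A QC-excluded assay makes its pairs "not
evaluable", never "not significant". No amplification-efficiency
correction is applied.

## Synthetic cohorts

The generator emulates the targeted study design: `n_pairs` matched
tumor/normal pairs (default 8) profiled for `n_mirna` = 200 miRNAs and
`n_mrna` = 2000 mRNA probes; 16 up- and 16 down-planted DE miRNAs with
log2 shift `de_effect` = 2 in tumor; 30 planted repressive edges with
distinct targets; residual noise SD 0.3; an optional per-patient random
intercept (default SD 0, since the real intra-patient correlation
structure is unknown); prediction sources that drop true edges with
probability `pred_fnr` = 0.1 and add false pairs at per-pair rate
`pred_fpr` = 0.05 (a realistic database error rate at this scale,
chosen once); and a 40-pair qPCR cohort.

Repression is linear-Gaussian on the log2 scale: a target receives
−coupling × (regulator value centered across samples), coupling = 0.9.
This is the simplest model producing the anti-correlation the screen
assumes; no degradation kinetics are modeled. Because the regulator's
tumor shift passes through the coupling, targets are automatically DE in
the opposite direction — the generator's truth network records both.

Sequences: each miRNA is a random 22-mer; every true-edge target UTR
(150 nt) carries one planted 8mer site for its regulator; decoy UTRs are
rejection-sampled (cap 200 attempts) to contain no seed core for any
planted DE miRNA — only DE miRNAs, to keep rejection tractable. qPCR
plates map expression to CT as CT = 30 − 1 × log2(expression) plus noise
(SD 0.2), reference CT ~ Normal(20, 0.25) — an arbitrary but documented
mapping; a failing assay draws CT ~ Normal(37, 1) with 30% missing.
All randomness flows through the single `SimConfig.seed`; each generator
derives an independent deterministic stream, and per-assay qPCR noise is
keyed by assay id so plate composition does not perturb other assays.

What the generator does **not** emulate: probe-level scanner effects,
dye bias, isomiRs, miRNA secondary structure, indirect regulation,
competing regulators of one target (each target has exactly one planted
regulator), or realistic correlation among decoy genes. Passing tests
therefore demonstrate that the screen recovers the planted mechanism
under its own assumptions, not performance on real microarray data.

## Problem sizes and verification

The test suite and the acceptance run use the default cohort
(200 × 2000 × 8 pairs; SAM runs its exhaustive 256 sign flips), 10 seeds
for the recovery and null benchmarks, 50 small cohorts for the
prediction-table independence check, and a 40-patient plate for qPCR —
each full screen completes in well under a second, the entire suite in
seconds. Under these conditions the planted network is recovered with
median recall ≈ 0.78 and precision ≈ 0.95 over ten seeds, and the
all-null configuration yields a median of zero final pairs.

## Known limitations

* SAM's δ-grid, permutation count and π₀ = 1 are implementation
  defaults, not estimates; π₀ estimation refinements are out of scope.
* The unpaired calling mode gates on the t branch only (sign-flip
  permutations require the paired design).
* The aligner's score threshold (100) was fixed a priori from the
  perfect-complement score, not tuned.
* Enrichment consumes user-supplied gene sets; no annotation database
  or term-graph propagation ships with the package.
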