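# Methods

## Assay model and quantities

A barcode MPRA couples each allele of each variant to a set of short
transcribed barcodes.  Sequencing the plasmid pool (2 DNA samples) and the
transcripts after transfection (3 cDNA samples) gives a count matrix over
barcodes × samples.  All analyses share one depth normalization:

    depth_factor_s = column_sum_s / mean(column sums of same-material samples)

so factors average exactly 1 within DNA and within RNA.  Scaling any one
column rescales every same-material factor; activities therefore move by a
single material-wide additive constant while every transcription shift and
p-value is exactly invariant (tested).

**Activity** of barcode b in RNA sample r: `ln(normRNA(b,r) / meanNormDNA(b))`,
where `meanNormDNA(b)` averages the barcode's normalized counts over the
DNA samples (the assay does not pair DNA replicates with transfections).
Natural log throughout: shifts are in nats.  **Transcription shift**:
mean(alt activities) − mean(ref activities).

## Traditional analysis

1. Depth-normalize; error on a zero-total sample.
2. Remove barcodes with mean normalized DNA count < 1.0 (configurable;
   the low-representation cut-off is a declared default, not a measured
   constant — published screens rarely state theirs).
3. Compute activities; (barcode, sample) pairs with zero RNA are dropped
   and tallied — this loss of data is exactly what motivates the count
   model below.
4. Per variant, pooling the (barcode, transfection) observations of each
   allele as independent: two-sided **Welch** t-test (the
   unequal-variance form is the safer default when the base test is
   unspecified) and a two-sided **Mann-Whitney U** test — exact by full
   enumeration of the C(n1+n2, n1) group assignments when both groups have
   ≤ 8 observations (a permutation test on U, hence valid under ties),
   tie-corrected normal approximation otherwise.
5. Benjamini-Hochberg step-up within each test family across all variants
   of the run; variants with < 2 observations in either allele are
   reported NA and excluded from the family.

Pooling transfections as independent observations mildly understates
within-barcode correlation (the DNA denominator is shared across a
barcode's three RNA observations); with tight plasmid sequencing this
effect is small, and the null-calibration test verifies the realized
type-I behaviour.

## Bayesian coupled negative-binomial model

Per variant v with alleles a ∈ {ref, alt}, barcodes b, samples s with
depth factor d_s:

    DNA:  y_bs ~ NB(mean = d_s·μ_b,          var = mean + mean²/φ_DNA)
    RNA:  y_bs ~ NB(mean = d_s·μ_b·α_{a(b)}, var = mean + mean²/φ_RNA)
    μ_b ~ Gamma(k_μ, r_μ),   α_a ~ Gamma(k_α, r_α)
    TS_v = ln α_alt − ln α_ref

Zero counts are ordinary likelihood terms; nothing is discarded.  One
activity parameter per allele (not per barcode) matches the quantity the
ratio analysis averages.  Depth factors are identical to the frequentist
ones, so the two methods are directly comparable.

### Empirical priors

Hyperparameters are estimated once, marginally across the whole assay
(requiring ≥ 50 barcodes with nonzero DNA counts):

- `μ` prior: gamma MLE (`scipy.stats.gamma.fit`, location fixed at 0) on
  crude per-barcode means `m̂_b = mean_s(y_bs/d_s)`.
- `α` prior: gamma MLE on crude per-allele activities
  `α̂_a = mean_{b,s}( y_RNA / (d_s·m̂_b) )` pooled over every allele of
  every variant.
- Dispersions: pooled method of moments within each material.  With
  `x_bs = y_bs/d_s`, `Var(x_bs) = μ_b/d_s + μ_b²/φ`, so
  `φ̂ = Σ_b m̂_b² / Σ_b (v̂_b − m̂_b·mean(1/d_s))`.  If every barcode's
  across-sample variance is exactly zero the estimate is undefined and
  estimation errors out; if the pooled excess variance is non-positive or
  φ̂ exceeds 10³ the data are flagged Poisson-like in the estimation
  report (φ set to ≥ 10³).

Dispersions are held fixed during sampling — priors are placed on the NB
*means* only.  Giving φ a hyperprior is a defensible alternative; fixing
it keeps the per-variant posterior 2 + B dimensional and the marginal
estimates are precise because they pool thousands of barcodes.

### Sampler

Given α the μ_b are conditionally independent, and given all μ the two α_a
are conditionally independent, so each Gibbs scan performs one vectorized
random-walk Metropolis update of all log μ_b (elementwise accept/reject)
and one of (log α_ref, log α_alt).  Because φ is fixed, the NB log-pmf
reduces to `y·ln m − (y+φ)·ln(m+φ)` up to constants, so no special
functions are evaluated in the loop.  Per-parameter step sizes adapt
toward 44% acceptance (Robbins-Monro, decay t^-0.6) during warmup only.
Defaults: 4 chains × 1000 warmup + 1000 kept draws; chains are
initialized at jittered crude estimates.

Diagnostics: split-R̂ and ESS (arviz) for log α_ref, log α_alt, TS and
every log μ_b.  Any R̂ > 1.05 flags the variant (`converged = False`) and
the CLI exits 4 under `--strict-convergence`; results are never silently
dropped.  Per-variant RNG streams are spawned from the master seed keyed
by design order, so runs are reproducible and order-independent.

### Summaries and hit calling

Posterior mean and the 95% **equal-tailed** interval from empirical
quantiles of the pooled draws (equal-tailed rather than HPD: the interval
is transformation-consistent on TS and matches symmetric reported bounds);
a variant is a hit iff the interval excludes 0.  No effect-size floor and
no multiplicity correction — the empirical prior's shrinkage is the
false-positive control.

## Library design

Restriction motifs screened: SfiI (GGCCNNNNNGGCC), KpnI (GGTACC), XbaI
(TCTAGA).  All three are palindromic as IUPAC patterns, so one-strand
scanning is complete.  A variant is discarded when *either* allele's 150 bp
context contains any motif.  Barcodes (10 bp) are sampled under: no
screened motif (optionally including junction flanks so no motif forms
across linker/primer-arm boundaries at assembly), homopolymer runs < 4,
uniqueness, and pairwise Hamming distance ≥ 2 — enforced in O(n·L) with
single-position-wildcard keys.  The distance-2 floor is what justifies
exact-match demultiplexing: one sequencing error cannot turn a designed
barcode into another designed barcode, and quality-filtered exact matching
(every barcode base strictly above Q30) then needs no mismatch rescue.
These barcode criteria are this package's explicit defaults, not a claim
about any published criteria set.  Coordinates are 0-based half-open;
contexts are stored on the + strand of the design.

## Simulator: the stated world

`simulate_experiment` draws from exactly the model above.  Defaults mirror
a screening panel of 91 constructs (81 test SNPs + 10 positive controls) ×
2 alleles × 40 barcodes/allele, 2 DNA + 3 RNA samples:

| parameter | default | why |
|---|---|---|
| μ prior | Gamma(4, 0.08) (mean 50, CV 0.5) | typical plasmid representation; puts per-sample totals at ~3–4×10⁵ assigned reads, MiSeq-scale |
| α prior | Gamma(4, 4) (mean 1) | activities centred on the pool average |
| φ_DNA | 100 | plasmid resequencing is nearly a technical replicate: DNA-DNA log-count correlations near 1 |
| φ_RNA | 4 | transfection + transcription add large extra-Poisson noise; DNA-RNA correlations visibly lower |
| depth factors | DNA (0.9, 1.1); RNA (0.8, 1.0, 1.2) | realistic modest depth imbalance, mean 1 per material |

Presets: `paper-scale-null` (all TS = 0), `paper-scale-mixed` (the 10
controls carry |TS| ~ U[0.2, 1.1] with random signs — ≈10/91 active),
`sparse` (5 barcodes/allele, μ mean 5: shallow, zero-inflated counts, the
regime where discarding zeros costs the ratio analysis its power).
`simulate_fastq` realizes a count table as reads with constant base
quality plus planted low-quality and off-design reads for end-to-end
testing of the extractor; it has no instrument error model.

What the simulator does **not** emulate: PCR jackpotting, sequencing
substitution errors, barcode cross-talk, position effects in the plasmid,
or any mismatch between the model and reality (the NB-gamma form is both
the generator and the analyst's assumption).  A green calibration test
therefore establishes self-consistency — correct coverage, shrinkage and
power *under the model* — not robustness to model misspecification.

## Numerical choices and degenerate inputs

- Q>30 is strict: a base at exactly Q30 fails the filter.
- Welch test with two zero-variance groups: p = 1 if means are equal
  (identical constant groups carry no evidence), else 0.
- Exact U two-sided p = min(1, 2·min(P(U ≤ u), P(U ≥ u))) with a 1e-9
  tie tolerance on U comparisons.
- BH is the textbook step-up (stable sort, cumulative minimum from the
  largest p), clipped to 1, order-preserving.
- `summarize` requires ≥ 100 draws; equal-tailed quantiles at (2.5%,
  97.5%) for the default level.
- Gamma MLE refuses < 10 positive values or an all-equal sample.
- Zero-total sample columns, unpaired variants, unknown barcodes and
  non-integer raw counts all raise typed errors rather than propagating
  NaNs.

## Known limitations

- The sampler is random-walk based; for very large barcode sets per
  variant (≫ 100) a gradient-based sampler would mix faster per draw.
- The activity-prior MLE uses crude ratio estimates whose sampling noise
  widens the fitted prior relative to the latent α spread; this is
  conservative (less shrinkage than ideal) and matters little at default
  scale.
- Exact U enumeration is limited to ≤ 8 observations per group
  (C(16,8) = 12,870 splits); beyond that the tie-corrected normal
  approximation is used, which at 9+ observations is accurate to well
  under 0.02.
- Frequentist pooling across transfections ignores within-barcode
  correlation (see above); the Bayesian model accounts for it explicitly
  through the shared μ_b.
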