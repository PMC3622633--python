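# Methods

This note documents the statistical model behind `edmr`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that affect results.

## The gap model and the empirical boundary distance

Enrichment bisulfite protocols sequence CpGs in clusters (restriction
fragments, CpG islands). The log2-transformed distance x = log2(Δpos)
between adjacent covered CpGs on the same chromosome is therefore bimodal:
component 1 (weight λ₁, mean μ₁) collects within-cluster ("regional") gaps
and component 2 (λ₂ = 1 − λ₁, μ₂ > μ₁) between-cluster ("boundary") gaps.
Non-destranded input additionally shows a spike at Δpos = 1 bp — the
reverse-complement GpC measurement of the same dinucleotide on the other
strand. The spike carries no boundary information and is removed before
fitting; `compute_gap_sample` removes Δpos ≤ 1 (a Δpos of 0 is the same
artifact observed at the same coordinate) and counts the removals.

The mixture is fitted by a standard two-component univariate Gaussian EM.
Initialization splits the sample at its median and uses each half's moments
— deterministic, so repeated runs and permuted inputs give identical fits
and no label switching; components are relabelled μ₁ < μ₂ afterwards.
Convergence: |Δ log-likelihood| < tol·(1 + |log-likelihood|) with
tol = 1e-8, max 1000 iterations. A component collapsing below σ = 1e-6 or
λ = 1e-4, or a constant sample, raises a degenerate-mixture error rather
than returning nonsense.

Because the regional component dominates (λ₁ ≈ 0.85 in enrichment data), a
plain density-crossing would mislabel many regional gaps. The boundary
point instead minimizes the weighted misclassification cost
C(x) = λ₁·P₁(X ≥ x) + λ₂·P₂(X ≤ x), whose interior minimum satisfies
λ₁f₁(x̂) = λ₂f₂(x̂). Minimization uses bounded scalar minimization
(Brent-type, xatol 1e-6) over the observed range of retained gaps, then
polishes x̂ by root-finding on λ₂f₂ − λ₁f₁ when the stationary point is
bracketed, so the crossing condition holds to ~1e-12. If the minimum sits
at an endpoint the components do not separate and a warning is emitted.
The segmentation cutoff is D = round(2^x̂) base pairs; with typical
enrichment parameters D lands near 180 bp. Segmentation splits strictly:
a gap equal to D stays inside a region.

Users can bypass fitting with `--dist-cutoff <bp>` (the fitted cutoff is
stable across comparable samples, so a fixed project-wide D is sensible).

## Filters

Candidate regions must pass three independent filters (all adjustable):
≥ 1 DMC, ≥ 3 CpGs, and |mean Δmeth| strictly > 20 percentage points. The
mean is the unweighted arithmetic mean over member CpGs — the simplest
reading, and coverage weighting would couple the region statistic to depth.
The per-site DMC definition defaults to q < 0.01 and |Δmeth| ≥ 25, the
conventional thresholds of the upstream single-cytosine callers whose
output this package consumes. Direction is the sign of the region mean
(treatment − control); a mean of exactly 0 cannot survive the 20% filter,
so the hyper/hypo classification has no tie case.

## Dependence-adjusted significance

Differential-methylation p-values of nearby CpGs are strongly correlated,
so a naive Stouffer combination within a region is anti-conservative. The
adjustment follows the combined-probability approach for spatially
correlated tests: partition each chromosome into `bin_size` = 100-bp bins,
transform p-values to z = Φ⁻¹(1 − p), average within bins, and estimate
ρ(ℓ) as the Pearson correlation of bin-mean pairs exactly ℓ bins apart
(lags 1..`max_lag` = 10; lags with < 3 pairs or zero variance are set to 0
with a warning). For a region with member positions p₁..p_k the working
correlation is σᵢⱼ = ρ(⌈|pᵢ − pⱼ|/bin_size⌉), unit diagonal, zero beyond
`max_lag`. Because this mapping need not be positive semidefinite, the
matrix is repaired by flooring negative eigenvalues at zero and rescaling
to unit diagonal. The combined p-value is 1 − Φ(T) with
T = Σzᵢ/√(Σᵢⱼσᵢⱼ), z clamped via p ∈ [1e-15, 1 − 1e-15] to avoid infinite
probits. Benjamini–Hochberg correction is applied over the combined
p-values of the filtered regions (filter first, then test: fewer tests,
and the regions actually reported are exactly the family corrected for).

Two choices are deliberately exposed rather than fixed:

* `--combine {all, dmc-only}` — whether all member p-values or only DMC
  p-values enter the combination. Default `all`: combining only the
  already-significant sites would bias the region statistic, and using
  every member is the conservative choice.
* `--acf-source {pvalue, meth_diff}` — the ACF of methylation differences
  is always computed and written to `acf.tsv` as a diagnostic, but the
  p-value ACF drives the adjustment by default since the combination acts
  on p-values.

## Annotation

Gene parts derive from refFlat transcripts (converted to 1-based inclusive
coordinates on ingestion): promoter = TSS ± 1000 bp (strand-aware,
configurable; no consensus definition exists, this is the common default of
the upstream toolchain), 5'/3'UTR = exonic sequence outside the CDS bounds
on the appropriate strand side, CDS = exonic ∩ CDS bounds, introns = gaps
between exons. For every coding transcript the UTR/CDS/intron parts tile
[txStart, txEnd] exactly and disjointly (a tested invariant). CpG-island
shores are the 2-kb flanks clipped at position 1 with all island bases
subtracted. A DMR is reported against every feature class it overlaps by
≥ 1 bp (strand ignored); `--precedence` switches to disjoint counting in
the order promoter > 5'UTR > 3'UTR > CDS > intron. Transcripts are
annotated independently, with no collapsing to canonical isoforms.

## The synthetic generator

`edmr simulate` emulates the structure the method assumes, with known
truth:

* **Positions.** Gaps are max(2, round(2^x)) with x from the two-component
  mixture. Defaults λ₁ = 0.85, μ₁ = 4.66, σ₁ = 1.2, μ₂ = 9.5, σ₂ = 1.5
  put the weighted-density crossing at x* ≈ 7.52, i.e. a boundary distance
  of ≈183 bp — typical of enrichment assays. `spike_fraction` = 10% of
  CpGs are duplicated at +1 bp on the − strand to reproduce non-destranded
  input.
* **Planted DMRs.** 50 runs of 10 consecutive CpGs by default, effect
  ±40 pp with 5 pp noise. Interior gaps of a run are drawn from the
  regional component and the two flanking gaps from the boundary component
  conditioned on exceeding x* — a planted DMR is a cluster genuinely
  separated from its neighbours, otherwise the truth interval itself would
  be ill-defined.
* **P-values.** A latent z per 100-bp bin follows a stationary AR(1) chain
  (ρ = 0.7) along each chromosome; each CpG observes
  √w·z_bin + √(1−w)·ε with within-bin share w = 0.9, so null p-values are
  marginally uniform but strongly locally correlated, as observed for
  differential-methylation p-values at this scale. CpGs in planted runs
  receive an additional probit shift of 8 — the order of significance a
  Fisher exact test yields for a 40-pp difference at the default ~80X
  coverage — so effect size and significance are coherent. q-values are BH
  over all CpGs; coverage is 10 + negative binomial (mean 79).

What the generator does **not** emulate: read-level sampling and bisulfite
conversion errors, coverage-dependent p-value precision, chromosome-scale
covariates (GC waves, replication timing), island/shore structure of the
positions beyond cluster spacing, and missingness patterns between
samples. Passing the recovery gates therefore demonstrates correctness of
the algorithmic chain under its stated model, not performance on any
particular patient dataset.

## Problem sizes and reproducibility

The default end-to-end check uses 200,000 CpGs over 4 chromosomes with 50
planted DMRs — large enough that the mixture fit, ACF estimate and FDR
behave asymptotically while a full run (generation + two pipeline passes)
completes in well under a minute. Calibration experiments use 10,000
regions/bins; the effect-free pipeline calibration uses 50,000 CpGs
(≈5,500 testable regions). All randomness flows through a single integer
seed (numpy `default_rng`); identical seed and configuration give
bit-identical output files, and the pipeline is single-threaded by design
so determinism does not depend on scheduling.

## Known limitations

* The ceil-lag correlation lookup assigns sub-bin pairs the lag-1
  autocorrelation, which understates very short-range correlation; with
  strong short-range ACFs the adjusted null rejection at 0.05 runs ≈6%
  rather than 5% (measured on the effect-free synthetic methylome). The
  unadjusted combination runs > 20% under the same conditions.
* The two-component mixture is a modelling choice; data whose gap
  distribution is unimodal (e.g. whole-genome bisulfite sequencing at high
  uniform coverage) will not separate, and the fit will warn or error. A
  fixed `--dist-cutoff` is the right tool there.
* p-value combination treats the per-site p-values as given; systematic
  miscalibration upstream propagates.
* Regions are never merged after filtering, and no sliding-window caller
  is provided.
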