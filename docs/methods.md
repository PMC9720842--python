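# Methods

## The measurement model

qMSP quantifies methylated template by the PCR cycle threshold Ct: lower Ct
means more methylated cfDNA. The assay runs 45 cycles, so "no amplification"
and any Ct that would exceed 45 are both recorded as Ct = 45. We model the
observed Ct of a gene in a group as a right-censored normal,
Y = min(X, c) with X ~ N(μ, σ²) and c = 45. The censored moments are

    E[Y]   = μΦ(a) − σφ(a) + cΦ(−a),          a = (c − μ)/σ
    E[Y²]  = (μ² + σ²)Φ(a) − σ(c + μ)φ(a) + c²Φ(−a)

Published group tables report censored moments, so the generator calibrates
the *latent* (μ, σ) numerically (Powell hybrid root-finder on (μ, log σ),
several starts, required agreement 1e−3 in both moments). Degenerate targets
(SD 0) return a point mass; a censored mean at the ceiling with positive SD
is infeasible and raises. For the control group the calibration is strongly
censored: e.g. observed (44.46, 1.78) corresponds to latent
(μ ≈ 52.6, σ ≈ 7.2) with ~85% of mass censored.

Genes are independent within a patient by default (no joint distribution is
published); a Gaussian-copula correlation parameter is available for
sensitivity analyses. Cross-gene independence is the main simplification:
real tumors likely methylate GNB4 and Riplet jointly, which would lower the
incremental value of the second gene relative to our simulations.

## Synthetic cohorts

Defaults are the published study conditions: 17 HCC vs. 11 HBV-DeCi
controls; per-gene group moments from the published Ct summary table; HCC
CTC counts negative binomial with mean 5 and variance 4.1² = 16.81
(dispersion r = mean²/(var − mean) ≈ 2.12), matching the reported
overdispersion. Control CTC counts are not published beyond "significantly
lower"; we default to Poisson(1), which makes roughly 1 in 11 controls
exceed a small positivity cutoff — consistent with the reported 90.9% CTC
specificity regime. Candidate-cell tables draw a latent malignant/benign
population: malignant cells N(20, 3²) μm diameter, N(1.0, 0.15²) N/C ratio
and 0.85-probability qualitative flags; benign cells N(11, 2²), N(0.55,
0.1²) and 0.04 flags. These profiles are chosen so malignant cells meet ≥ 4
criteria and benign cells ≤ 2 with high probability; they emulate annotated
feature tables, not images — staining, segmentation and inter-observer
variability are outside the model, so classifier performance here bounds
what clean annotations allow, not microscope reality.

Beta matrices plant marker probes at (tumor 0.45, normal 0.05, blood 0.02,
other-cancer 0.05) against background probes at (0.35, 0.25, 0.30, 0.30)
with N(0, 0.05²) noise clipped to [0, 1]. Markers therefore pass all four
screening filters in expectation and background fails at least one (fold
< 2, normal β > 0.1, high blood and pan-cancer β). Real 450K data has
correlated probes, batch effects and bimodal β distributions; passing the
recovery tests shows the cascade's logic is correct, not that the original
probe counts (1,148 → 447 → 30 → 2) would be reproduced on TCGA/GEO.

Every generator is a pure function of (parameters, seed) via
`numpy.random.default_rng`; the pipeline derives per-stage child seeds from
the single config seed (default 17, the cohort size).

## Screening cascade choices

Rank-sum tests are two-sided Mann–Whitney, exact enumeration when both
groups have ≤ 10 samples and no ties, tie-corrected normal approximation
otherwise (sidedness and tie handling are not stated in the source
protocol). No multiple-testing correction is applied — the selection rule
is raw p < 0.05, deliberately; specificity comes from the effect-size and
absence filters. The fold ratio uses per-group arithmetic mean β with a
denominator floor of 1e−3. Thresholds ≥ 2, ≥ 0.3, ≤ 0.1 are inclusive as
printed; the pan-cancer cutoff is *strictly* below 0.2, because markers
must be absent in other cancers and the printed rule gives no direction.
Stage 3 ranks by mean blood β (the printed "smallest β values" could also
mean median; mean chosen) with lexicographic probe-id tie-breaks; stage 4
applies the cutoff per cancer type (strictest reading) rather than pooled.

## CTC rule

The two printed rule sentences are treated as exhaustive. That leaves a
deliberate gap: criterion 6 plus exactly one other criterion matches
neither sentence and is classified negative, even though criterion 6 alone
is "suspected". The class ordering is therefore *not* fully monotone in
added criteria — the implementation and tests document this single
exception rather than smoothing it away; CTC-ness itself is monotone.
Suspected CTCs are excluded from the diagnostic count by default
(`include_suspected=True` reverses this). The dual-pathologist blind review
is out of computational scope; a Cohen's-kappa agreement helper is provided
for annotator tables.

## Diagnostic statistics

The empirical ROC enumerates thresholds at midpoints between consecutive
distinct scores plus ±∞ sentinels; AUC is computed from ranks and equals
pair-counting with ties ½. Ct features use `direction="lower_positive"`.
The AUC CI is DeLong's; sensitivity/specificity CIs are Clopper–Pearson.
Youden ties break toward higher specificity, then the more conservative
threshold. Logistic models maximize the Bernoulli likelihood with a small
L2 penalty (1e−6, intercept unpenalized) by damped Newton iterations
(convergence when the penalized deviance changes < 1e−10, cap 100
iterations); the penalty keeps the separated regimes these biomarkers
produce finite, and any coefficient magnitude above 50 sets
`separation_detected`. Zero-variance features warn and get coefficient 0.

Descriptive summaries use the clinical-software dialect: n−1 SD, t-based
95% CI, bias-corrected skewness G1 = g1·√(n(n−1))/(n−2) and excess kurtosis
G2 = [n(n+1)/((n−1)(n−2)(n−3))]·Σd⁴/s⁴ − 3(n−1)²/((n−2)(n−3)), linear
interpolated quartiles. This dialect is what reproduces the published
skewness −3.32 and kurtosis 11.00 on the reconstructed control vector (the
uncorrected moment versions give −2.85 / 9.07 − 3 and do not). The 5%
trimmed mean removes round(0.05·n) whole observations from each end — on
the reconstructed control vector this gives the published 45.00, whereas
fractional-observation interpolation would give 44.73; we follow the value
the source software evidently produced. Skewness/kurtosis of constant
input are reported as NaN (the published table prints the group constant in
those cells, which we treat as a typesetting artifact).

## Reconstruction from summary statistics

For a printed row (n, mean, SD, median, ceiling, optional min/max) the
solver hypothesizes k observations at the ceiling, k = n down to 0, and
solves the remaining m = n − k values to match the printed mean and SD:
closed form for m ≤ 2, otherwise an equally spaced pattern rescaled to the
required sum of squares (bounded least squares as fallback when the pattern
would exceed the ceiling). The first (largest-k) solution agreeing with all
supplied statistics within 0.05 — the scale of two-decimal printing — is
returned. Preferring large k encodes the censoring prior: Ct 45 means "not
detected", the typical control outcome. For the control GNB4 row this is
essentially exact: median 45 with n = 11 forces ≥ 9 ceiling values, and
mean 44.46 then forces ten at 45 and one at 11·44.46 − 10·45 = 39.06,
consistent with the published minimum 39.10 under input rounding. The
residual field reports the achieved-vs-printed discrepancies, so downstream
users can see exactly how constrained a given row was. Rows with light
censoring admit many solutions; the reconstruction is then a representative
cohort matching the printed moments, not a recovery of patient data.

## Problem sizes

The test suite and the acceptance script run everything at sizes chosen to
keep the full run in seconds-to-minutes on one core while leaving Monte-
Carlo error well inside the asserted tolerances: moment-recovery checks at
n = 10⁴–10⁵ draws, the calibrated two-gene AUC at 5,000 per arm, cascade
recovery over 100 seeds on 80-probe matrices, and property tests bounded at
cohorts of ≤ 30 for the exhaustive pair-count oracle.

## Known limitations

* Cross-gene and gene–CTC independence in the generator (see above).
* The β-matrix generator has no probe–probe correlation or batch structure.
* Amplification-curve shape (the kit's S-curve requirement) is assumed
  satisfied for tabulated Ct values; raw fluorescence is out of scope.
* Published single-gene sensitivities (77.8%, 88.9%) imply n = 18
  denominators while the cohort has 17 HCC patients; the final-model 88.2%
  = 15/17 is consistent. We do not force agreement with the n = 18 figures.
* Whether the real assay logged "no amplification" as Ct 45 or as missing
  is not stated; the Ct-45 encoding is adopted throughout (the published
  maxima are all 45.00), and the > 43 negativity rule makes the choice
  diagnostically irrelevant.
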