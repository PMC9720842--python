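# liquidhcc

Liquid-biopsy diagnostics for early detection of hepatocellular carcinoma
(HCC): plasma cfDNA methylation of two marker genes (**GNB4** and
**Riplet**/RNF135) read out by quantitative methylation-specific PCR (qMSP),
combined with circulating tumor cell (CTC) enumeration, evaluated against
HBV-related decompensated cirrhosis (HBV-DeCi) controls.

The package is aimed at researchers who want to re-analyze, stress-test or
extend this class of combined CTC + methylation assays without access to the
original patient-level data: every stage of the published analysis is
implemented as tested library code, and a calibrated synthetic-cohort
generator plus a summary-statistics reconstruction routine make the printed
results re-checkable.

## What it implements

* **Censored-normal Ct model.** qMSP reports a cycle threshold Ct; no
  amplification within 45 cycles is encoded as Ct = 45, so observed Ct is
  right-censored: Y = min(X, c) with X ~ N(μ, σ²), c = 45. Published group
  tables report the *censored* moments; `calibrate_censored_distribution`
  solves the latent (μ, σ) whose censored mean/SD (closed form in Φ, φ)
  match the printed values, so simulated cohorts reproduce the study
  conditions rather than a biased version of them.
* **Kit calling rules** (`liquidhcc.qmsp`): sample valid iff β-actin
  Ct ≤ 35; gene positive iff Ct ≤ 43; sample positive iff GNB4 OR Riplet
  positive; invalid samples are excluded and logged.
* **CTC morphology rule** (`liquidhcc.ctc`): six criteria (nuclear atypia,
  N/C ratio > 0.8, long diameter > 15 μm, hyperchromasia, nuclear-membrane
  wrinkling, large nucleoli/abnormal division); CTC iff ≥ 4 criteria or
  criterion 6 plus ≥ 2 others; "suspected" for exactly 3 of the first five
  or criterion 6 alone.
* **450K probe-screening cascade** (`liquidhcc.screening`): rank-sum
  p < 0.05 with β_T/β_N ≥ 2, β_T ≥ 0.3, β_N ≤ 0.1 → independent-set
  replication → top-k lowest whole-blood β → mean β < 0.2 in every other
  cancer type. Verified by planted-marker recovery on synthetic matrices.
* **Diagnostic evaluation** (`liquidhcc.diagnostics`): empirical ROC with
  AUC = Mann–Whitney U/(n₁n₀) (ties ½), DeLong CI, Youden-index cutoff
  (J = sens + spec − 1), penalized-MLE logistic combination, Clopper–Pearson
  CIs for sensitivity/specificity.
* **Reconstruction from summary statistics** (`liquidhcc.summaries`): under
  heavy censoring, a printed (n, mean, SD, median) row pins the individual
  values; `reconstruct_from_summary` hypothesizes k values at the ceiling
  (largest k first) and solves the remainder to match the printed moments.

## Worked example

```python
>>> from liquidhcc.summaries import cohort_summary, reconstruct_from_summary
>>> rec = reconstruct_from_summary(n=11, mean=44.46, sd=1.78, median=45.0,
...                                ceiling=45.0)
>>> rec.values.round(2)
array([39.06, 45.  , 45.  , 45.  , 45.  , 45.  , 45.  , 45.  , 45.  ,
       45.  , 45.  ])
>>> s = cohort_summary(rec.values)
>>> round(s.skewness, 2), round(s.kurtosis, 2)
(-3.32, 11.0)
```

Ten of the eleven control patients had no detectable GNB4 methylation
(Ct censored at 45) and one amplified at Ct ≈ 39.06 — this single vector
reproduces the published minimum (39.10), skewness (−3.32) and kurtosis
(11.00), and under the Ct ≤ 43 positivity rule yields the published
single-gene specificity of 10/11 = 90.9%.

The numbered drivers under `analysis/` run the full story; for example:

```text
$ python analysis/03_run_pipeline.py --seed 17
simulated 28 patients; 87 cells called CTC
combined model: AUC 1.000 (1.00-1.00), sens 100.0% / spec 100.0% at the Youden cutoff
kit OR-rule on the same cohort: sens 94.1% / spec 100.0%

$ python analysis/04_evaluate_models.py --seed 17
      ctc: AUC 0.840 (0.69-0.99), sens 64.7% / spec 90.9%
     gnb4: AUC 0.971 (0.91-1.00), sens 94.1% / spec 100.0%
   riplet: AUC 0.941 (0.86-1.00), sens 88.2% / spec 100.0%
    genes: AUC 1.000 (1.00-1.00), sens 100.0% / spec 100.0%
 combined: AUC 1.000 (1.00-1.00), sens 100.0% / spec 100.0%
```

On one simulated study-sized cohort the single-marker models are weakest
(CTC count AUC 0.84 with specificity 90.9%), the genes are stronger, and the
combined model separates the arms — the same ordering the published study
reports (CTC 0.81, genes 0.97, combined 0.98). Small-cohort AUCs are noisy;
exact values move with the seed.

A `liquidhcc` console script exposes the same stages
(`simulate`, `screen-probes`, `call-qmsp`, `classify-ctc`, `evaluate`,
`reconstruct`, `reproduce`, `run`); see `liquidhcc --help`.

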