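"""Published study parameters used as defaults throughout the package.

These are the group-level summary statistics of the 17-HCC / 11-control
(HBV-related decompensated cirrhosis) qMSP cohort and the assay constants of
the methylation detection kit. They parameterize the synthetic-cohort
generators and the reconstruction checks; nothing here is a computed result.
"""

# Assay constants -----------------------------------------------------------

#: Ct value encoding "no amplification"; the PCR runs 45 cycles, so every
#: reported Ct is right-censored at 45.
CT_CEILING = 45.0

#: A sample is valid only if the endogenous control (beta-actin) amplifies
#: by this cycle.
ACTB_VALID_MAX = 35.0

#: A target gene (GNB4 or Riplet) is methylation-positive at or below this Ct.
TARGET_POSITIVE_MAX = 43.0

# Cohort sizes --------------------------------------------------------------

N_HCC = 17
N_CONTROL = 11

# Per-group Ct summary statistics (control group = HBV-DeCi) ----------------
# keys: (gene, group) -> dict of printed summary statistics.

CT_SUMMARY = {
    ("gnb4", "control"): dict(mean=44.46, sd=1.78, median=45.00,
                              minimum=39.10, maximum=45.00),
    ("gnb4", "hcc"): dict(mean=37.44, sd=3.99, median=37.74,
                          minimum=30.32, maximum=45.00),
    ("riplet", "control"): dict(mean=45.00, sd=0.00, median=45.00,
                                minimum=45.00, maximum=45.00),
    ("riplet", "hcc"): dict(mean=38.49, sd=4.74, median=38.23,
                            minimum=30.05, maximum=45.00),
    ("actb", "control"): dict(mean=30.53, sd=0.55, median=30.50,
                              minimum=29.40, maximum=31.18),
    ("actb", "hcc"): dict(mean=27.80, sd=1.89, median=27.66,
                          minimum=24.03, maximum=31.29),
}

# CTC counts (cells per 5 ml whole blood) -----------------------------------

#: HCC group: mean 5, SD 4.1 (range 0-16) -> overdispersed vs. Poisson.
CTC_HCC_MEAN = 5.0
CTC_HCC_SD = 4.1
#: Control counts are not printed, only that they are "significantly lower";
#: the default control model is Poisson with mean 1.
CTC_CONTROL_MEAN = 1.0

# Headline diagnostic metrics (for the side-by-side comparison report) ------

HEADLINE = {
    "ctc_auc": 0.81,
    "ctc_sensitivity_pct": 70.6,
    "ctc_specificity_pct": 90.9,
    "genes_auc": 0.97,
    "gnb4_specificity_pct": 90.9,
    "combined_auc": 0.98,
    "combined_sensitivity_pct": 88.2,
    "combined_specificity_pct": 100.0,
}
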