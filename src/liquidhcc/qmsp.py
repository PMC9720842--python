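"""Deterministic qMSP call interpretation.

The detection kit's rules, applied to tabulated Ct values:

* a sample is *valid* iff the endogenous control beta-actin has Ct <= 35;
* a target gene (GNB4, Riplet) is methylation-*positive* iff its Ct <= 43
  (Ct > 43 or no amplification, encoded upstream as the ceiling 45, is
  negative);
* a valid sample is positive iff GNB4 OR Riplet is positive.

Invalid samples carry no gene calls and are excluded from downstream metric
denominators (logged, standard diagnostic convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from liquidhcc import reference

__all__ = ["CallThresholds", "SampleCall", "call_sample", "call_cohort"]


@dataclass(frozen=True)
class CallThresholds:
    actb_valid_max: float = reference.ACTB_VALID_MAX
    target_positive_max: float = reference.TARGET_POSITIVE_MAX

    def __post_init__(self) -> None:
        for name in ("actb_valid_max", "target_positive_max"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive")


@dataclass(frozen=True)
class SampleCall:
    sample_id: str
    valid: bool
    gnb4_positive: bool | None
    riplet_positive: bool | None
    combined_positive: bool | None


def _check_ct(value, gene: str, sample_id: str) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise ValueError(f"sample {sample_id}: missing Ct value for {gene}")
    v = float(value)
    if v <= 0:
        raise ValueError(f"sample {sample_id}: non-positive Ct for {gene}")
    return v


def call_sample(sample, thresholds: CallThresholds | None = None) -> SampleCall:
    """Interpret one sample's Ct triple under the kit thresholds.

    ``sample`` is any mapping/namespace with ``sample_id``, ``ct_gnb4``,
    ``ct_riplet``, ``ct_actb`` (a DataFrame row works). Boundary values are
    inclusive as the kit states (<= 35 valid, <= 43 positive).
    """
    thresholds = thresholds or CallThresholds()
    get = sample.get if hasattr(sample, "get") else lambda k, d=None: getattr(sample, k, d)
    sample_id = str(get("sample_id", "?"))
    actb = _check_ct(get("ct_actb"), "actb", sample_id)
    gnb4 = _check_ct(get("ct_gnb4"), "gnb4", sample_id)
    riplet = _check_ct(get("ct_riplet"), "riplet", sample_id)

    valid = actb <= thresholds.actb_valid_max
    if not valid:
        return SampleCall(sample_id, False, None, None, None)
    g = gnb4 <= thresholds.target_positive_max
    r = riplet <= thresholds.target_positive_max
    return SampleCall(sample_id, True, g, r, g or r)


def call_cohort(
    samples: pd.DataFrame, thresholds: CallThresholds | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Call every sample in a cohort table, order-preserving.

    Returns ``(calls, excluded)`` where ``calls`` has one row per input
    sample (columns ``sample_id, valid, gnb4_call, riplet_call,
    combined_call``; call columns are nullable booleans, NA for invalid
    samples) and ``excluded`` lists the invalid sample ids.
    """
    thresholds = thresholds or CallThresholds()
    rows, excluded = [], []
    for _, s in samples.iterrows():
        c = call_sample(s, thresholds)
        if not c.valid:
            excluded.append(c.sample_id)
        rows.append(
            dict(sample_id=c.sample_id, valid=c.valid, gnb4_call=c.gnb4_positive,
                 riplet_call=c.riplet_positive, combined_call=c.combined_positive)
        )
    calls = pd.DataFrame(rows, columns=["sample_id", "valid", "gnb4_call",
                                        "riplet_call", "combined_call"])
    for col in ("gnb4_call", "riplet_call", "combined_call"):
        calls[col] = calls[col].astype("boolean")
    return calls, excluded
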