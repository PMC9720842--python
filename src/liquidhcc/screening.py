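"""Four-stage methylation marker screening cascade over beta-value matrices.

The cascade mirrors how hypermethylated HCC marker probes are selected from
450K-array data:

1. **differential** — tumor vs. adjacent-normal: two-sided rank-sum p < 0.05,
   fold ratio mean(beta_T)/mean(beta_N) >= 2, mean(beta_T) >= 0.3 and
   mean(beta_N) <= 0.1 (all thresholds inclusive as stated);
2. **validation** — the survivors must replicate (rank-sum p < 0.05) in an
   independent tumor/normal matrix;
3. **blood filter** — keep the top-k probes with the *smallest* mean beta in
   healthy whole blood (markers must be silent in leukocyte background);
4. **pan-cancer** — mean beta strictly below 0.2 in every other cancer type
   (markers must be HCC-specific).

No multiple-testing correction is applied: the selection uses raw p < alpha,
deliberately, with specificity enforced by the effect-size and absence
filters rather than by family-wise error control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from liquidhcc.synthetic import BetaMatrix

__all__ = [
    "StageReport",
    "CascadeResult",
    "ScreeningConfig",
    "stage_differential",
    "stage_validation",
    "stage_blood_filter",
    "stage_pan_cancer",
    "run_cascade",
]

logger = logging.getLogger(__name__)

#: Floor on the normal-group mean beta when forming the fold ratio; the
#: beta_N <= 0.1 filter makes near-zero denominators common.
FOLD_DENOM_FLOOR = 1e-3


@dataclass
class StageReport:
    stage_name: str
    probes_in: int
    probes_out: int
    surviving_ids: list[str]
    per_probe_stats: pd.DataFrame

    def __post_init__(self) -> None:
        if self.probes_out > self.probes_in:
            raise ValueError("probes_out cannot exceed probes_in")


@dataclass
class CascadeResult:
    stages: list[StageReport]
    final_probes: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.final_probes = list(self.stages[-1].surviving_ids) if self.stages else []

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.stage_name, s.probes_in, s.probes_out) for s in self.stages],
            columns=["stage", "probes_in", "probes_out"],
        )


@dataclass(frozen=True)
class ScreeningConfig:
    alpha: float = 0.05
    fold_min: float = 2.0
    beta_tumor_min: float = 0.3
    beta_normal_max: float = 0.1
    validation_alpha: float = 0.05
    top_k: int = 30
    pan_max: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1 or not 0 < self.validation_alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.fold_min < 1:
            raise ValueError("fold_min must be >= 1")


def _group_values(matrix: BetaMatrix, group: str) -> np.ndarray:
    samples = matrix.samples_in(group)
    if not samples:
        raise ValueError(f"matrix has no samples in group {group!r}")
    return matrix.values[samples].to_numpy()


def _ranksum_p(tumor: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Mann-Whitney p-values (tumor vs. normal).

    Exact enumeration when both groups have <= 10 samples (and scipy can,
    i.e. no ties); tie-corrected normal approximation otherwise.
    """
    method = "exact" if tumor.shape[1] <= 10 and normal.shape[1] <= 10 else "asymptotic"
    try:
        res = stats.mannwhitneyu(tumor, normal, alternative="two-sided",
                                 method=method, axis=1)
    except ValueError:
        # exact method refuses tied data -> fall back to the approximation
        res = stats.mannwhitneyu(tumor, normal, alternative="two-sided",
                                 method="asymptotic", axis=1)
    return np.atleast_1d(res.pvalue)


def stage_differential(
    matrix: BetaMatrix,
    alpha: float = 0.05,
    fold_min: float = 2.0,
    beta_tumor_min: float = 0.3,
    beta_normal_max: float = 0.1,
) -> StageReport:
    """Differential-methylation filter on a tumor/normal matrix.

    A probe survives iff rank-sum p < ``alpha`` AND fold ratio >= ``fold_min``
    AND mean tumor beta >= ``beta_tumor_min`` AND mean normal beta <=
    ``beta_normal_max``.
    """
    tumor = _group_values(matrix, "tumor")
    normal = _group_values(matrix, "normal")
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("differential stage needs >= 2 samples per group")
    beta_t = tumor.mean(axis=1)
    beta_n = normal.mean(axis=1)
    fold = beta_t / np.maximum(beta_n, FOLD_DENOM_FLOOR)
    p = _ranksum_p(tumor, normal)
    keep = (p < alpha) & (fold >= fold_min) & (beta_t >= beta_tumor_min) & (
        beta_n <= beta_normal_max
    )
    statsdf = pd.DataFrame(
        {"p_value": p, "beta_tumor": beta_t, "beta_normal": beta_n,
         "fold_ratio": fold, "survives": keep},
        index=matrix.values.index,
    )
    survivors = [pid for pid, k in zip(matrix.probe_ids, keep) if k]
    report = StageReport("differential", len(matrix.probe_ids), len(survivors),
                         survivors, statsdf)
    logger.info("differential: %d -> %d probes", report.probes_in, report.probes_out)
    return report


def stage_validation(
    probes: list[str], matrix: BetaMatrix, alpha: float = 0.05
) -> StageReport:
    """Replication filter: rank-sum p < alpha in an independent matrix.

    Probes absent from the validation matrix are dropped with a warning.
    """
    probes = list(probes)
    present = [p for p in probes if p in matrix.values.index]
    absent = sorted(set(probes) - set(present))
    if absent:
        logger.warning("validation: %d probes absent from validation matrix "
                       "and dropped: %s", len(absent), absent[:5])
    if not present:
        return StageReport("validation", len(probes), 0, [],
                           pd.DataFrame(columns=["p_value", "survives"]))
    sub = BetaMatrix(matrix.values.loc[present], matrix.group_labels,
                     marker_truth=matrix.marker_truth)
    tumor = _group_values(sub, "tumor")
    normal = _group_values(sub, "normal")
    p = _ranksum_p(tumor, normal)
    keep = p < alpha
    statsdf = pd.DataFrame({"p_value": p, "survives": keep}, index=present)
    survivors = [pid for pid, k in zip(present, keep) if k]
    report = StageReport("validation", len(probes), len(survivors), survivors, statsdf)
    logger.info("validation: %d -> %d probes", report.probes_in, report.probes_out)
    return report


def stage_blood_filter(
    probes: list[str], blood_matrix: BetaMatrix, k: int = 30
) -> StageReport:
    """Keep the k probes least methylated (smallest mean beta) in whole blood.

    Ties are broken by probe id, lexicographically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    probes = list(probes)
    missing = sorted(set(probes) - set(blood_matrix.values.index))
    if missing:
        raise KeyError(f"probes missing from blood matrix: {missing[:5]}")
    blood = blood_matrix.values.loc[probes, blood_matrix.samples_in("blood")]
    means = blood.mean(axis=1)
    order = sorted(probes, key=lambda pid: (means[pid], pid))
    survivors = order[: min(k, len(order))]
    statsdf = pd.DataFrame(
        {"blood_mean_beta": means, "survives": means.index.isin(survivors)},
        index=means.index,
    )
    report = StageReport("blood_filter", len(probes), len(survivors),
                         survivors, statsdf)
    logger.info("blood_filter: %d -> %d probes", report.probes_in, report.probes_out)
    return report


def stage_pan_cancer(
    probes: list[str], pan_matrix: BetaMatrix | pd.DataFrame, max_beta: float = 0.2
) -> StageReport:
    """HCC-specificity filter: mean beta strictly below ``max_beta`` in every
    other cancer type.

    ``pan_matrix`` is either a BetaMatrix whose ``pan_cancer_*`` groups are
    the other cancer types, or a precomputed probes-by-type DataFrame of mean
    beta values.
    """
    probes = list(probes)
    if isinstance(pan_matrix, BetaMatrix):
        types = [g for g in pan_matrix.groups() if g.startswith("pan_cancer")]
        if not types:
            raise ValueError("pan-cancer matrix has no pan_cancer_* groups")
        means = pd.DataFrame(
            {t: pan_matrix.values[pan_matrix.samples_in(t)].mean(axis=1) for t in types}
        )
    else:
        means = pan_matrix
    missing = sorted(set(probes) - set(means.index))
    if missing:
        raise KeyError(f"probes missing from pan-cancer means: {missing[:5]}")
    if means.isna().any().any():
        raise ValueError("pan-cancer mean table contains missing entries")
    sub = means.loc[probes]
    keep = (sub < max_beta).all(axis=1)
    statsdf = sub.copy()
    statsdf["max_pan_beta"] = sub.max(axis=1)
    statsdf["survives"] = keep
    survivors = [p for p in probes if keep[p]]
    report = StageReport("pan_cancer", len(probes), len(survivors),
                         survivors, statsdf)
    logger.info("pan_cancer: %d -> %d probes", report.probes_in, report.probes_out)
    return report


def run_cascade(
    discovery: BetaMatrix,
    validation: BetaMatrix,
    blood: BetaMatrix,
    pan_cancer: BetaMatrix | pd.DataFrame,
    config: ScreeningConfig | None = None,
) -> CascadeResult:
    """Apply the four stages in their fixed order.

    Survivor counts are monotone non-increasing by construction; each stage
    receives exactly the previous stage's survivors.
    """
    cfg = config or ScreeningConfig()
    s1 = stage_differential(discovery, cfg.alpha, cfg.fold_min,
                            cfg.beta_tumor_min, cfg.beta_normal_max)
    s2 = stage_validation(s1.surviving_ids, validation, cfg.validation_alpha)
    s3 = stage_blood_filter(s2.surviving_ids, blood, cfg.top_k)
    s4 = stage_pan_cancer(s3.surviving_ids, pan_cancer, cfg.pan_max)
    return CascadeResult([s1, s2, s3, s4])
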