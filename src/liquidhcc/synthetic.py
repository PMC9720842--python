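"""Seeded synthetic cohorts calibrated to the published summary statistics.

Four generators cover the data the downstream stages consume:

* qMSP Ct triples (GNB4, Riplet, beta-actin) per patient, drawn from
  right-censored normal distributions whose *censored* moments are
  calibrated to the published group means and SDs (ceiling Ct 45 encodes
  "not detected"),
* per-patient CTC counts (negative binomial for the overdispersed HCC group,
  Poisson limit available),
* probes-by-samples methylation beta matrices with planted marker probes that
  satisfy the screening cascade's filters in expectation, and
* per-cell morphology feature tables for the CTC rule classifier.

All generators are pure functions of their parameters and an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from liquidhcc import reference

__all__ = [
    "CtDistribution",
    "CountDistribution",
    "BetaMatrix",
    "CalibrationError",
    "calibrate_censored_distribution",
    "censored_normal_moments",
    "gen_qmsp_cohort",
    "gen_ctc_counts",
    "gen_beta_matrix",
    "gen_cell_table",
    "resample_empirical",
    "default_ct_params",
    "default_count_params",
]


class CalibrationError(ValueError):
    """Raised when no censored-normal distribution attains the target moments."""


# ---------------------------------------------------------------------------
# Censored-normal Ct model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CtDistribution:
    """A latent normal Ct distribution right-censored at the assay ceiling.

    Samples are ``min(N(latent_mean, latent_sd), ceiling)``; the observed
    (censored) mean and SD therefore differ from the latent parameters
    whenever appreciable mass lies above the ceiling.
    """

    latent_mean: float
    latent_sd: float
    ceiling: float = reference.CT_CEILING

    def __post_init__(self) -> None:
        if self.latent_sd < 0:
            raise ValueError("latent_sd must be >= 0")
        if not math.isfinite(self.ceiling):
            raise ValueError("ceiling must be finite")

    def censored_moments(self) -> tuple[float, float]:
        """Mean and SD of the censored variable (closed form)."""
        return censored_normal_moments(self.latent_mean, self.latent_sd, self.ceiling)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.latent_sd == 0:
            x = np.full(n, self.latent_mean, dtype=float)
        else:
            x = rng.normal(self.latent_mean, self.latent_sd, size=n)
        return np.clip(x, 1e-6, self.ceiling)


def censored_normal_moments(mu: float, sigma: float, ceiling: float) -> tuple[float, float]:
    """Closed-form mean and SD of min(N(mu, sigma), ceiling).

    With ``a = (ceiling - mu) / sigma``::

        E[Y]  = mu * Phi(a) - sigma * phi(a) + ceiling * (1 - Phi(a))
        E[Y^2] = (mu^2 + sigma^2) * Phi(a) - sigma * (ceiling + mu) * phi(a)
                 + ceiling^2 * (1 - Phi(a))
    """
    if sigma == 0:
        return min(mu, ceiling), 0.0
    a = (ceiling - mu) / sigma
    cdf = stats.norm.cdf(a)
    pdf = stats.norm.pdf(a)
    m1 = mu * cdf - sigma * pdf + ceiling * (1.0 - cdf)
    m2 = (mu**2 + sigma**2) * cdf - sigma * (ceiling + mu) * pdf + ceiling**2 * (1.0 - cdf)
    var = max(m2 - m1 * m1, 0.0)
    return m1, math.sqrt(var)


def calibrate_censored_distribution(
    target_mean: float,
    target_sd: float,
    ceiling: float = reference.CT_CEILING,
    tol: float = 1e-3,
) -> CtDistribution:
    """Find latent (mean, sd) whose censored moments hit the observed targets.

    The published tables report observed (censored) group moments; sampling
    from a normal with those parameters and then censoring would bias both
    moments, so the latent parameters are solved for numerically.

    Parameters
    ----------
    target_mean, target_sd
        Observed mean and SD of the censored Ct values.
    ceiling
        Assay ceiling (default 45).
    tol
        Required absolute agreement of the censored moments with the targets.

    Raises
    ------
    CalibrationError
        If the targets are infeasible (e.g. mean above the ceiling, or mean
        equal to the ceiling with positive SD).
    """
    if target_sd < 0:
        raise CalibrationError("target_sd must be >= 0")
    if target_mean > ceiling:
        raise CalibrationError(
            f"target mean {target_mean} exceeds the censoring ceiling {ceiling}"
        )
    if target_sd == 0:
        return CtDistribution(target_mean, 0.0, ceiling)
    if target_mean == ceiling:
        raise CalibrationError(
            "a censored mean equal to the ceiling forces a point mass; "
            "positive SD is infeasible"
        )
    # No appreciable censoring: the latent parameters are the targets.
    if (ceiling - target_mean) > 8.0 * target_sd:
        return CtDistribution(target_mean, target_sd, ceiling)

    def residual(theta: np.ndarray) -> np.ndarray:
        mu, log_sigma = theta
        m, s = censored_normal_moments(mu, math.exp(log_sigma), ceiling)
        return np.array([m - target_mean, s - target_sd])

    starts = [
        (target_mean, math.log(target_sd)),
        (ceiling + target_sd, math.log(2.0 * target_sd)),
        (ceiling + 3.0 * target_sd, math.log(4.0 * target_sd)),
        (target_mean - target_sd, math.log(0.5 * target_sd)),
    ]
    best = None
    for x0 in starts:
        sol = optimize.root(residual, np.asarray(x0, dtype=float), method="hybr")
        err = float(np.max(np.abs(residual(sol.x))))
        if best is None or err < best[0]:
            best = (err, sol.x)
        if err < tol:
            break
    err, x = best
    if err >= tol:
        raise CalibrationError(
            f"no censored normal reproduces mean={target_mean}, sd={target_sd} "
            f"at ceiling {ceiling} (best residual {err:.2e})"
        )
    return CtDistribution(float(x[0]), float(math.exp(x[1])), ceiling)


# ---------------------------------------------------------------------------
# CTC count model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountDistribution:
    """Negative-binomial count model: variance = mean + mean^2 / dispersion.

    ``dispersion = inf`` gives the Poisson limit (variance = mean).
    """

    mean: float
    dispersion: float = math.inf

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError("mean must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")

    @property
    def variance(self) -> float:
        if math.isinf(self.dispersion):
            return self.mean
        return self.mean + self.mean**2 / self.dispersion

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.mean == 0:
            return np.zeros(n, dtype=int)
        if math.isinf(self.dispersion):
            return rng.poisson(self.mean, size=n)
        r = self.dispersion
        p = r / (r + self.mean)
        return rng.negative_binomial(r, p, size=n)


def default_count_params(group: str) -> CountDistribution:
    """Published CTC count models: HCC mean 5, SD 4.1; control Poisson(1)."""
    if group == "hcc":
        m, v = reference.CTC_HCC_MEAN, reference.CTC_HCC_SD**2
        return CountDistribution(m, m**2 / (v - m))
    if group == "control":
        return CountDistribution(reference.CTC_CONTROL_MEAN, math.inf)
    raise ValueError(f"unknown group {group!r}")


def gen_ctc_counts(params: CountDistribution, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` per-patient CTC counts (non-negative integers)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    return params.sample(n, rng)


# ---------------------------------------------------------------------------
# qMSP cohort
# ---------------------------------------------------------------------------

GENES = ("gnb4", "riplet", "actb")


def default_ct_params(group: str, ceiling: float = reference.CT_CEILING) -> dict[str, CtDistribution]:
    """Censored-normal Ct models calibrated to the published group moments."""
    out = {}
    for gene in GENES:
        s = reference.CT_SUMMARY[(gene, group)]
        out[gene] = calibrate_censored_distribution(s["mean"], s["sd"], ceiling)
    return out


def gen_qmsp_cohort(
    hcc_params: dict[str, CtDistribution],
    control_params: dict[str, CtDistribution],
    n_hcc: int,
    n_control: int,
    seed: int,
    gene_corr: float = 0.0,
) -> pd.DataFrame:
    """Simulate a two-arm qMSP cohort of Ct triples.

    Parameters
    ----------
    hcc_params, control_params
        Mapping gene name -> :class:`CtDistribution` for each arm; genes are
        ``gnb4``, ``riplet``, ``actb``.
    gene_corr
        Gaussian-copula correlation between genes within a patient
        (0 = independent, the default; no joint distribution is published).

    Returns
    -------
    DataFrame with columns ``sample_id, group, ct_gnb4, ct_riplet, ct_actb``.
    """
    if n_hcc < 0 or n_control < 0:
        raise ValueError("cohort sizes must be >= 0")
    if not -1.0 < gene_corr < 1.0:
        raise ValueError("gene_corr must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    frames = []
    for group, params, n, prefix in (
        ("HCC", hcc_params, n_hcc, "H"),
        ("control", control_params, n_control, "C"),
    ):
        missing = [g for g in GENES if g not in params]
        if missing:
            raise ValueError(f"missing Ct parameters for genes {missing} in group {group}")
        # Gaussian copula: correlated standard normals mapped through each
        # gene's latent normal, then censored at the ceiling.
        cov = np.full((3, 3), gene_corr) + (1.0 - gene_corr) * np.eye(3)
        z = rng.multivariate_normal(np.zeros(3), cov, size=n)
        cols = {}
        for j, gene in enumerate(GENES):
            d = params[gene]
            x = d.latent_mean + d.latent_sd * z[:, j]
            cols[f"ct_{gene}"] = np.clip(x, 1e-6, d.ceiling)
        df = pd.DataFrame(cols)
        df.insert(0, "group", group)
        df.insert(0, "sample_id", [f"{prefix}{i + 1:04d}" for i in range(n)])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def resample_empirical(values, n: int, seed: int) -> np.ndarray:
    """Bootstrap-resample an empirical distribution (e.g. a reconstructed
    control cohort) to an arbitrary sample size."""
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot resample an empty distribution")
    return rng.choice(values, size=n, replace=True)


# ---------------------------------------------------------------------------
# Methylation beta matrices
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Probes-by-samples methylation beta values with group annotations.

    ``values`` is a DataFrame (rows = probes, columns = samples), all entries
    in [0, 1]; ``group_labels`` maps each sample to its group (``tumor``,
    ``normal``, ``blood`` or a pan-cancer type ``pan_cancer_*``);
    ``marker_truth`` records planted marker probes when generated.
    """

    values: pd.DataFrame
    group_labels: pd.Series
    marker_truth: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.size and (np.nanmin(v) < 0 or np.nanmax(v) > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if not set(self.values.columns) <= set(self.group_labels.index):
            raise ValueError("every sample column needs a group label")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    def samples_in(self, group: str) -> list[str]:
        mask = self.group_labels == group
        return [s for s in self.values.columns if s in self.group_labels.index[mask]]

    def groups(self) -> list[str]:
        return sorted(self.group_labels.unique())


DEFAULT_GROUP_SIZES = {
    "tumor": 50,
    "normal": 50,
    "blood": 20,
    "pan_cancer_1": 15,
    "pan_cancer_2": 15,
    "pan_cancer_3": 15,
}

#: Planted markers: hypermethylated in tumor, quiet in normal tissue, whole
#: blood and other cancer types -- passing every cascade filter in expectation.
DEFAULT_MARKER_PROFILE = {
    "tumor": 0.45,
    "normal": 0.05,
    "blood": 0.02,
    "pan_cancer": 0.05,
}

#: Background probes fail at least one filter in expectation (fold < 2,
#: normal beta > 0.1, high blood and pan-cancer methylation).
DEFAULT_BACKGROUND_PROFILE = {
    "tumor": 0.35,
    "normal": 0.25,
    "blood": 0.30,
    "pan_cancer": 0.30,
}


def _profile_mean(profile: dict[str, float], group: str) -> float:
    if group in profile:
        return profile[group]
    if group.startswith("pan_cancer") and "pan_cancer" in profile:
        return profile["pan_cancer"]
    raise ValueError(f"profile has no mean for group {group!r}")


def gen_beta_matrix(
    n_probes: int = 300,
    n_markers: int = 20,
    group_sizes: dict[str, int] | None = None,
    marker_profile: dict[str, float] | None = None,
    background_profile: dict[str, float] | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    probe_ids: list[str] | None = None,
    marker_ids: list[str] | None = None,
) -> BetaMatrix:
    """Simulate a beta matrix with planted marker probes.

    Marker probes draw around ``marker_profile`` means, background probes
    around ``background_profile`` means, with i.i.d. Gaussian noise clipped to
    [0, 1]. Passing ``probe_ids``/``marker_ids`` from a previous matrix
    generates an independent matrix over the same probes (e.g. a validation
    set); otherwise marker positions are drawn from the seed.
    """
    group_sizes = dict(DEFAULT_GROUP_SIZES if group_sizes is None else group_sizes)
    marker_profile = dict(DEFAULT_MARKER_PROFILE if marker_profile is None else marker_profile)
    background_profile = dict(
        DEFAULT_BACKGROUND_PROFILE if background_profile is None else background_profile
    )
    for prof in (marker_profile, background_profile):
        for g, m in prof.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"profile mean for {g!r} must be in [0, 1]")
    rng = np.random.default_rng(seed)

    if probe_ids is None:
        probe_ids = [f"cg{i:06d}" for i in range(n_probes)]
    else:
        probe_ids = list(probe_ids)
        n_probes = len(probe_ids)
    if marker_ids is None:
        if n_markers > n_probes:
            raise ValueError("n_markers must be <= n_probes")
        marker_idx = rng.choice(n_probes, size=n_markers, replace=False)
        marker_ids = [probe_ids[i] for i in sorted(marker_idx)]
    else:
        marker_ids = list(marker_ids)
        if not set(marker_ids) <= set(probe_ids):
            raise ValueError("marker_ids must be a subset of probe_ids")
    is_marker = np.isin(np.array(probe_ids), np.array(marker_ids))

    sample_ids, labels, blocks = [], [], []
    for group, size in group_sizes.items():
        mu = np.where(
            is_marker,
            _profile_mean(marker_profile, group),
            _profile_mean(background_profile, group),
        )
        block = rng.normal(mu[:, None], noise_sd, size=(n_probes, size))
        blocks.append(np.clip(block, 0.0, 1.0))
        sample_ids += [f"{group}_{i + 1:03d}" for i in range(size)]
        labels += [group] * size

    values = pd.DataFrame(
        np.hstack(blocks) if blocks else np.empty((n_probes, 0)),
        index=pd.Index(probe_ids, name="probe_id"),
        columns=sample_ids,
    )
    return BetaMatrix(values, pd.Series(labels, index=sample_ids, name="group"),
                      marker_truth=marker_ids)


# ---------------------------------------------------------------------------
# Candidate-cell morphology tables
# ---------------------------------------------------------------------------

#: Feature models for the two latent cell populations. Quantitative features
#: (long diameter in um, nuclear/cytoplasmic area ratio) are Gaussian; the
#: four qualitative criteria are Bernoulli flags as a cytopathologist would
#: annotate them.
MALIGNANT_PROFILE = dict(
    diameter_mean=20.0, diameter_sd=3.0,
    nc_mean=1.00, nc_sd=0.15,
    flag_prob=0.85,
)
BENIGN_PROFILE = dict(
    diameter_mean=11.0, diameter_sd=2.0,
    nc_mean=0.55, nc_sd=0.10,
    flag_prob=0.04,
)

CELL_FLAG_COLUMNS = [
    "nuclear_atypia",
    "hyperchromatic_nonhomogeneous",
    "membrane_thickened_wrinkled",
    "large_nucleoli_or_abnormal_division",
]


def gen_cell_table(
    n_cells: int,
    fraction_malignant: float,
    seed: int,
    sample_id: str = "S0001",
    malignant_profile: dict | None = None,
    benign_profile: dict | None = None,
) -> pd.DataFrame:
    """Simulate candidate cells captured on the filtration membrane.

    Returns a DataFrame with one row per cell: ``cell_id``, ``sample_id``,
    ``long_diameter`` (um), ``nc_ratio``, the four qualitative criterion
    flags, and the generator's truth label ``is_malignant``.
    """
    if not 0.0 <= fraction_malignant <= 1.0:
        raise ValueError("fraction_malignant must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mal = dict(MALIGNANT_PROFILE, **(malignant_profile or {}))
    ben = dict(BENIGN_PROFILE, **(benign_profile or {}))
    truth = rng.random(n_cells) < fraction_malignant

    def draw(profile, n):
        d = np.maximum(rng.normal(profile["diameter_mean"], profile["diameter_sd"], n), 0.5)
        r = np.clip(rng.normal(profile["nc_mean"], profile["nc_sd"], n), 0.0, 1.5)
        flags = rng.random((n, 4)) < profile["flag_prob"]
        return d, r, flags

    diameter = np.empty(n_cells)
    nc = np.empty(n_cells)
    flags = np.empty((n_cells, 4), dtype=bool)
    for mask, profile in ((truth, mal), (~truth, ben)):
        d, r, f = draw(profile, int(mask.sum()))
        diameter[mask], nc[mask], flags[mask] = d, r, f

    df = pd.DataFrame({
        "cell_id": [f"{sample_id}_cell{i + 1:04d}" for i in range(n_cells)],
        "sample_id": sample_id,
        "long_diameter": diameter,
        "nc_ratio": nc,
    })
    for j, col in enumerate(CELL_FLAG_COLUMNS):
        df[col] = flags[:, j]
    df["is_malignant"] = truth
    return df
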