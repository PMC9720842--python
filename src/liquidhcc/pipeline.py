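"""End-to-end pipeline: simulate -> screen -> call -> classify -> evaluate.

The pipeline reproduces the study's analysis order on a synthetic cohort:
simulate qMSP Ct triples and per-patient candidate-cell tables, run the
probe-screening cascade on matched synthetic beta matrices, apply the kit
calling rules, enumerate CTCs with the morphology classifier, and evaluate
the chosen diagnostic model. All stages derive their randomness from one
config seed, so a config determines every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from liquidhcc import io as lio
from liquidhcc import reference
from liquidhcc.ctc import classify_cells, count_ctcs
from liquidhcc.diagnostics import fit_logistic, roc_curve, sens_spec, youden_cutoff
from liquidhcc.qmsp import CallThresholds, call_cohort
from liquidhcc.screening import ScreeningConfig, run_cascade
from liquidhcc.synthetic import (
    CountDistribution,
    calibrate_censored_distribution,
    gen_beta_matrix,
    gen_cell_table,
)
from liquidhcc import synthetic

__all__ = ["PipelineConfig", "ConfigError", "PipelineError",
           "validate_config", "run_pipeline", "evaluate_model"]

MODELS = ("ctc", "gnb4", "riplet", "genes", "combined")


class ConfigError(ValueError):
    pass


class PipelineError(RuntimeError):
    pass


def _table2(gene: str, group: str) -> dict:
    s = reference.CT_SUMMARY[(gene, group)]
    return {"mean": s["mean"], "sd": s["sd"]}


def _default_ct_block() -> dict:
    return {
        "hcc": {g: _table2(g, "hcc") for g in ("gnb4", "riplet", "actb")},
        "control": {g: _table2(g, "control") for g in ("gnb4", "riplet", "actb")},
    }


def _default_ctc_block() -> dict:
    hcc = synthetic.default_count_params("hcc")
    return {
        "hcc": {"mean": hcc.mean, "dispersion": hcc.dispersion},
        "control": {"mean": reference.CTC_CONTROL_MEAN, "dispersion": float("inf")},
    }


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with the study defaults.

    Default cohort sizes and Ct/count parameters are the published cohort's
    (17 HCC / 11 HBV-DeCi controls, group moments from the Ct summary table).
    """

    seed: int = 17
    n_hcc: int = reference.N_HCC
    n_control: int = reference.N_CONTROL
    ceiling: float = reference.CT_CEILING
    gene_corr: float = 0.0
    ct: dict = field(default_factory=_default_ct_block)
    ctc: dict = field(default_factory=_default_ctc_block)
    cells_background_per_sample: int = 50
    calling: dict = field(default_factory=lambda: {
        "actb_max": reference.ACTB_VALID_MAX,
        "target_max": reference.TARGET_POSITIVE_MAX,
    })
    screening: dict = field(default_factory=lambda: {
        "alpha": 0.05, "fold_min": 2.0, "beta_tumor_min": 0.3,
        "beta_normal_max": 0.1, "validation_alpha": 0.05, "top_k": 30,
        "pan_max": 0.2, "n_probes": 300, "n_markers": 20, "noise_sd": 0.05,
    })
    model: str = "combined"
    use_binary_calls: bool = False

    def serialize(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.serialize().encode()).hexdigest()[:16]


_SCALAR_VALIDATORS = {
    "seed": lambda v: isinstance(v, int) and 0 <= v,
    "n_hcc": lambda v: isinstance(v, int) and v >= 0,
    "n_control": lambda v: isinstance(v, int) and v >= 0,
    "ceiling": lambda v: np.isfinite(v) and v > 0,
    "gene_corr": lambda v: -1 < v < 1,
    "cells_background_per_sample": lambda v: isinstance(v, int) and v >= 0,
    "model": lambda v: v in MODELS,
    "use_binary_calls": lambda v: isinstance(v, bool),
}


def validate_config(raw=None) -> PipelineConfig:
    """Parse and validate a config (YAML text, mapping, or None for defaults).

    Unknown keys are rejected; known keys are merged over the defaults and
    range-checked. ``validate_config(serialize(cfg))`` is idempotent.
    """
    if raw is None or raw == "":
        data = {}
    elif isinstance(raw, str):
        data = yaml.safe_load(raw) or {}
    elif isinstance(raw, dict):
        data = dict(raw)
    elif isinstance(raw, PipelineConfig):
        return validate_config(dataclasses.asdict(raw))
    else:
        raise ConfigError(f"unsupported config input type {type(raw)!r}")
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")

    cfg = PipelineConfig()
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    for key, value in data.items():
        if key in ("ct", "ctc", "calling", "screening"):
            base = getattr(cfg, key)
            _merge_block(base, value, path=key)
        else:
            setattr(cfg, key, value)

    for key, check in _SCALAR_VALIDATORS.items():
        v = getattr(cfg, key)
        try:
            ok = bool(check(v))
        except TypeError:
            ok = False
        if not ok:
            raise ConfigError(f"invalid value for {key!r}: {v!r}")
    scr = cfg.screening
    if not 0 < scr["alpha"] <= 1 or not 0 < scr["validation_alpha"] <= 1:
        raise ConfigError(f"alpha must lie in (0, 1], got {scr['alpha']!r}")
    if scr["n_markers"] > scr["n_probes"]:
        raise ConfigError("n_markers cannot exceed n_probes")
    if scr["top_k"] < 1:
        raise ConfigError("top_k must be >= 1")
    for block in ("hcc", "control"):
        for gene in ("gnb4", "riplet", "actb"):
            entry = cfg.ct[block][gene]
            if entry["sd"] < 0 or entry["mean"] <= 0:
                raise ConfigError(f"invalid Ct parameters for {block}/{gene}")
        if cfg.ctc[block]["mean"] < 0 or cfg.ctc[block]["dispersion"] <= 0:
            raise ConfigError(f"invalid CTC count parameters for {block}")
    if cfg.calling["actb_max"] <= 0 or cfg.calling["target_max"] <= 0:
        raise ConfigError("calling thresholds must be positive")
    return cfg


def _merge_block(base: dict, update, path: str) -> None:
    if not isinstance(update, dict):
        raise ConfigError(f"config section {path!r} must be a mapping")
    for k, v in update.items():
        if k not in base:
            raise ConfigError(f"unknown config key: {path}.{k}")
        if isinstance(base[k], dict):
            _merge_block(base[k], v, f"{path}.{k}")
        else:
            base[k] = v


# ---------------------------------------------------------------------------


def _ct_params(cfg: PipelineConfig, group: str) -> dict:
    return {
        gene: calibrate_censored_distribution(
            cfg.ct[group][gene]["mean"], cfg.ct[group][gene]["sd"], cfg.ceiling
        )
        for gene in ("gnb4", "riplet", "actb")
    }


def simulate_cohort(cfg: PipelineConfig, seed: int) -> pd.DataFrame:
    return synthetic.gen_qmsp_cohort(
        _ct_params(cfg, "hcc"), _ct_params(cfg, "control"),
        cfg.n_hcc, cfg.n_control, seed=seed, gene_corr=cfg.gene_corr,
    )


def simulate_cells(cfg: PipelineConfig, cohort: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Per patient: draw a target CTC count, then emit that many
    malignant-profile cells plus a benign background."""
    rng = np.random.default_rng(seed)
    frames = []
    for _, row in cohort.iterrows():
        group = "hcc" if row["group"] == "HCC" else "control"
        dist = CountDistribution(**cfg.ctc[group])
        target = int(dist.sample(1, rng)[0])
        sub_seed = int(rng.integers(0, 2**31 - 1))
        mal = gen_cell_table(target, 1.0, seed=sub_seed, sample_id=row["sample_id"])
        ben = gen_cell_table(cfg.cells_background_per_sample, 0.0,
                             seed=sub_seed + 1, sample_id=row["sample_id"])
        cells = pd.concat([mal, ben], ignore_index=True)
        cells["cell_id"] = [f"{row['sample_id']}_cell{i + 1:04d}"
                            for i in range(len(cells))]
        frames.append(cells)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=lio.CELLS_COLUMNS + ["is_malignant"])


def screen_markers(cfg: PipelineConfig, seeds: np.ndarray):
    scr = cfg.screening
    gen = dict(n_probes=scr["n_probes"], n_markers=scr["n_markers"],
               noise_sd=scr["noise_sd"])
    discovery = gen_beta_matrix(seed=int(seeds[0]), **gen)
    validation = gen_beta_matrix(
        seed=int(seeds[1]), probe_ids=discovery.probe_ids,
        marker_ids=discovery.marker_truth, **gen)
    screen_cfg = ScreeningConfig(
        alpha=scr["alpha"], fold_min=scr["fold_min"],
        beta_tumor_min=scr["beta_tumor_min"], beta_normal_max=scr["beta_normal_max"],
        validation_alpha=scr["validation_alpha"], top_k=scr["top_k"],
        pan_max=scr["pan_max"])
    result = run_cascade(discovery, validation, discovery, discovery, screen_cfg)
    truth = set(discovery.marker_truth)
    found = set(result.final_probes)
    recall = len(found & truth) / len(truth) if truth else float("nan")
    precision = len(found & truth) / len(found) if found else float("nan")
    return result, {"marker_recall": recall, "marker_precision": precision}


def evaluate_model(
    cohort: pd.DataFrame,
    calls: pd.DataFrame,
    counts: pd.Series | pd.DataFrame,
    model: str,
    use_binary_calls: bool = False,
) -> dict:
    """Fit/score the chosen diagnostic model on valid samples and return
    ROC metrics (AUC with DeLong CI, Youden cutoff, sens/spec at cutoff)."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if isinstance(counts, pd.DataFrame):
        counts = counts.set_index("sample_id")["ctc_count"]
    df = cohort.merge(calls, on="sample_id")
    df = df[df["valid"]].copy()
    df["ctc_count"] = df["sample_id"].map(counts)
    if df["group"].nunique() < 2:
        raise ValueError("both classes must be present after exclusions")
    y = (df["group"] == "HCC").astype(int).to_numpy()

    if use_binary_calls:
        gene_feats = {"gnb4": "gnb4_call", "riplet": "riplet_call"}
        df["gnb4_call"] = df["gnb4_call"].astype(float)
        df["riplet_call"] = df["riplet_call"].astype(float)
        gene_dir = "higher_positive"
    else:
        gene_feats = {"gnb4": "ct_gnb4", "riplet": "ct_riplet"}
        gene_dir = "lower_positive"

    fitted = None
    if model == "ctc":
        scores, direction = df["ctc_count"].to_numpy(float), "higher_positive"
    elif model in ("gnb4", "riplet"):
        scores, direction = df[gene_feats[model]].to_numpy(float), gene_dir
    else:
        cols = [gene_feats["gnb4"], gene_feats["riplet"]]
        if model == "combined":
            cols = ["ctc_count"] + cols
        X = df[cols].to_numpy(float)
        fitted = fit_logistic(X, y)
        scores, direction = fitted.decision_score(X), "higher_positive"

    roc = roc_curve(scores, y, direction=direction)
    cutoff, sens_at, spec_at = youden_cutoff(roc)
    out = {
        "model": model,
        "n_hcc": int(y.sum()),
        "n_control": int(len(y) - y.sum()),
        "auc": roc.auc,
        "auc_ci": list(roc.auc_ci),
        "youden_cutoff": cutoff,
        "youden_j": roc.youden_j,
        "sensitivity_at_cutoff": sens_at,
        "specificity_at_cutoff": spec_at,
    }
    if fitted is not None:
        out["logistic"] = {
            "intercept": fitted.intercept,
            "coefficients": list(fitted.coefficients),
            "converged": fitted.converged,
            "separation_detected": fitted.separation_detected,
        }
    # kit-rule sensitivity/specificity alongside the score-based metrics
    rule = sens_spec(df["combined_call"].astype(int).to_numpy(), y)
    out["kit_rule"] = {
        "sensitivity": rule.sensitivity,
        "specificity": rule.specificity,
        "sensitivity_ci": list(rule.sensitivity_ci),
        "specificity_ci": list(rule.specificity_ci),
    }
    return out


def run_pipeline(config: PipelineConfig | dict | str | None, out_dir) -> dict:
    """Run every stage, write the artifact files, and return the manifest.

    Artifacts in ``out_dir``: cohort.tsv, cells.tsv, calls.tsv, counts.tsv,
    screening.json, metrics.json, manifest.json.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.default_rng(cfg.seed).integers(0, 2**31 - 1, size=8)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": _pkg_version(),
        "stages": {},
    }

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # surface which stage failed
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    cohort = stage("simulate", lambda: simulate_cohort(cfg, int(seeds[0])))
    lio.write_tsv(cohort, out / "cohort.tsv")
    manifest["stages"]["simulate"] = {"samples": len(cohort)}

    cascade, recovery = stage("screen", lambda: screen_markers(cfg, seeds[2:4]))
    lio.write_json(
        {"stages": [dict(stage=s.stage_name, probes_in=s.probes_in,
                         probes_out=s.probes_out) for s in cascade.stages],
         "final_probes": cascade.final_probes, **recovery},
        out / "screening.json")
    manifest["stages"]["screen"] = {
        "counts": [(s.stage_name, s.probes_in, s.probes_out) for s in cascade.stages],
        **recovery}

    thresholds = CallThresholds(cfg.calling["actb_max"], cfg.calling["target_max"])
    calls, excluded = stage("call", lambda: call_cohort(cohort, thresholds))
    lio.write_tsv(calls, out / "calls.tsv")
    manifest["stages"]["call"] = {"samples": len(calls), "excluded": excluded}

    cells = stage("classify", lambda: simulate_cells(cfg, cohort, int(seeds[4])))
    classified = stage("classify", lambda: classify_cells(cells))
    counts = count_ctcs(classified)
    counts = counts.reindex(cohort["sample_id"], fill_value=0)
    lio.write_tsv(classified.drop(columns=["is_malignant"]), out / "cells.tsv")
    lio.write_tsv(counts.rename_axis("sample_id").reset_index(), out / "counts.tsv")
    manifest["stages"]["classify"] = {
        "cells": len(classified),
        "ctc_cells": int((classified["cell_class"] == "CTC").sum()),
    }

    metrics = stage("evaluate", lambda: evaluate_model(
        cohort, calls, counts, cfg.model, cfg.use_binary_calls))
    lio.write_json(metrics, out / "metrics.json")
    manifest["stages"]["evaluate"] = {"model": cfg.model, "auc": metrics["auc"]}

    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    lio.write_json(manifest, out / "manifest.json")
    return manifest


def _pkg_version() -> str:
    from liquidhcc import __version__
    return __version__
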