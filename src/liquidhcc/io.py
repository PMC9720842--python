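"""Fixed TSV/JSON schemas for the pipeline's on-disk artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from liquidhcc.synthetic import BetaMatrix

COHORT_COLUMNS = ["sample_id", "group", "ct_gnb4", "ct_riplet", "ct_actb"]
CALLS_COLUMNS = ["sample_id", "valid", "gnb4_call", "riplet_call", "combined_call"]
COUNTS_COLUMNS = ["sample_id", "ctc_count"]
CELLS_COLUMNS = [
    "cell_id", "sample_id", "long_diameter", "nc_ratio",
    "nuclear_atypia", "hyperchromatic_nonhomogeneous",
    "membrane_thickened_wrinkled", "large_nucleoli_or_abnormal_division",
]


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, COHORT_COLUMNS, "cohort table")
    return df


def read_cells(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, CELLS_COLUMNS, "cell table")
    return df


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, CALLS_COLUMNS, "calls table")
    return df


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, COUNTS_COLUMNS, "counts table")
    return df


def write_beta_matrix(matrix: BetaMatrix, values_path, labels_path) -> None:
    """Beta matrix as probes-by-samples TSV plus a sample->group sidecar."""
    matrix.values.to_csv(values_path, sep="\t")
    labels = matrix.group_labels.rename_axis("sample_id").reset_index()
    labels.to_csv(labels_path, sep="\t", index=False)


def read_beta_matrix(values_path, labels_path) -> BetaMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t").set_index("sample_id")["group"]
    return BetaMatrix(values, labels)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
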