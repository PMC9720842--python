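"""Rule-based CTC classification from quantitative cell morphology.

Candidate cells captured by size-based filtration are scored against six
morphology criteria:

1. nuclear atypia (irregular, nodular or lobulated nuclear shape);
2. nuclear/cytoplasmic area ratio above 0.8 (strict);
3. long diameter above 15 um (strict);
4. hyperchromatic nucleus with non-homogeneous staining;
5. thickened, sunken or wrinkled nuclear membrane;
6. large nucleoli or abnormal nuclear division.

A cell is a **CTC** if it meets at least four criteria, or meets criterion 6
plus any two others. It is a **suspected CTC** if it meets exactly three of
criteria 1-5 (without 6), or only criterion 6. Every other pattern —
including criterion 6 plus exactly one other — is negative: the two rule
sentences are treated as exhaustive. Criteria 1, 4, 5 and 6 are qualitative
and enter as expert-annotated flags; 2 and 3 are computed from measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CellRecord",
    "CriteriaVector",
    "CellCall",
    "evaluate_criteria",
    "classify_cell",
    "classify_cells",
    "count_ctcs",
    "annotator_agreement",
]

NC_RATIO_MIN = 0.8   # criterion 2, strict ("higher than 0.8")
DIAMETER_MIN = 15.0  # criterion 3, strict (um)


@dataclass(frozen=True)
class CellRecord:
    cell_id: str
    sample_id: str
    long_diameter: float
    nc_ratio: float
    nuclear_atypia: bool
    hyperchromatic_nonhomogeneous: bool
    membrane_thickened_wrinkled: bool
    large_nucleoli_or_abnormal_division: bool

    def __post_init__(self) -> None:
        if self.long_diameter <= 0:
            raise ValueError(f"cell {self.cell_id}: long_diameter must be > 0")
        if not 0.0 <= self.nc_ratio <= 1.5:
            raise ValueError(f"cell {self.cell_id}: nc_ratio must lie in [0, 1.5]")


@dataclass(frozen=True)
class CriteriaVector:
    c1: bool  # nuclear atypia
    c2: bool  # N/C ratio > 0.8
    c3: bool  # long diameter > 15 um
    c4: bool  # hyperchromatic, non-homogeneous nucleus
    c5: bool  # thickened/wrinkled nuclear membrane
    c6: bool  # large nucleoli or abnormal division

    @property
    def total(self) -> int:
        return sum((self.c1, self.c2, self.c3, self.c4, self.c5, self.c6))


@dataclass(frozen=True)
class CellCall:
    cls: str  # "CTC" | "suspected" | "negative"
    criteria_met: int


def evaluate_criteria(cell: CellRecord) -> CriteriaVector:
    """Derive the six-criterion vector from a cell's features."""
    return CriteriaVector(
        c1=bool(cell.nuclear_atypia),
        c2=cell.nc_ratio > NC_RATIO_MIN,
        c3=cell.long_diameter > DIAMETER_MIN,
        c4=bool(cell.hyperchromatic_nonhomogeneous),
        c5=bool(cell.membrane_thickened_wrinkled),
        c6=bool(cell.large_nucleoli_or_abnormal_division),
    )


def classify_cell(criteria: CriteriaVector) -> CellCall:
    """Apply the decision rule to a criteria vector."""
    total = criteria.total
    others = total - int(criteria.c6)
    if total >= 4 or (criteria.c6 and others >= 2):
        cls = "CTC"
    elif (not criteria.c6 and others == 3) or (criteria.c6 and others == 0):
        cls = "suspected"
    else:
        cls = "negative"
    return CellCall(cls, total)


def classify_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Classify a table of cells; returns the input plus ``criteria_met`` and
    ``cell_class`` columns. Expects the CellRecord column schema."""
    out = cells.copy()
    classes, met = [], []
    for _, row in cells.iterrows():
        record = CellRecord(
            cell_id=str(row["cell_id"]),
            sample_id=str(row["sample_id"]),
            long_diameter=float(row["long_diameter"]),
            nc_ratio=float(row["nc_ratio"]),
            nuclear_atypia=bool(row["nuclear_atypia"]),
            hyperchromatic_nonhomogeneous=bool(row["hyperchromatic_nonhomogeneous"]),
            membrane_thickened_wrinkled=bool(row["membrane_thickened_wrinkled"]),
            large_nucleoli_or_abnormal_division=bool(
                row["large_nucleoli_or_abnormal_division"]
            ),
        )
        call = classify_cell(evaluate_criteria(record))
        classes.append(call.cls)
        met.append(call.criteria_met)
    out["criteria_met"] = met
    out["cell_class"] = classes
    return out


def count_ctcs(classified: pd.DataFrame, include_suspected: bool = False) -> pd.Series:
    """Per-sample CTC counts from a classified cell table.

    Suspected CTCs are excluded from the diagnostic count by default (the
    conservative reading of a single reported "CTC count").
    """
    wanted = {"CTC", "suspected"} if include_suspected else {"CTC"}
    hit = classified["cell_class"].isin(wanted)
    counts = classified.loc[hit].groupby("sample_id").size()
    all_samples = classified["sample_id"].unique()
    return counts.reindex(all_samples, fill_value=0).astype(int).rename("ctc_count")


def annotator_agreement(calls_a, calls_b) -> float:
    """Cohen's kappa between two annotators' cell classifications."""
    a = pd.Series(list(calls_a))
    b = pd.Series(list(calls_b))
    if len(a) != len(b):
        raise ValueError("annotator call lists differ in length")
    if len(a) == 0:
        raise ValueError("no calls to compare")
    po = float((a.values == b.values).mean())
    cats = sorted(set(a) | set(b))
    pe = sum(float((a == c).mean()) * float((b == c).mean()) for c in cats)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)
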