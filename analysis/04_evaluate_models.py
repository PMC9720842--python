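#!/usr/bin/env python
"""Evaluate all five diagnostic models on one simulated study-sized cohort.

Reuses the artifacts of 03_run_pipeline.py (runs it if absent) and scores
CTC count alone, each gene alone (raw Ct, lower = positive), the two-gene
logistic combination, and the full CTC + two-gene model. Small-cohort AUCs
are noisy; the point is the ranking structure the published study reports:
single markers < two genes <= combined.
"""

import argparse
import json
import sys
from pathlib import Path

import pandas as pd

from liquidhcc import io as lio
from liquidhcc.pipeline import evaluate_model, run_pipeline

ROOT = Path(__file__).resolve().parents[1]
PIPE = ROOT / "results" / "pipeline"
OUT = ROOT / "results"


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=17)
    args = parser.parse_args()

    if not (PIPE / "cohort.tsv").exists():
        run_pipeline({"seed": args.seed}, PIPE)
    cohort = lio.read_cohort(PIPE / "cohort.tsv")
    calls = lio.read_calls(PIPE / "calls.tsv")
    counts = lio.read_counts(PIPE / "counts.tsv")

    rows = {}
    for model in ("ctc", "gnb4", "riplet", "genes", "combined"):
        m = evaluate_model(cohort, calls, counts, model)
        rows[model] = m
        print(f"{model:>9}: AUC {m['auc']:.3f} "
              f"({m['auc_ci'][0]:.2f}-{m['auc_ci'][1]:.2f}), "
              f"sens {m['sensitivity_at_cutoff']:.1%} / "
              f"spec {m['specificity_at_cutoff']:.1%}")

    OUT.mkdir(exist_ok=True)
    (OUT / "model_metrics.json").write_text(json.dumps(rows, indent=2) + "\n")
    table = pd.DataFrame(
        [(k, v["auc"], v["sensitivity_at_cutoff"], v["specificity_at_cutoff"])
         for k, v in rows.items()],
        columns=["model", "auc", "sensitivity", "specificity"])
    table.to_csv(OUT / "model_metrics.tsv", sep="\t", index=False)
    return 0


if __name__ == "__main__":
    sys.exit(main())
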