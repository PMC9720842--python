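"""Probe-screening cascade: per-stage filters, calibration, invariances."""

import numpy as np
import pandas as pd
import pytest

from liquidhcc.screening import (
    ScreeningConfig,
    run_cascade,
    stage_blood_filter,
    stage_differential,
    stage_pan_cancer,
    stage_validation,
)
from liquidhcc.synthetic import BetaMatrix, gen_beta_matrix

GROUPS = {"tumor": 20, "normal": 20, "blood": 10, "pan_cancer_1": 8,
          "pan_cancer_2": 8}


def small_matrix(seed=0, n_probes=60, n_markers=6, **kw):
    return gen_beta_matrix(n_probes=n_probes, n_markers=n_markers,
                           group_sizes=GROUPS, seed=seed, **kw)


def manual_matrix(tumor_rows, normal_rows, probe_ids=None):
    """Build a tumor/normal BetaMatrix from explicit per-probe value lists."""
    tumor = np.asarray(tumor_rows, dtype=float)
    normal = np.asarray(normal_rows, dtype=float)
    ids = probe_ids or [f"p{i}" for i in range(tumor.shape[0])]
    cols = [f"t{i}" for i in range(tumor.shape[1])] + \
           [f"n{i}" for i in range(normal.shape[1])]
    values = pd.DataFrame(np.hstack([tumor, normal]), index=ids, columns=cols)
    labels = pd.Series(["tumor"] * tumor.shape[1] + ["normal"] * normal.shape[1],
                       index=cols)
    return BetaMatrix(values, labels)


class TestDifferential:
    def test_clear_marker_survives(self):
        rng = np.random.default_rng(0)
        tumor = np.clip(rng.normal(0.45, 0.02, (1, 20)), 0, 1)
        normal = np.clip(rng.normal(0.05, 0.02, (1, 20)), 0, 1)
        report = stage_differential(manual_matrix(tumor, normal))
        assert report.surviving_ids == ["p0"]
        row = report.per_probe_stats.loc["p0"]
        assert row["p_value"] < 0.05
        assert row["fold_ratio"] >= 2
        assert row["beta_tumor"] >= 0.3 and row["beta_normal"] <= 0.1

    def test_tumor_mean_below_threshold_fails(self):
        # mean tumor beta 0.29 < 0.30 fails regardless of p-value
        tumor = np.full((1, 20), 0.29)
        normal = np.full((1, 20), 0.01)
        report = stage_differential(manual_matrix(tumor, normal))
        assert report.surviving_ids == []

    def test_null_probes_survive_at_most_alpha(self):
        """Exchangeable groups: the p-condition fires in ~alpha of probes and
        upper-bounds the full filter's survival."""
        rng = np.random.default_rng(42)
        n_probes, alpha = 1000, 0.05
        null = np.clip(rng.normal(0.2, 0.05, (n_probes, 40)), 0, 1)
        m = manual_matrix(null[:, :20], null[:, 20:])
        report = stage_differential(m, alpha=alpha)
        p_frac = (report.per_probe_stats["p_value"] < alpha).mean()
        assert 0.02 <= p_frac <= 0.08  # ~alpha within Monte-Carlo noise
        assert report.probes_out / n_probes <= p_frac + 1e-12

    def test_missing_group_errors(self):
        bm = small_matrix()
        blood_only = BetaMatrix(
            bm.values[bm.samples_in("blood")],
            bm.group_labels[bm.group_labels == "blood"])
        with pytest.raises(ValueError):
            stage_differential(blood_only)


class TestValidation:
    def test_planted_markers_replicate(self):
        bm = small_matrix(seed=1)
        val = small_matrix(seed=2, probe_ids=bm.probe_ids,
                           marker_ids=bm.marker_truth)
        report = stage_validation(bm.marker_truth, val)
        assert len(report.surviving_ids) >= 0.95 * len(bm.marker_truth)

    def test_absent_probes_dropped(self):
        bm = small_matrix(seed=1)
        report = stage_validation(bm.marker_truth + ["cg_missing"], bm)
        assert "cg_missing" not in report.surviving_ids
        assert report.probes_in == len(bm.marker_truth) + 1

    def test_alpha_one_keeps_all_present(self):
        bm = small_matrix(seed=1)
        report = stage_validation(bm.probe_ids, bm, alpha=1.0)
        assert report.surviving_ids == bm.probe_ids

    def test_empty_input_empty_report(self):
        report = stage_validation([], small_matrix())
        assert report.probes_in == 0 and report.surviving_ids == []


class TestBloodFilter:
    def test_k_exceeding_pool_keeps_all(self):
        bm = small_matrix()
        probes = bm.probe_ids[:5]
        report = stage_blood_filter(probes, bm, k=30)
        assert sorted(report.surviving_ids) == sorted(probes)

    def test_smallest_means_kept_with_lexicographic_ties(self):
        ids = ["pB", "pA", "pC"]
        values = pd.DataFrame(
            [[0.02, 0.02], [0.02, 0.02], [0.30, 0.30]],
            index=ids, columns=["b0", "b1"])
        labels = pd.Series(["blood", "blood"], index=["b0", "b1"])
        report = stage_blood_filter(ids, BetaMatrix(values, labels), k=2)
        assert report.surviving_ids == ["pA", "pB"]  # tie -> id order

    def test_planted_markers_beat_decoys(self):
        bm = small_matrix(seed=3)
        report = stage_blood_filter(bm.probe_ids, bm, k=len(bm.marker_truth))
        assert sorted(report.surviving_ids) == sorted(bm.marker_truth)


class TestPanCancer:
    def test_low_means_survive_boundary_strict(self):
        means = pd.DataFrame({"typeA": [0.05, 0.2], "typeB": [0.05, 0.05]},
                             index=["low", "edge"])
        report = stage_pan_cancer(["low", "edge"], means, max_beta=0.2)
        assert report.surviving_ids == ["low"]  # exactly 0.2 fails (strict)

    def test_missing_entries_error(self):
        means = pd.DataFrame({"typeA": [0.05]}, index=["p0"])
        with pytest.raises(KeyError):
            stage_pan_cancer(["p0", "p1"], means)


class TestCascade:
    def test_survivor_counts_monotone(self):
        bm = small_matrix(seed=5)
        val = small_matrix(seed=6, probe_ids=bm.probe_ids,
                           marker_ids=bm.marker_truth)
        res = run_cascade(bm, val, bm, bm, ScreeningConfig(top_k=10))
        counts = [s.probes_in for s in res.stages] + [res.stages[-1].probes_out]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert res.final_probes == res.stages[-1].surviving_ids

    def test_zero_markers_yield_empty_final(self):
        bm = small_matrix(seed=7, n_markers=0)
        val = small_matrix(seed=8, probe_ids=bm.probe_ids, marker_ids=[])
        res = run_cascade(bm, val, bm, bm)
        assert res.final_probes == []

    def test_composition_with_vacuous_first_stage(self):
        """With stage-1 thresholds loosened to pass-all, the cascade equals
        the composition of stages 2-4 applied to every probe."""
        bm = small_matrix(seed=9)
        val = small_matrix(seed=10, probe_ids=bm.probe_ids,
                           marker_ids=bm.marker_truth)
        cfg = ScreeningConfig(alpha=1.0, fold_min=1.0, beta_tumor_min=0.0,
                              beta_normal_max=1.0, top_k=10)
        res = run_cascade(bm, val, bm, bm, cfg)
        s2 = stage_validation(bm.probe_ids, val, cfg.validation_alpha)
        s3 = stage_blood_filter(s2.surviving_ids, bm, cfg.top_k)
        s4 = stage_pan_cancer(s3.surviving_ids, bm, cfg.pan_max)
        assert res.final_probes == s4.surviving_ids

    def test_stage_idempotence(self):
        bm = small_matrix(seed=11)
        r1 = stage_differential(bm)
        sub = BetaMatrix(bm.values.loc[r1.surviving_ids], bm.group_labels,
                         marker_truth=bm.marker_truth)
        r2 = stage_differential(sub)
        assert r2.surviving_ids == r1.surviving_ids

    def test_row_and_column_order_invariance(self):
        bm = small_matrix(seed=12)
        rng = np.random.default_rng(0)
        rows = rng.permutation(bm.values.index)
        cols = rng.permutation(bm.values.columns)
        shuffled = BetaMatrix(bm.values.loc[rows, cols], bm.group_labels,
                              marker_truth=bm.marker_truth)
        a = stage_differential(bm)
        b = stage_differential(shuffled)
        assert sorted(a.surviving_ids) == sorted(b.surviving_ids)
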