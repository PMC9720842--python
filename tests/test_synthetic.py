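"""Synthetic-cohort generators: calibration, moment recovery, determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from liquidhcc.synthetic import (
    CalibrationError,
    CountDistribution,
    CtDistribution,
    calibrate_censored_distribution,
    censored_normal_moments,
    default_count_params,
    gen_beta_matrix,
    gen_cell_table,
    gen_ctc_counts,
    gen_qmsp_cohort,
    resample_empirical,
)
from liquidhcc.ctc import classify_cells


def quadrature_censored_moments(mu, sigma, ceiling):
    """Independent oracle: censored-normal mean/SD by numerical integration."""
    pdf = stats.norm(mu, sigma).pdf
    lo, hi = mu - 12 * sigma, ceiling
    m1 = integrate.quad(lambda x: x * pdf(x), lo, hi)[0]
    m2 = integrate.quad(lambda x: x * x * pdf(x), lo, hi)[0]
    tail = stats.norm(mu, sigma).sf(ceiling)
    m1 += ceiling * tail
    m2 += ceiling**2 * tail
    return m1, math.sqrt(m2 - m1 * m1)


class TestCalibration:
    @pytest.mark.parametrize(
        "target_mean,target_sd",
        [(44.46, 1.78), (37.44, 3.99), (38.49, 4.74), (30.53, 0.55)],
    )
    def test_censored_moments_match_targets(self, target_mean, target_sd):
        """Calibrated latent parameters reproduce the target censored moments,
        verified against a quadrature oracle."""
        d = calibrate_censored_distribution(target_mean, target_sd, 45.0)
        m, s = quadrature_censored_moments(d.latent_mean, d.latent_sd, 45.0)
        assert m == pytest.approx(target_mean, abs=1e-3)
        assert s == pytest.approx(target_sd, abs=1e-3)

    def test_zero_sd_is_point_mass(self):
        d = calibrate_censored_distribution(45.0, 0.0, 45.0)
        assert (d.latent_mean, d.latent_sd) == (45.0, 0.0)
        x = d.sample(100, np.random.default_rng(0))
        assert np.all(x == 45.0)

    def test_no_censoring_returns_targets(self):
        d = calibrate_censored_distribution(10.0, 1.0, 45.0)
        assert d.latent_mean == pytest.approx(10.0)
        assert d.latent_sd == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "mean,sd", [(46.0, 1.0), (45.0, 2.0), (44.0, -1.0)]
    )
    def test_infeasible_targets_raise(self, mean, sd):
        with pytest.raises(CalibrationError):
            calibrate_censored_distribution(mean, sd, 45.0)

    def test_sampling_respects_ceiling_and_moments(self):
        d = calibrate_censored_distribution(44.46, 1.78, 45.0)
        x = d.sample(100_000, np.random.default_rng(7))
        assert x.max() <= 45.0
        se_mean = 1.78 / math.sqrt(len(x))
        assert x.mean() == pytest.approx(44.46, abs=3 * se_mean)
        assert x.std(ddof=1) == pytest.approx(1.78, abs=0.05)


class TestQmspCohort:
    def test_point_mass_control_riplet(self, hcc_ct_params, control_ct_params):
        df = gen_qmsp_cohort(hcc_ct_params, control_ct_params, 5, 8, seed=3)
        controls = df[df["group"] == "control"]
        assert np.all(controls["ct_riplet"] == 45.0)

    def test_empty_stratum(self, hcc_ct_params, control_ct_params):
        df = gen_qmsp_cohort(hcc_ct_params, control_ct_params, 0, 4, seed=0)
        assert (df["group"] == "HCC").sum() == 0
        assert len(df) == 4

    def test_moments_converge(self, hcc_ct_params, control_ct_params):
        n = 10_000
        df = gen_qmsp_cohort(hcc_ct_params, control_ct_params, n, n, seed=11)
        targets = {("HCC", "ct_gnb4"): (37.44, 3.99),
                   ("HCC", "ct_riplet"): (38.49, 4.74),
                   ("control", "ct_gnb4"): (44.46, 1.78)}
        for (group, col), (mean, sd) in targets.items():
            x = df.loc[df["group"] == group, col]
            assert x.mean() == pytest.approx(mean, abs=3 * sd / math.sqrt(n))

    def test_seed_determinism(self, hcc_ct_params, control_ct_params):
        a = gen_qmsp_cohort(hcc_ct_params, control_ct_params, 10, 10, seed=5)
        b = gen_qmsp_cohort(hcc_ct_params, control_ct_params, 10, 10, seed=5)
        assert a.equals(b)

    def test_gene_correlation_copula(self, hcc_ct_params, control_ct_params):
        df = gen_qmsp_cohort(hcc_ct_params, control_ct_params, 5000, 0,
                             seed=2, gene_corr=0.8)
        r = np.corrcoef(df["ct_gnb4"], df["ct_riplet"])[0, 1]
        assert r > 0.5  # censoring attenuates but cannot erase the correlation


class TestCtcCounts:
    def test_hcc_defaults_mean_and_variance(self):
        params = default_count_params("hcc")
        x = gen_ctc_counts(params, 10_000, seed=4)
        se = math.sqrt(params.variance / len(x))
        assert x.mean() == pytest.approx(5.0, abs=3 * se)
        assert x.var(ddof=1) == pytest.approx(16.81, abs=1.5)
        assert x.min() >= 0 and np.issubdtype(x.dtype, np.integer)

    def test_determinism(self):
        p = default_count_params("hcc")
        assert gen_ctc_counts(p, 1, seed=9)[0] == gen_ctc_counts(p, 1, seed=9)[0]

    def test_poisson_limit(self):
        p = CountDistribution(mean=3.0, dispersion=math.inf)
        assert p.variance == pytest.approx(3.0)
        x = p.sample(50_000, np.random.default_rng(0))
        assert x.var() == pytest.approx(3.0, rel=0.05)


class TestBetaMatrix:
    def test_values_clipped_and_truth_recorded(self):
        bm = gen_beta_matrix(n_probes=50, n_markers=5, seed=1)
        v = bm.values.to_numpy()
        assert v.min() >= 0.0 and v.max() <= 1.0
        assert len(bm.marker_truth) == 5
        assert set(bm.marker_truth) <= set(bm.probe_ids)

    def test_no_markers(self):
        bm = gen_beta_matrix(n_probes=20, n_markers=0, seed=1)
        assert bm.marker_truth == []

    def test_validation_matrix_shares_layout(self):
        a = gen_beta_matrix(n_probes=40, n_markers=4, seed=1)
        b = gen_beta_matrix(probe_ids=a.probe_ids, marker_ids=a.marker_truth, seed=2)
        assert b.probe_ids == a.probe_ids
        assert b.marker_truth == a.marker_truth
        assert not np.allclose(a.values.to_numpy(), b.values.to_numpy())

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_bounds_hold_for_any_seed(self, seed):
        bm = gen_beta_matrix(n_probes=30, n_markers=3,
                             group_sizes={"tumor": 4, "normal": 4, "blood": 3,
                                          "pan_cancer_1": 3},
                             seed=seed)
        v = bm.values.to_numpy()
        assert v.min() >= 0.0 and v.max() <= 1.0


class TestCellTable:
    def test_all_malignant_high_recall(self):
        cells = gen_cell_table(500, 1.0, seed=6)
        classified = classify_cells(cells)
        recall = (classified["cell_class"] == "CTC").mean()
        assert recall >= 0.9

    def test_all_benign_near_zero_calls(self):
        cells = gen_cell_table(500, 0.0, seed=6)
        classified = classify_cells(cells)
        assert (classified["cell_class"] == "CTC").mean() <= 0.02

    def test_determinism(self):
        a = gen_cell_table(50, 0.5, seed=8)
        b = gen_cell_table(50, 0.5, seed=8)
        assert a.equals(b)


def test_resample_empirical_support(control_gnb4_vector):
    x = resample_empirical(control_gnb4_vector, 1000, seed=0)
    assert set(np.round(x, 6)) <= set(np.round(control_gnb4_vector, 6))
    # the censored point mass dominates: about 10/11 of draws sit at 45
    assert (x == 45.0).mean() == pytest.approx(10 / 11, abs=0.05)
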