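"""Phenotype score gamma, weight calibration, and the (rho x period) map."""

import numpy as np
import pytest

from optorho import (
    CalibrationError,
    KineticParams,
    Trace,
    WindowError,
    calibrate_weight,
    compute_gamma,
    intensity_sweep,
    simulate_cdc42,
    simulate_rhoa,
)
from optorho.phenotype import _step_responses
from optorho.stimulus import analytic_to_trace, step_input


def _grid(T=130.0, dt=1.0):
    return np.arange(0.0, T + dt / 2, dt)


class TestGamma:
    def test_identical_traces_score_zero_mixed(self):
        t = _grid()
        r = Trace(t, 1.0 + 0.3 * np.sin(t / 40.0), channel="r")
        score = compute_gamma(r, r, weight=1.0)
        assert score.gamma == 0.0
        assert score.label == "mixed"

    def test_null_stimulus_scores_zero(self):
        t = _grid()
        flat = Trace(t, np.ones_like(t), channel="r")
        assert compute_gamma(flat, flat, weight=2.0).gamma == 0.0

    def test_rho_zero_with_dominant_rhoa_weight_retracts(self, kin, weight):
        r, c = _step_responses(0.0, kin, fold=2.0, T=120.0, dt=0.5)
        score = compute_gamma(r, c, weight)
        assert score.gamma > 0
        assert score.label == "retraction"

    def test_gamma_bounded_by_construction(self, kin, weight):
        for rho in np.linspace(0.0, 3.0, 7):
            r, c = _step_responses(rho, kin, fold=2.0, T=120.0, dt=0.5)
            assert -1.0 <= compute_gamma(r, c, weight).gamma <= 1.0

    def test_gamma_monotone_decreasing_in_rho(self, kin, weight):
        gammas = []
        for rho in np.linspace(0.0, 2.0, 50):
            r, c = _step_responses(rho, kin, fold=2.0, T=120.0, dt=1.0)
            gammas.append(compute_gamma(r, c, weight).gamma)
        assert np.all(np.diff(gammas) < 0)

    def test_short_trace_rejected(self):
        t = np.arange(0.0, 60.0, 1.0)
        tr = Trace(t, np.ones_like(t))
        with pytest.raises(WindowError):
            compute_gamma(tr, tr, weight=1.0, window=120.0)

    def test_raw_difference_variant_matches_sign(self, kin, weight):
        r, c = _step_responses(1.5, kin, fold=2.0, T=120.0, dt=0.5)
        norm = compute_gamma(r, c, weight).gamma
        raw = compute_gamma(r, c, weight, normalized=False).gamma
        assert np.sign(norm) == np.sign(raw)


class TestCalibration:
    def test_weight_places_zero_at_target_and_exceeds_one(self, kin, weight):
        assert weight > 1.0
        r, c = _step_responses(0.5, kin, fold=2.0, T=120.0, dt=0.5)
        assert compute_gamma(r, c, weight).gamma == pytest.approx(0.0, abs=1e-6)

    def test_sign_pattern_around_calibrated_root(self, kin, weight):
        r_lo, c_lo = _step_responses(0.25, kin, fold=2.0, T=120.0, dt=0.5)
        r_hi, c_hi = _step_responses(1.0, kin, fold=2.0, T=120.0, dt=0.5)
        assert compute_gamma(r_lo, c_lo, weight).gamma > 0
        assert compute_gamma(r_hi, c_hi, weight).gamma < 0

    def test_doubling_step_amplitude_preserves_signs(self, kin, weight):
        for rho, sign in ((0.25, 1), (1.0, -1)):
            r, c = _step_responses(rho, kin, fold=3.0, T=120.0, dt=0.5)
            assert np.sign(compute_gamma(r, c, weight).gamma) == sign

    def test_calibration_idempotent(self, kin, weight):
        again = calibrate_weight(kin)
        assert again == pytest.approx(weight, abs=1e-6)

    def test_no_bracket_raises(self, kin):
        with pytest.raises(CalibrationError):
            calibrate_weight(kin, bracket=(2e3, 1e4))


class TestPhenotypeMap:
    def test_low_expression_row_always_retracts(self, phenotype_map):
        assert set(phenotype_map.labels[0]) == {"retraction"}

    def test_switchable_band_over_probed_periods_centers_near_half(self, phenotype_map):
        band = phenotype_map.switchable_band(period_range=(15.0, 60.0))
        assert band is not None
        lo, hi, center = band
        assert 0.35 <= center <= 0.65

    def test_frequency_flip_at_band_center(self, phenotype_map):
        # high-frequency (15 s) drives the score negative (protrusion side),
        # low-frequency (30-60 s) positive (retraction side); compared on the
        # sign of gamma because the 2x frequency contrast sits inside the
        # arbitrary gray zone at several grid points
        j15 = int(np.argmin(np.abs(phenotype_map.period_grid - 15.0)))
        j30 = int(np.argmin(np.abs(phenotype_map.period_grid - 30.0)))
        j60 = int(np.argmin(np.abs(phenotype_map.period_grid - 60.0)))
        flip = [
            i
            for i in range(phenotype_map.rho_grid.size)
            if phenotype_map.gamma[i, j15] < 0 < phenotype_map.gamma[i, j30]
        ]
        assert flip, "no rho row flips sign between 15 s and 30 s periods"
        center = phenotype_map.rho_grid[flip].mean()
        assert 0.35 <= center <= 0.65
        i = int(np.argmin(np.abs(phenotype_map.rho_grid - center)))
        assert phenotype_map.gamma[i, j15] < 0 < phenotype_map.gamma[i, j60]

    def test_labels_single_boundary_in_period_after_gray_zone(self, phenotype_map):
        # collapsing the gray zone, each rho row is protrusions (short
        # periods) followed by retractions (long periods)
        for i in range(phenotype_map.rho_grid.size):
            seq = [lab for lab in phenotype_map.labels[i] if lab != "mixed"]
            runs = []
            for lab in seq:
                if not runs or runs[-1] != lab:
                    runs.append(lab)
            assert runs in ([], ["protrusion"], ["retraction"], ["protrusion", "retraction"])

    def test_gamma_monotone_in_rho_at_every_period(self, phenotype_map):
        assert np.all(np.diff(phenotype_map.gamma, axis=0) <= 1e-9)


class TestIntensitySweep:
    def test_low_expression_never_switches(self, kin, weight):
        sweep = intensity_sweep(0.2, 30.0, kin, weight)
        assert {lab for _, _, lab in sweep["labels"]} == {"retraction"}
        assert not sweep["switched"]

    def test_high_expression_never_switches(self, kin, weight):
        sweep = intensity_sweep(1.5, 30.0, kin, weight)
        assert {lab for _, _, lab in sweep["labels"]} == {"protrusion"}
        assert not sweep["switched"]

    def test_unit_fold_is_null_stimulus(self, kin, weight):
        sweep = intensity_sweep(0.8, 30.0, kin, weight, fold_range=(1.0, 1.0), n_folds=1)
        fold, gamma, label = sweep["labels"][0]
        assert gamma == 0.0
        assert label == "mixed"
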