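import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ramdi.errors import ComputationError
from ramdi.mdi_index import (
    AdjustConfig,
    PhaseSummary,
    PipelineConfig,
    beat_auc,
    compute_ra_mdi,
    covariate_adjust,
    raw_distensibility,
    summarize_phase,
)
from ramdi.pulse_analysis import (
    EnvelopeTrend,
    HeartRateSeries,
    PulsePeakSeries,
    ValidityMask,
    detect_peaks,
)
from ramdi.signal_model import SubjectProfile
from ramdi.simulator import HyperaemiaResponse, NoiseModel, synth_session

FS = 200.0


def _summary(phase="resting", env=1.0, hr=70.0, vf=1.0):
    return PhaseSummary(phase=phase, mean_hr=hr, median_envelope=env,
                        mean_beat_auc=0.2, valid_fraction=vf)


def _trend(values, start=645.0, hop=15.0):
    centers = start + hop * np.arange(len(values))
    return EnvelopeTrend(centers, np.asarray(values, float), 30.0)


class TestBeatAUC:
    def test_rectangular_pulses(self):
        # 0.2 s unit rectangles once per second
        n = int(10 * FS)
        x = np.zeros(n)
        for k in range(10):
            x[int(k * FS): int(k * FS + 0.2 * FS)] = 1.0
        peaks = PulsePeakSeries(np.arange(10) * int(FS) + 20, np.ones(10), FS)
        areas = beat_auc(x, peaks, FS)
        np.testing.assert_allclose(areas, 0.2, atol=2 / FS)

    def test_half_sine_closed_form(self):
        # beats: half-sine of duration d and amplitude A, area 2 A d / pi
        A, d = 1.5, 0.4
        n = int(20 * FS)
        x = np.zeros(n)
        for k in range(20):
            seg = np.arange(int(d * FS))
            x[k * int(FS): k * int(FS) + seg.size] = A * np.sin(np.pi * seg / (d * FS))
        peaks = detect_peaks(x, FS)
        areas = beat_auc(x, peaks, FS)
        np.testing.assert_allclose(areas, 2 * A * d / np.pi, rtol=0.01)

    def test_linearity_in_scale(self):
        x, _, _ = __import__("ramdi.simulator", fromlist=["synth_beat_train"]).synth_beat_train(
            30, FS, 70, jitter_sd=0
        )
        peaks = detect_peaks(x, FS)
        a1 = beat_auc(x, peaks, FS)
        a3 = beat_auc(3 * x, peaks, FS)
        np.testing.assert_allclose(a3, 3 * a1, rtol=1e-12)

    def test_too_few_peaks_empty(self):
        peaks = PulsePeakSeries(np.array([50]), np.array([1.0]), FS)
        assert beat_auc(np.ones(1000), peaks, FS).size == 0


class TestRawDistensibility:
    def test_no_change_scores_zero(self):
        raw, flags = raw_distensibility(_summary(), _trend([1, 1, 1]), _summary(), _trend([1, 1, 1]))
        assert raw == 0.0 and flags == []

    def test_doubling_occluded_envelope_scores_one(self):
        raw, _ = raw_distensibility(_summary(), _trend([1.2, 2.0, 1.5]), _summary(), _trend([1, 1, 1]))
        assert raw == pytest.approx(1.0)

    def test_common_mode_doubling_cancels(self):
        raw, _ = raw_distensibility(
            _summary(env=1.0), _trend([2, 2, 2]), _summary(env=1.0), _trend([2, 2, 2])
        )
        assert raw == 0.0

    def test_unusable_control_flags_and_uses_unity(self):
        raw, flags = raw_distensibility(_summary(), _trend([1.5]), None, None)
        assert raw == pytest.approx(0.5)
        assert "control_unusable" in flags

    def test_zero_baseline_envelope_is_an_error(self):
        with pytest.raises(ComputationError):
            raw_distensibility(_summary(env=0.0), _trend([1.0]), _summary(), _trend([1.0]))


class TestCovariateAdjust:
    CFG = AdjustConfig(enabled=True, gamma_map=1.0, gamma_age=0.5, gamma_hr=1.0)

    def _phases(self, hr_rest=70.0, hr_relax=70.0):
        return {"resting": _summary(hr=hr_rest), "occlusion": _summary(phase="occlusion"),
                "relaxation": _summary(phase="relaxation", hr=hr_relax)}

    def test_reference_profile_factor_is_one(self):
        subj = SubjectProfile("ref", age=40, sex="male", sbp=103, dbp=88)  # MAP = 93
        ra, factor, flags = covariate_adjust(0.5, subj, self._phases(), self.CFG)
        assert factor == pytest.approx(1.0)
        assert ra == pytest.approx(0.5)
        assert flags == []

    def test_doubling_map_halves_factor(self):
        subj_ref = SubjectProfile("a", age=40, sex="male", sbp=103, dbp=88)      # MAP 93
        subj_2x = SubjectProfile("b", age=40, sex="male", sbp=216, dbp=171)      # MAP 186
        cfg = AdjustConfig(enabled=True, gamma_map=1.0)
        _, f_ref, _ = covariate_adjust(1.0, subj_ref, self._phases(), cfg)
        _, f_2x, _ = covariate_adjust(1.0, subj_2x, self._phases(), cfg)
        assert f_2x == pytest.approx(f_ref / 2)

    def test_missing_covariate_returns_unadjusted(self):
        subj = SubjectProfile("c", age=40)  # no sex, no pressures
        ra, factor, flags = covariate_adjust(0.7, subj, self._phases(), self.CFG)
        assert (ra, factor) == (0.7, 1.0)
        assert "unadjusted" in flags

    @given(
        age=st.floats(18, 100),
        dbp=st.floats(40, 110),
        pulse=st.floats(10, 100),
        hr_rest=st.floats(45, 110),
        hr_relax=st.floats(45, 110),
        female=st.booleans(),
    )
    def test_factor_strictly_positive_over_domain(self, age, dbp, pulse, hr_rest, hr_relax, female):
        subj = SubjectProfile("d", age=age, sex="female" if female else "male",
                              sbp=dbp + pulse, dbp=dbp)
        cfg = AdjustConfig(enabled=True, gamma_map=0.8, gamma_age=0.4, gamma_hr=0.6,
                           sex_factor_female=1.1)
        _, factor, flags = covariate_adjust(1.0, subj, self._phases(hr_rest, hr_relax), cfg)
        assert flags == []
        assert np.isfinite(factor) and factor > 0

    def test_disabled_adjustment_is_identity_without_flags(self):
        subj = SubjectProfile("e")
        ra, factor, flags = covariate_adjust(0.9, subj, self._phases(), AdjustConfig())
        assert (ra, factor, flags) == (0.9, 1.0, [])


class TestSummarizePhase:
    def test_gated_out_phase_has_zero_valid_fraction(self):
        interval = (0, int(60 * FS))
        mask = ValidityMask.all_valid(int(120 * FS))
        mask.invalidate(*interval, "manual")
        hr = HeartRateSeries(np.array([30.0]), np.array([np.nan]), np.array([False]), 60.0)
        env = EnvelopeTrend(np.empty(0), np.empty(0), 30.0)
        s = summarize_phase(interval, "baseline", FS, mask, hr, env)
        assert s.valid_fraction == 0.0
        assert np.isnan(s.mean_hr) and np.isnan(s.median_envelope)

    def test_clean_baseline_heart_rate(self, quiet_session):
        rec, ann = quiet_session
        res = compute_ra_mdi(rec)
        s = res.phase_summaries["occluded"]["resting"]
        assert s.mean_hr == pytest.approx(ann.hr_bpm, abs=1.0)
        assert s.median_envelope == pytest.approx(ann.base_amplitude, rel=0.06)


class TestComputeRaMdi:
    def test_zero_response_session_scores_near_zero(self, zero_response_session):
        rec, _ = zero_response_session
        res = compute_ra_mdi(rec)
        assert res.ra_mdi < 0.05

    def test_deterministic(self, noisy_session):
        import json

        rec, _ = noisy_session
        r1 = compute_ra_mdi(rec)
        r2 = compute_ra_mdi(rec)
        # serialize for a NaN-tolerant bit-identity comparison
        assert json.dumps(r1.to_dict()) == json.dumps(r2.to_dict())

    def test_incomplete_occlusion_flagged_not_fatal(self, subject):
        rec, _ = synth_session(subject, noise=NoiseModel.quiet(), seed=77,
                               occlusion_residual=0.5)
        res = compute_ra_mdi(rec)
        assert "occlusion_incomplete" in res.qc_flags

    def test_common_gain_drift_changes_index_little(self, subject):
        from dataclasses import replace

        rec, _ = synth_session(subject, noise=NoiseModel.quiet(), seed=55)
        base = compute_ra_mdi(rec).ra_mdi
        t = np.arange(rec.n_samples) / rec.fs
        # slow common-mode sensor gain drift; the index shifts by at most the
        # gain excursion itself, so a 2% drift must stay well inside 5%
        gain = 1.0 + 0.02 * np.sin(2 * np.pi * t / 400.0)
        drifted = replace(rec, occluded_arm=rec.occluded_arm * gain,
                          control_arm=rec.control_arm * gain)
        assert compute_ra_mdi(drifted).ra_mdi == pytest.approx(base, rel=0.05)

    def test_auc_index_mode_tracks_response(self, subject):
        cfg = PipelineConfig.from_dict({"index.mode": "auc"})
        lo, _ = synth_session(subject, HyperaemiaResponse(dilation_amplitude=0.2),
                              NoiseModel.quiet(), seed=21)
        hi, _ = synth_session(subject, HyperaemiaResponse(dilation_amplitude=1.0),
                              NoiseModel.quiet(), seed=21)
        assert compute_ra_mdi(hi, cfg).ra_mdi > compute_ra_mdi(lo, cfg).ra_mdi > 0


class TestPipelineConfig:
    def test_flat_dotted_keys(self):
        cfg = PipelineConfig.from_dict(
            {"notch.f0_hz": 60.0, "dc.window_s": 8.0, "index.mode": "auc",
             "adjust": {"enabled": True, "gamma_map": 1.0}}
        )
        assert cfg.notch.f0_hz == 60.0
        assert cfg.dc_window_s == 8.0
        assert cfg.index_mode == "auc"
        assert cfg.adjust.enabled and cfg.adjust.gamma_map == 1.0
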