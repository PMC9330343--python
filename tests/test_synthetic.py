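"""Generator behavior: determinism, ranges, and the pain->HRV coupling."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from anihrv import (
    PainTrajectory,
    SynthConfig,
    gen_cohort,
    gen_ecg_from_rr,
    gen_pain_trajectory,
    gen_rater_scores,
    gen_rr_from_pain,
)
from anihrv.synthetic import write_cohort


def flat_pain(level: float, duration: int = 900) -> PainTrajectory:
    t = np.arange(float(duration))
    return PainTrajectory(time_s=t, pain=np.full(duration, float(level)))


class TestPainTrajectory:
    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            gen_pain_trajectory(60, n_events=0, seed=0)

    def test_no_events_flat_after_spike(self):
        p = gen_pain_trajectory(900, n_events=0, seed=0)
        # after ~5 time constants the spike is gone: the tail is constant
        tail = p.pain[400:]
        assert np.ptp(tail) < 1.0
        assert 15.0 <= tail.mean() <= 26.0

    def test_initial_spike_present_and_decaying(self):
        p = gen_pain_trajectory(900, n_events=0, seed=1)
        assert p.pain[0] > p.pain[200] + 30
        assert np.all(np.diff(p.pain[:120]) <= 0)

    def test_determinism(self):
        a = gen_pain_trajectory(900, n_events=3, seed=5)
        b = gen_pain_trajectory(900, n_events=3, seed=5)
        np.testing.assert_array_equal(a.pain, b.pain)

    def test_event_count_matches_peak_finder(self):
        # independent oracle: scipy peak finding above baseline + 5
        p = gen_pain_trajectory(900, n_events=3, seed=1)
        baseline = np.median(p.pain[300:])
        peaks, _ = sp_signal.find_peaks(p.pain[120:], height=baseline + 5, prominence=5, distance=30)
        assert len(peaks) == 3

    def test_values_bounded(self):
        for seed in range(5):
            p = gen_pain_trajectory(900, n_events=5, seed=seed)
            assert np.all(p.pain >= 0) and np.all(p.pain <= 100)


class TestRRFromPain:
    def test_zero_pain_oscillates_around_base(self):
        cfg = SynthConfig(rr_noise_sd_ms=0.0, artifact_rate=0.0, lf_drift_amp_ms=0.0)
        rr, _ = gen_rr_from_pain(flat_pain(0), cfg, seed=0)
        assert abs(rr.rr_ms.mean() - cfg.base_rr_ms) < 2.0
        ptp = np.ptp(rr.rr_ms)
        assert ptp == pytest.approx(2 * cfg.rsa_amp_max_ms, rel=0.1)

    def test_max_pain_kills_hf_modulation(self):
        cfg = SynthConfig(rr_noise_sd_ms=0.0, artifact_rate=0.0, lf_drift_amp_ms=0.0)
        rr, _ = gen_rr_from_pain(flat_pain(100), cfg, seed=0)
        assert abs(rr.rr_ms.mean() - (cfg.base_rr_ms - 100 * cfg.pain_rr_slope)) < 2.0
        assert np.ptp(rr.rr_ms) < 2.0

    def test_artifact_count_within_binomial_interval(self):
        # ~1000 beats at rate 0.01: count within the central 99% binomial range
        cfg = SynthConfig(duration_s=800, artifact_rate=0.01, rr_noise_sd_ms=0.0)
        pain = flat_pain(20, 800)
        rr, arts = gen_rr_from_pain(pain, cfg, seed=42)
        n_beats = len(rr)
        from scipy.stats import binom

        lo, hi = binom.ppf([0.005, 0.995], n_beats, cfg.artifact_rate)
        assert lo <= len(arts) <= hi

    def test_rejects_out_of_range_pain(self):
        cfg = SynthConfig()
        bad = PainTrajectory.__new__(PainTrajectory)
        object.__setattr__(bad, "time_s", np.arange(200.0))
        object.__setattr__(bad, "pain", np.full(200, 150.0))
        with pytest.raises(ValueError):
            gen_rr_from_pain(bad, cfg, seed=0)

    def test_hf_power_lower_under_high_pain(self):
        # module invariant: windows whose mean pain differs by >= 30 points
        # have strictly lower HF-band power in the higher-pain window
        cfg = SynthConfig(rr_noise_sd_ms=0.0, artifact_rate=0.0)
        lo, _ = gen_rr_from_pain(flat_pain(10), cfg, seed=3)
        hi, _ = gen_rr_from_pain(flat_pain(70), cfg, seed=3)

        def hf_power(rr):
            from anihrv import resample_rr

            u = resample_rr(rr)
            f, pxx = sp_signal.welch(u.values - u.values.mean(), fs=u.rate_hz, nperseg=512)
            band = (f >= 0.15) & (f <= 0.5)
            return np.trapezoid(pxx[band], f[band])

        assert hf_power(hi) < hf_power(lo)


class TestRaterScores:
    def test_zero_noise_zero_bias_equals_pain(self):
        cfg = SynthConfig(rater_biases=(0.0, 0.0), rater_noise_sd=0.0)
        pain = gen_pain_trajectory(900, 2, seed=0)
        rs = gen_rater_scores(pain, cfg, seed=0)
        np.testing.assert_allclose(rs.scores, np.column_stack([pain.pain, pain.pain]))

    def test_bias_shifts_mean(self):
        cfg = SynthConfig(rater_noise_sd=0.0)  # biases (0,0,0,-10,0)
        pain = flat_pain(50)
        rs = gen_rater_scores(pain, cfg, seed=0)
        assert rs.scores[:, 3].mean() == pytest.approx(pain.pain.mean() - 10, abs=0.1)

    def test_noise_sd_near_nominal(self):
        # AR(1) noise at rho 0.99 has few effective dof: use a long record
        cfg = SynthConfig(duration_s=3600)
        pain = flat_pain(50, 3600)
        rs = gen_rater_scores(pain, cfg, seed=0)
        resid = rs.scores - pain.pain[:, None] - np.asarray(cfg.rater_biases)[None, :]
        sds = resid.std(axis=0)
        assert 2.0 <= sds.mean() <= 4.0

    def test_scores_bounded(self, default_cohort):
        for p in default_cohort:
            assert np.all(p.raters.scores >= 0) and np.all(p.raters.scores <= 100)


class TestSyntheticEcg:
    def test_peaks_at_beat_times(self):
        from anihrv import RRSeries

        rr_ms = np.full(10, 800.0)
        rr = RRSeries(beat_time_s=np.cumsum(rr_ms) / 1000, rr_ms=rr_ms)
        ecg = gen_ecg_from_rr(rr, fs_hz=512, seed=0)
        assert len(ecg.true_beat_time_s) == 11  # opening beat + 10 stamps
        for bt in ecg.true_beat_time_s:
            c = int(round(bt * 512))
            lo = max(0, c - 2)
            w = ecg.record.samples[lo : c + 3]
            assert np.argmax(w) + lo == pytest.approx(c, abs=2)

    def test_deterministic(self):
        from anihrv import RRSeries

        rr_ms = np.full(20, 750.0)
        rr = RRSeries(beat_time_s=np.cumsum(rr_ms) / 1000, rr_ms=rr_ms)
        a = gen_ecg_from_rr(rr, fs_hz=256, seed=9, noise_sd=0.05)
        b = gen_ecg_from_rr(rr, fs_hz=256, seed=9, noise_sd=0.05)
        np.testing.assert_array_equal(a.record.samples, b.record.samples)

    def test_rejects_low_rate_and_empty(self):
        from anihrv import RRSeries

        rr_ms = np.full(5, 800.0)
        rr = RRSeries(beat_time_s=np.cumsum(rr_ms) / 1000, rr_ms=rr_ms)
        with pytest.raises(ValueError):
            gen_ecg_from_rr(rr, fs_hz=64, seed=0)


class TestCohort:
    def test_shapes_and_distinct_series(self, clean_cohort):
        assert len(clean_cohort) == 4
        assert all(len(p.pain) == 900 for p in clean_cohort)
        assert all(p.raters.scores.shape == (900, 5) for p in clean_cohort)
        a, b = clean_cohort.patients[0], clean_cohort.patients[1]
        assert len(a.rr) != len(b.rr) or not np.array_equal(a.rr.rr_ms, b.rr.rr_ms)

    def test_bit_identical_regeneration(self):
        cfg = SynthConfig(n_patients=2, duration_s=300, seed=12)
        c1, c2 = gen_cohort(cfg), gen_cohort(cfg)
        for p1, p2 in zip(c1, c2):
            np.testing.assert_array_equal(p1.rr.rr_ms, p2.rr.rr_ms)
            np.testing.assert_array_equal(p1.raters.scores, p2.raters.scores)
            np.testing.assert_array_equal(p1.pain.pain, p2.pain.pain)

    def test_roundtrip_csv(self, tmp_path, default_cohort):
        from anihrv.io import read_eaps_csv, read_rr_csv

        write_cohort(default_cohort, tmp_path)
        p = default_cohort.patients[0]
        rr = read_rr_csv(tmp_path / f"rr_{p.patient_id}.csv")
        np.testing.assert_allclose(rr.rr_ms, p.rr.rr_ms)
        rs = read_eaps_csv(tmp_path / f"eaps_{p.patient_id}.csv")
        np.testing.assert_allclose(rs.scores, p.raters.scores)
        assert rs.rater_ids == p.raters.rater_ids

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SynthConfig(n_patients=0)
        with pytest.raises(ValueError):
            SynthConfig(duration_s=60)
        with pytest.raises(ValueError):
            SynthConfig(rsa_freq_hz=0.6)
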