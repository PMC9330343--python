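"""Windowing, normalization, wavelet band-pass, envelope areas, ANI formula."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anihrv import (
    AniConfig,
    RRSeries,
    UniformRRSeries,
    ani_from_aucmin,
    center_and_normalize,
    compute_ani_series,
    compute_envelope,
    extract_windows,
    subwindow_aucs,
    wavelet_rrhf,
)
from anihrv.ani import AniWindow, RRHF


def uniform(values, rate=8.0):
    return UniformRRSeries(values=np.asarray(values, dtype=float), rate_hz=rate)


class TestExtractWindows:
    def test_exactly_one_window(self):
        wins = extract_windows(uniform(np.arange(512)))
        assert len(wins) == 1
        assert wins[0].N == 512

    @pytest.mark.parametrize("k", [0, 1, 5, 17])
    def test_window_count_arithmetic(self, k):
        wins = extract_windows(uniform(np.zeros(512 + 8 * k)))
        assert len(wins) == k + 1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            extract_windows(uniform(np.zeros(511)))

    def test_end_times_advance_by_one_second(self):
        wins = extract_windows(uniform(np.zeros(512 + 8 * 3)))
        ends = [w.window_end_time_s for w in wins]
        np.testing.assert_allclose(np.diff(ends), 1.0)


class TestCenterAndNormalize:
    def test_toy_example(self):
        w = AniWindow(values=np.array([1.0, 2.0, 3.0]), window_end_time_s=0.0)
        out = center_and_normalize(w)
        assert out.M == pytest.approx(2.0)
        assert out.S == pytest.approx(np.sqrt(2.0))
        np.testing.assert_allclose(out.values, [-0.7071, 0.0, 0.7071], atol=1e-4)

    def test_constant_window_degenerate(self):
        out = center_and_normalize(AniWindow(values=np.full(512, 800.0), window_end_time_s=0.0))
        assert out.degenerate
        assert np.all(out.values == 0.0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_unit_norm_invariant(self, seed):
        rng = np.random.default_rng(seed)
        w = AniWindow(values=800 + 30 * rng.standard_normal(512), window_end_time_s=0.0)
        out = center_and_normalize(w)
        assert abs(np.linalg.norm(out.values) - 1.0) < 1e-9
        assert abs(out.values.sum()) < 1e-9


class TestWaveletBandpass:
    @staticmethod
    def _energy_ratio(freq_hz):
        t = np.arange(512) / 8.0
        x = np.sin(2 * np.pi * freq_hz * t)
        w = center_and_normalize(AniWindow(values=x, window_end_time_s=0.0))
        h = wavelet_rrhf(w)
        return np.sum(h.values**2) / np.sum(w.values**2)

    def test_in_band_energy_retained(self):
        assert self._energy_ratio(0.25) >= 0.8

    def test_out_of_band_energy_rejected(self):
        assert self._energy_ratio(0.05) <= 0.2

    def test_zero_in_zero_out(self):
        w = AniWindow(values=np.zeros(512), window_end_time_s=0.0)
        h = wavelet_rrhf(w)
        assert np.all(h.values == 0.0)

    def test_depth_exceeding_length_rejected(self):
        w = AniWindow(values=np.zeros(16), window_end_time_s=0.0)
        with pytest.raises(ValueError):
            wavelet_rrhf(w, levels=(8, 9))

    def test_literal_level_config_passes_wider_band(self):
        # levels (3,4,5) additionally keep 0.5-1.0 Hz
        t = np.arange(512) / 8.0
        x = np.sin(2 * np.pi * 0.7 * t)
        w = center_and_normalize(AniWindow(values=x, window_end_time_s=0.0))
        default = np.sum(wavelet_rrhf(w, (4, 5)).values ** 2)
        literal = np.sum(wavelet_rrhf(w, (3, 4, 5)).values ** 2)
        assert literal > 2 * default


class TestEnvelope:
    def test_sine_envelope_near_amplitude(self):
        t = np.arange(512) / 8.0
        a = 0.05
        h = RRHF(values=a * np.sin(2 * np.pi * 0.25 * t), grid_rate_hz=8.0)
        env = compute_envelope(h)
        interior = slice(40, 472)
        assert np.mean(env.upper[interior]) == pytest.approx(a, rel=0.05)
        assert np.mean(env.lower[interior]) == pytest.approx(-a, rel=0.05)

    def test_maxima_lie_on_upper_line(self):
        rng = np.random.default_rng(0)
        h = RRHF(values=rng.standard_normal(256), grid_rate_hz=8.0)
        env = compute_envelope(h)
        np.testing.assert_allclose(env.upper[env.max_idx], h.values[env.max_idx])
        np.testing.assert_allclose(env.lower[env.min_idx], h.values[env.min_idx])

    def test_constant_signal_degenerate_zero_gap(self):
        h = RRHF(values=np.full(64, 0.3), grid_rate_hz=1.0)
        env = compute_envelope(h)
        assert env.degenerate
        aucs, auc_min = subwindow_aucs(env)
        assert auc_min == 0.0 and all(a == 0.0 for a in aucs)


class TestSubwindowAucs:
    def test_constant_gap(self):
        # gap 0.2 n.u. over the full 64-s window: each 16-s area is 3.2 s
        from anihrv.ani import Envelope

        t = np.arange(64.0)
        env = Envelope(
            time_s=t, upper=np.full(64, 0.1), lower=np.full(64, -0.1),
            max_idx=np.array([1, 2]), min_idx=np.array([1, 2]), window_s=64.0,
        )
        aucs, auc_min = subwindow_aucs(env)
        assert aucs == pytest.approx((3.2, 3.2, 3.2, 3.2))
        assert auc_min == pytest.approx(3.2)

    def test_sine_envelope_matches_trapezoid_oracle(self):
        t8 = np.arange(512) / 8.0
        a = 0.05
        h = RRHF(values=a * np.sin(2 * np.pi * 0.25 * t8), grid_rate_hz=8.0)
        env = compute_envelope(h)
        aucs, _ = subwindow_aucs(env)
        # oracle: ideal envelope gap is 2a over each 16-s sub-window
        for auc in aucs:
            assert auc == pytest.approx(2 * a * 16.0, rel=0.1)


class TestAniFormula:
    @pytest.mark.parametrize(
        "auc_min,expected",
        [(0.0, 9.375), (1.0, 49.21875), (2.0, 89.0625)],
    )
    def test_closed_form(self, auc_min, expected):
        assert ani_from_aucmin(auc_min) == pytest.approx(expected, abs=1e-9)

    def test_clipped_at_100(self):
        # raw value for 3.2 s is 136.875, clipped into range
        assert ani_from_aucmin(3.2) == 100.0

    def test_monotone_in_aucmin(self):
        grid = np.linspace(0.0, 3.0, 50)
        vals = [ani_from_aucmin(a) for a in grid]
        assert np.all(np.diff(vals) >= 0)
        pre_clip = [v for v in vals if v < 100.0]
        assert np.all(np.diff(pre_clip) > 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ani_from_aucmin(-0.1)


class TestFullPipeline:
    def test_point_count_and_opposite(self, clean_cohort):
        p = clean_cohort.patients[0]
        s = compute_ani_series(p.rr)
        from anihrv import filter_rr, resample_rr

        n_samples = len(resample_rr(filter_rr(p.rr)))
        assert len(s) == (n_samples - 512) // 8 + 1
        np.testing.assert_allclose(s.ani + s.opposite, 100.0)

    def test_integer_coverage_point_count(self):
        # beats every 1000 ms: T seconds of coverage -> T - 63 ANI points
        rr_ms = np.full(150, 1000.0)
        rr = RRSeries(beat_time_s=np.cumsum(rr_ms) / 1000, rr_ms=rr_ms)
        assert len(compute_ani_series(rr)) == 149 - 63

    def test_deterministic(self, clean_cohort):
        p = clean_cohort.patients[0]
        s1 = compute_ani_series(p.rr)
        s2 = compute_ani_series(p.rr)
        np.testing.assert_array_equal(s1.ani, s2.ani)

    def test_attenuated_modulation_lowers_ani(self):
        # same RR composition, HF amplitude halved: ANI must drop
        rng = np.random.default_rng(4)
        t = np.arange(2048) / 8.0
        drift = 20 * np.sin(2 * np.pi * 0.04 * t)
        for amp_full, amp_half in [(30.0, 15.0)]:
            out = []
            for a in (amp_full, amp_half):
                vals = 800 + a * np.sin(2 * np.pi * 0.25 * t) + drift
                beats = []
                tt = 0.0
                while tt < 250.0:
                    rr = float(np.interp(tt, t, vals))
                    tt += rr / 1000.0
                    beats.append(rr)
                rr_arr = np.asarray(beats)
                series = RRSeries(beat_time_s=np.cumsum(rr_arr) / 1000, rr_ms=rr_arr)
                out.append(np.median(compute_ani_series(series).ani))
            assert out[1] < out[0]

    def test_pain_tracks_opposite_ani(self, clean_cohort):
        # end-to-end monotone coupling: latent pain vs (100 - ANI), rank
        # correlation over window-aligned 64-s pain means
        from scipy.stats import spearmanr

        for p in clean_cohort:
            s = compute_ani_series(p.rr)
            pain = p.pain.pain
            pm = np.array([pain[max(0, int(t) - 64) : int(t)].mean() for t in s.time_s])
            assert spearmanr(pm, s.opposite).statistic > 0.7

    def test_quality_flags_on_constant_rr(self):
        rr_ms = np.full(150, 800.0)
        rr = RRSeries(beat_time_s=np.cumsum(rr_ms) / 1000, rr_ms=rr_ms)
        s = compute_ani_series(rr)
        assert np.all(s.quality_flag > 0)
        assert np.all(s.ani == pytest.approx(9.375))
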