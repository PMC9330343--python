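"""RR-interval preprocessing: R-peak detection, adaptive artifact filtering, resampling.

The tachogram that feeds the nociception index must be clean and uniformly
sampled.  This module detects R peaks in an ECG waveform, removes ectopic /
missed-beat artifacts with an auto-adaptive moving-window threshold filter,
and resamples the irregular beat-to-beat series onto an 8-Hz grid by linear
interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

__all__ = [
    "EcgRecord",
    "RRSeries",
    "UniformRRSeries",
    "detect_r_peaks",
    "filter_rr",
    "resample_rr",
]


@dataclass(frozen=True)
class EcgRecord:
    """Single-lead ECG waveform with its sampling rate."""

    samples: np.ndarray
    fs_hz: float
    patient_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.samples.size == 0:
            raise ValueError("ECG record is empty")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz


@dataclass(frozen=True)
class RRSeries:
    """Beat-to-beat intervals (ms) stamped at the later beat of each pair.

    ``replaced_mask`` marks samples substituted by the artifact filter.
    """

    beat_time_s: np.ndarray
    rr_ms: np.ndarray
    replaced_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    patient_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.beat_time_s, dtype=float)
        rr = np.asarray(self.rr_ms, dtype=float)
        if t.shape != rr.shape or t.ndim != 1:
            raise ValueError("beat_time_s and rr_ms must be 1-d arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(rr <= 0):
            raise ValueError("RR intervals must be positive")
        mask = self.replaced_mask
        mask = np.zeros(rr.size, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
        if mask.shape != rr.shape:
            raise ValueError("replaced_mask length mismatch")
        object.__setattr__(self, "beat_time_s", t)
        object.__setattr__(self, "rr_ms", rr)
        object.__setattr__(self, "replaced_mask", mask)

    def __len__(self) -> int:
        return int(self.rr_ms.size)


@dataclass(frozen=True)
class UniformRRSeries:
    """RR series (ms) on an equidistant grid, default 8 Hz."""

    values: np.ndarray
    rate_hz: float = 8.0
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def time_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.values.size) / self.rate_hz

    def __len__(self) -> int:
        return int(self.values.size)


class PeakDetectionError(RuntimeError):
    """Raised when fewer than two R peaks can be located."""


def detect_r_peaks(ecg: EcgRecord, refractory_s: float = 0.25) -> RRSeries:
    """Detect R peaks and return the raw RR series.

    A Pan-Tompkins-style chain: band-pass (5-30 Hz), differentiate, square,
    moving-window integrate, then adaptive-threshold peak picking with a
    refractory period.  Each detected peak is refined to the local ECG
    maximum.  Interval ``i`` is stamped at the time of its *later* peak.
    """
    x = ecg.samples - np.mean(ecg.samples)
    fs = ecg.fs_hz
    nyq = fs / 2.0
    hi = min(30.0, 0.9 * nyq)
    sos = _signal.butter(2, [5.0 / nyq, hi / nyq], btype="band", output="sos")
    xf = _signal.sosfiltfilt(sos, x)
    energy = np.gradient(xf) ** 2
    win = max(1, int(round(0.15 * fs)))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")

    thresh = 0.2 * np.max(integ)
    if thresh <= 0 or not np.isfinite(thresh):
        raise PeakDetectionError("no QRS energy found (flat-line input?)")
    distance = max(1, int(round(refractory_s * fs)))
    locs, _ = _signal.find_peaks(integ, height=thresh, distance=distance)
    # refine each candidate to the nearby raw-ECG maximum
    half = max(1, int(round(0.05 * fs)))
    peaks = []
    for loc in locs:
        lo, hi_ix = max(0, loc - half), min(x.size, loc + half + 1)
        peaks.append(lo + int(np.argmax(x[lo:hi_ix])))
    peaks = np.unique(peaks)
    if peaks.size < 2:
        raise PeakDetectionError(f"only {peaks.size} R peak(s) detected; need at least 2")

    beat_t = peaks / fs
    rr_ms = np.diff(beat_t) * 1000.0
    return RRSeries(beat_time_s=beat_t[1:], rr_ms=rr_ms, patient_id=ecg.patient_id)


def filter_rr(rr: RRSeries) -> RRSeries:
    """Remove RR artifacts with auto-adaptive thresholds in a 5-sample moving window.

    Head rule: the first five samples outside [m - 2s, m + 2s] (m, s = mean and
    population SD of the whole series) are replaced by the whole-series mean.

    Body rule, for sample i from the sixth up to one before the last: replace
    RR[i] by the mean of its previous five samples when any of the following
    holds, where m5, s5 are the mean / population SD of those five samples:

    1. RR[i] < m5 - 2*s5  and  RR[i+1] > m5 + 2*s5
    2. RR[i] < 0.75*RR[i-1]  or  RR[i+1] < 0.75*RR[i-1]
    3. RR[i] > 1.25*RR[i-1]

    Tail rule: the last sample is replaced by the mean of its previous five
    when it falls below 0.75x or above 1.25x its predecessor.

    Replacements are applied sequentially in place, so a corrected value feeds
    the moving statistics of later samples (this stops a single artifact from
    cascading).  RR[i+1] is always read from the original series, since it has
    not been visited yet.
    """
    n = len(rr)
    if n < 6:
        raise ValueError(f"filter_rr needs at least 6 samples, got {n}")
    orig = rr.rr_ms.copy()
    out = rr.rr_ms.copy()
    mask = np.zeros(n, dtype=bool)

    m = float(np.mean(orig))
    sd = float(np.std(orig))  # population SD: threshold use, not inference
    head_bad = (orig[:5] < m - 2 * sd) | (orig[:5] > m + 2 * sd)
    out[:5][head_bad] = m
    mask[:5] = head_bad

    for i in range(5, n - 1):
        prev5 = out[i - 5 : i]
        m5 = float(np.mean(prev5))
        s5 = float(np.std(prev5))
        nxt = orig[i + 1]  # successor not yet visited: use original value
        cond1 = out[i] < m5 - 2 * s5 and nxt > m5 + 2 * s5
        cond2 = out[i] < 0.75 * out[i - 1] or nxt < 0.75 * out[i - 1]
        cond3 = out[i] > 1.25 * out[i - 1]
        if cond1 or cond2 or cond3:
            out[i] = m5
            mask[i] = True

    last = n - 1
    if out[last] < 0.75 * out[last - 1] or out[last] > 1.25 * out[last - 1]:
        out[last] = float(np.mean(out[last - 5 : last]))
        mask[last] = True

    return RRSeries(beat_time_s=rr.beat_time_s, rr_ms=out, replaced_mask=mask, patient_id=rr.patient_id)


def resample_rr(rr: RRSeries, rate_hz: float = 8.0) -> UniformRRSeries:
    """Resample the irregular RR series to a uniform grid by linear interpolation.

    The grid spans [first, last] beat time; no extrapolation beyond the
    endpoints.
    """
    if len(rr) < 2:
        raise ValueError("resampling needs at least 2 beats")
    t0, t1 = float(rr.beat_time_s[0]), float(rr.beat_time_s[-1])
    n_grid = int(np.floor((t1 - t0) * rate_hz)) + 1
    grid = t0 + np.arange(n_grid) / rate_hz
    vals = np.interp(grid, rr.beat_time_s, rr.rr_ms)
    return UniformRRSeries(values=vals, rate_hz=rate_hz, start_time_s=t0)
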