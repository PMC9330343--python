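"""Synthetic surgical cohorts for exercising the ANI -> pain-score pipeline.

Real intraoperative recordings (ECG at 512 Hz plus five clinicians' 1-Hz
pain-score curves) are rarely shareable, so this module generates cohorts
with the statistical structure the analysis assumes:

* a latent per-second pain trajectory (0-100) with an induction/intubation
  spike at the start and smooth logistic pain events;
* an RR-interval point process whose respiratory (high-frequency) modulation
  amplitude shrinks as pain rises — the vagally mediated mechanism the ANI
  quantifies — plus low-frequency drift, white noise, and sporadic
  ectopic/missed-beat artifacts;
* five rater score curves equal to the latent pain plus per-rater bias and
  slowly varying AR(1) noise (hand-drawn curves are smooth, not white), with
  one rater strongly low-biased by default;
* optionally, a synthetic ECG waveform with one QRS-like template per beat.

Everything is deterministic given the config seed: per-patient generators
draw from `numpy.random.SeedSequence(seed).spawn(...)` children.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from anihrv.preprocess import EcgRecord, RRSeries

__all__ = [
    "PainTrajectory",
    "SynthConfig",
    "SynthPatient",
    "SynthCohort",
    "SyntheticEcg",
    "gen_pain_trajectory",
    "gen_rr_from_pain",
    "gen_rater_scores",
    "gen_ecg_from_rr",
    "gen_cohort",
    "write_cohort",
]

_MIN_DURATION_S = 128.0


@dataclass(frozen=True)
class PainTrajectory:
    """Latent per-second pain score (0-100) on a 1-Hz grid."""

    time_s: np.ndarray
    pain: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        p = np.asarray(self.pain, dtype=float)
        if t.shape != p.shape:
            raise ValueError("time and pain grids differ in length")
        if np.any(p < 0) or np.any(p > 100):
            raise ValueError("pain values must lie in [0, 100]")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "pain", p)

    def __len__(self) -> int:
        return int(self.pain.size)


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-generation parameters.

    Defaults encode a plausible adult under general anesthesia: resting mean
    RR 800 ms (75 bpm), ventilator-paced respiration at 0.25 Hz, respiratory
    sinus arrhythmia of up to 40 ms peak amplitude that vanishes at maximal
    pain, ~1 ms of mean-RR shortening per pain point, and one rater biased
    10 points low.
    """

    n_patients: int = 8
    duration_s: float = 900.0
    base_rr_ms: float = 800.0
    rsa_freq_hz: float = 0.25
    rsa_amp_max_ms: float = 40.0
    pain_rr_slope: float = 1.0
    artifact_rate: float = 0.005
    rater_biases: tuple = (0.0, 0.0, 0.0, -10.0, 0.0)
    rater_noise_sd: float = 3.0
    n_pain_events: int = 3
    lf_drift_amp_ms: float = 25.0
    rr_noise_sd_ms: float = 3.0
    include_ecg: bool = False
    ecg_fs_hz: float = 512.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.duration_s < _MIN_DURATION_S:
            raise ValueError(f"duration_s must be >= {_MIN_DURATION_S}")
        if not (0.15 <= self.rsa_freq_hz <= 0.5):
            raise ValueError("rsa_freq_hz must lie within [0.15, 0.5] (the HF band)")
        if len(self.rater_biases) < 2:
            raise ValueError("need at least 2 raters")


@dataclass(frozen=True)
class SyntheticEcg:
    """Synthetic ECG waveform plus the ground-truth beat times that produced it."""

    record: EcgRecord
    true_beat_time_s: np.ndarray


@dataclass(frozen=True)
class SynthPatient:
    patient_id: str
    pain: PainTrajectory
    rr: RRSeries
    raters: "RaterScores"  # noqa: F821 - imported lazily to avoid a cycle
    ecg: SyntheticEcg | None = None
    artifact_beats: tuple = ()


@dataclass(frozen=True)
class SynthCohort:
    patients: tuple
    config: SynthConfig

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def patient(self, pid: str) -> SynthPatient:
        for p in self.patients:
            if p.patient_id == pid:
                return p
        raise KeyError(pid)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def gen_pain_trajectory(
    duration_s: float,
    n_events: int = 3,
    seed: int | np.random.SeedSequence = 0,
    include_spike: bool = True,
) -> PainTrajectory:
    """Latent pain curve: baseline + induction spike + smooth event bumps.

    Baseline is drawn from 15-25.  The initial spike (intubation analog) is an
    exponential-decay bump of amplitude ~60 with a ~60-s time constant.  Each
    of the ``n_events`` pain events is a smooth logistic plateau bump
    (amplitude 15-40, half-width 20-45 s, 8-s shoulders); event centers are
    jittered within equal slots of the post-spike span so bumps never merge.
    """
    if duration_s < _MIN_DURATION_S:
        raise ValueError(f"duration_s must be >= {_MIN_DURATION_S}")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s)), dtype=float)
    baseline = rng.uniform(15.0, 25.0)
    pain = np.full_like(t, baseline)
    if include_spike:
        pain += 60.0 * np.exp(-t / 60.0)
    span_start = 150.0  # spike has decayed below ~5 points by here
    if n_events > 0 and duration_s > span_start + 60.0:
        slot = (duration_s - span_start - 30.0) / n_events
        for k in range(n_events):
            center = span_start + slot * (k + 0.5) + rng.uniform(-0.15, 0.15) * slot
            amp = rng.uniform(15.0, 40.0)
            w_lo = min(20.0, slot / 5.0)
            half_w = rng.uniform(w_lo, max(w_lo + 1.0, min(45.0, slot / 2.5)))
            pain += amp * _logistic((t - (center - half_w)) / 8.0) * _logistic(((center + half_w) - t) / 8.0)
    return PainTrajectory(time_s=t, pain=np.clip(pain, 0.0, 100.0))


def gen_rr_from_pain(
    pain: PainTrajectory,
    cfg: SynthConfig,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[RRSeries, tuple]:
    """Beat point process from the latent pain curve.

    Instantaneous RR(t) = base - slope*pain(t)
                          + A(t) * sin(2*pi*f_resp*t + phi)
                          + low-frequency drift + white noise,
    with respiratory amplitude A(t) = rsa_amp_max * (1 - pain(t)/100): high
    pain suppresses vagal (HF) modulation.  Beats are integrated first-order:
    the next beat falls RR(t)/1000 seconds after the current one.

    Artifacts are injected per-interval at ``cfg.artifact_rate``: an ectopic
    event replaces one interval RR by the pair (0.4*RR, 1.6*RR) — premature
    beat plus compensatory pause — and a missed-beat event merges two adjacent
    intervals.  Returns the series and the injected-artifact provenance
    (list of (interval_index, kind)).
    """
    p = np.asarray(pain.pain, dtype=float)
    if np.any(p < 0) or np.any(p > 100):
        raise ValueError("pain values must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    duration = float(pain.time_s[-1]) + 1.0

    phi = rng.uniform(0.0, 2.0 * np.pi)
    # LF drift: one constant-envelope Mayer-wave-like tone (0.03-0.06 Hz,
    # random per-patient frequency and phase).  A single tone keeps the
    # 64-s windowed drift power near-constant, so it acts as a stable
    # competitor in the window norm, and it sits well below the 0.125-Hz
    # edge of the HF wavelet band.
    lf_freq = rng.uniform(0.03, 0.06)
    lf_phi = rng.uniform(0.0, 2.0 * np.pi)

    def rr_inst(t: float) -> float:
        pv = float(np.interp(t, pain.time_s, p))
        amp = cfg.rsa_amp_max_ms * (1.0 - pv / 100.0)
        drift = cfg.lf_drift_amp_ms * np.sin(2.0 * np.pi * lf_freq * t + lf_phi)
        rr = cfg.base_rr_ms - cfg.pain_rr_slope * pv + amp * np.sin(2.0 * np.pi * cfg.rsa_freq_hz * t + phi) + drift
        if cfg.rr_noise_sd_ms > 0:
            rr += rng.normal(0.0, cfg.rr_noise_sd_ms)
        return max(rr, 200.0)  # physiological floor

    t = 0.0
    intervals: list[float] = []
    while True:
        rr = rr_inst(t)
        t_next = t + rr / 1000.0
        if t_next > duration:
            break
        intervals.append(rr)
        t = t_next

    # artifact injection on the interval list
    arts: list[tuple[int, str]] = []
    if cfg.artifact_rate > 0:
        out: list[float] = []
        i = 0
        while i < len(intervals):
            if rng.random() < cfg.artifact_rate:
                if rng.random() < 0.5 or i == len(intervals) - 1:
                    arts.append((i, "ectopic"))
                    out.extend([0.4 * intervals[i], 1.6 * intervals[i]])
                    i += 1
                else:
                    arts.append((i, "missed"))
                    out.append(intervals[i] + intervals[i + 1])
                    i += 2
            else:
                out.append(intervals[i])
                i += 1
        intervals = out

    rr_ms = np.asarray(intervals, dtype=float)
    beat_t = np.cumsum(rr_ms) / 1000.0  # first beat at t=0; stamps at the later beat
    return RRSeries(beat_time_s=beat_t, rr_ms=rr_ms), tuple(arts)


def gen_rater_scores(
    pain: PainTrajectory,
    cfg: SynthConfig,
    seed: int | np.random.SeedSequence = 0,
) -> "RaterScores":
    """Per-second rater curves: pain + per-rater bias + smooth AR(1) noise.

    The AR(1) coefficient is 0.99 at 1 Hz (hand-drawn score curves wander
    slowly); the white-noise driving SD is scaled so the stationary SD equals
    ``cfg.rater_noise_sd``.  Scores are clipped to [0, 100].
    """
    from anihrv.labels import RaterScores  # local import: labels also imports nothing from here

    if len(cfg.rater_biases) < 2:
        raise ValueError("need at least 2 raters")
    rng = np.random.default_rng(seed)
    n = len(pain)
    n_raters = len(cfg.rater_biases)
    rho = 0.99
    scores = np.empty((n, n_raters), dtype=float)
    for k, bias in enumerate(cfg.rater_biases):
        if cfg.rater_noise_sd > 0:
            w = rng.normal(0.0, cfg.rater_noise_sd * np.sqrt(1.0 - rho**2), size=n)
            e = np.empty(n)
            e[0] = rng.normal(0.0, cfg.rater_noise_sd)
            for i in range(1, n):
                e[i] = rho * e[i - 1] + w[i]
        else:
            e = np.zeros(n)
        scores[:, k] = np.clip(pain.pain + bias + e, 0.0, 100.0)
    ids = tuple(chr(ord("A") + k) for k in range(n_raters))
    return RaterScores(time_s=pain.time_s.copy(), scores=scores, rater_ids=ids)


def gen_ecg_from_rr(
    rr: RRSeries,
    fs_hz: float = 512.0,
    seed: int | np.random.SeedSequence = 0,
    noise_sd: float = 0.0,
    baseline_wander_amp: float = 0.0,
) -> SyntheticEcg:
    """Synthetic ECG: one QRS-like template per beat time.

    The template is a biphasic wavelet (narrow positive R lobe flanked by
    small negative Q/S lobes).  Ground-truth beat times (including the beat
    that opens the first interval) are returned for detector validation.
    """
    if fs_hz < 128:
        raise ValueError("fs_hz must be >= 128 to resolve the QRS complex")
    if len(rr) == 0:
        raise ValueError("empty RR series")
    rng = np.random.default_rng(seed)
    first_beat = float(rr.beat_time_s[0]) - float(rr.rr_ms[0]) / 1000.0
    beat_times = np.concatenate([[first_beat], rr.beat_time_s])
    beat_times = beat_times[beat_times >= 0]

    n = int(np.ceil((beat_times[-1] + 0.5) * fs_hz))
    x = np.zeros(n)
    # QRS template: gaussian R wave (sigma 10 ms) minus wider negative lobe
    half = int(round(0.08 * fs_hz))
    tt = (np.arange(-half, half + 1)) / fs_hz
    template = np.exp(-0.5 * (tt / 0.010) ** 2) - 0.25 * np.exp(-0.5 * (tt / 0.030) ** 2)
    for bt in beat_times:
        c = int(round(bt * fs_hz))
        lo, hi = c - half, c + half + 1
        tlo, thi = max(0, -lo), len(template) - max(0, hi - n)
        x[max(0, lo) : min(n, hi)] += template[tlo:thi]
    if baseline_wander_amp > 0:
        tgrid = np.arange(n) / fs_hz
        x += baseline_wander_amp * np.sin(2.0 * np.pi * 0.3 * tgrid + rng.uniform(0, 2 * np.pi))
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=n)
    return SyntheticEcg(record=EcgRecord(samples=x, fs_hz=fs_hz), true_beat_time_s=beat_times)


def gen_cohort(cfg: SynthConfig) -> SynthCohort:
    """Generate ``cfg.n_patients`` independent patients, deterministically.

    Patient k draws from the k-th child of ``SeedSequence(cfg.seed)``, so the
    cohort is reproducible byte-for-byte and individual patients are
    independent streams.
    """
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_patients)
    patients = []
    for k, child in enumerate(children):
        pid = f"P{k + 1:03d}"
        sub = child.spawn(4)
        pain = gen_pain_trajectory(cfg.duration_s, cfg.n_pain_events, seed=sub[0])
        rr, arts = gen_rr_from_pain(pain, cfg, seed=sub[1])
        rr = RRSeries(beat_time_s=rr.beat_time_s, rr_ms=rr.rr_ms, patient_id=pid)
        raters = gen_rater_scores(pain, cfg, seed=sub[2])
        ecg = gen_ecg_from_rr(rr, cfg.ecg_fs_hz, seed=sub[3]) if cfg.include_ecg else None
        patients.append(
            SynthPatient(patient_id=pid, pain=pain, rr=rr, raters=raters, ecg=ecg, artifact_beats=arts)
        )
    return SynthCohort(patients=tuple(patients), config=cfg)


def write_cohort(cohort: SynthCohort, outdir: str | Path) -> Path:
    """Write per-patient CSVs (`rr_<id>.csv`, `eaps_<id>.csv`, optional
    `ecg_<id>.csv`) and a JSON manifest carrying the config and seed."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for p in cohort:
        pd.DataFrame({"beat_time_s": p.rr.beat_time_s, "rr_ms": p.rr.rr_ms}).to_csv(
            outdir / f"rr_{p.patient_id}.csv", index=False
        )
        eaps = pd.DataFrame({"time_s": p.raters.time_s})
        for j, rid in enumerate(p.raters.rater_ids):
            eaps[f"rater_{rid}"] = p.raters.scores[:, j]
        eaps.to_csv(outdir / f"eaps_{p.patient_id}.csv", index=False)
        if p.ecg is not None:
            pd.DataFrame(
                {
                    "time_s": np.arange(p.ecg.record.samples.size) / p.ecg.record.fs_hz,
                    "amplitude": p.ecg.record.samples,
                }
            ).to_csv(outdir / f"ecg_{p.patient_id}.csv", index=False)
    manifest = {
        "config": dataclasses.asdict(cohort.config),
        "patients": [p.patient_id for p in cohort],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
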