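"""Plain-CSV readers and writers for the pipeline's file interfaces."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from anihrv.ani import AniSeries
from anihrv.labels import LabelSeries, RaterScores
from anihrv.preprocess import EcgRecord, RRSeries

__all__ = [
    "read_rr_csv",
    "write_rr_csv",
    "read_ecg_csv",
    "read_eaps_csv",
    "write_ani_csv",
    "read_ani_csv",
    "write_consensus_csv",
]


def read_rr_csv(path: str | Path, patient_id: str = "") -> RRSeries:
    df = pd.read_csv(path)
    mask = df["replaced"].to_numpy(dtype=bool) if "replaced" in df.columns else None
    return RRSeries(
        beat_time_s=df["beat_time_s"].to_numpy(float),
        rr_ms=df["rr_ms"].to_numpy(float),
        replaced_mask=mask,
        patient_id=patient_id,
    )


def write_rr_csv(rr: RRSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"beat_time_s": rr.beat_time_s, "rr_ms": rr.rr_ms, "replaced": rr.replaced_mask.astype(int)}
    ).to_csv(path, index=False)


def read_ecg_csv(path: str | Path, fs_hz: float | None = None, patient_id: str = "") -> EcgRecord:
    df = pd.read_csv(path)
    if fs_hz is None:
        t = df["time_s"].to_numpy(float)
        fs_hz = 1.0 / float(np.median(np.diff(t)))
    return EcgRecord(samples=df["amplitude"].to_numpy(float), fs_hz=fs_hz, patient_id=patient_id)


def read_eaps_csv(path: str | Path) -> RaterScores:
    df = pd.read_csv(path)
    rater_cols = [c for c in df.columns if c != "time_s"]
    ids = tuple(c.removeprefix("rater_") for c in rater_cols)
    return RaterScores(time_s=df["time_s"].to_numpy(float), scores=df[rater_cols].to_numpy(float), rater_ids=ids)


def write_ani_csv(s: AniSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": s.time_s, "ani": s.ani, "opposite": s.opposite, "quality_flag": s.quality_flag}
    ).to_csv(path, index=False)


def read_ani_csv(path: str | Path) -> AniSeries:
    df = pd.read_csv(path)
    return AniSeries(
        time_s=df["time_s"].to_numpy(float),
        ani=df["ani"].to_numpy(float),
        quality_flag=df["quality_flag"].to_numpy(int),
    )


def write_consensus_csv(lab: LabelSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": lab.time_s, "eaps": lab.eaps}).to_csv(path, index=False)
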