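"""File formats: BIDS-style events TSV, ratings CSV, calibration text, NIfTI.

One events TSV per block (columns: onset, duration, trial_type,
picture_id, rewarded, probe_delay, probe_duration and, for behavioural
logs, response_time, rt_ms, classification, payout, feedback; onsets and
durations in seconds), one ratings CSV per subject (subject, block,
cue_type, rating_mm), a two-column key/value calibration file, and a JSON
sidecar carrying subject metadata so a full :class:`SubjectLog` can be
round-tripped.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .task import (
    CalibrationProfile,
    CueStimulus,
    TaskVersion,
    TrialResult,
    TrialSchedule,
    TrialSpec,
)
from .agents import SubjectLog

__all__ = [
    "write_calibration",
    "read_calibration",
    "write_schedule",
    "write_subject",
    "read_subject",
    "read_events_tsv",
    "subject_from_frames",
    "save_map",
]


def write_calibration(calibration: CalibrationProfile, path) -> None:
    Path(path).write_text(
        f"mean_rt_ms\t{calibration.mean_rt_ms:.6g}\nsdf_ms\t{calibration.sdf_ms:.6g}\n"
    )


def read_calibration(path) -> CalibrationProfile:
    values = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            key, val = line.split()
            values[key] = float(val)
    return CalibrationProfile(mean_rt_ms=values["mean_rt_ms"], sdf_ms=values["sdf_ms"])


def _schedule_frame(schedule: TrialSchedule, block: int) -> pd.DataFrame:
    rows = []
    for t in schedule.blocks[block - 1]:
        rows.append(
            {
                "onset": t.cue_onset_s,
                "duration": t.probe_delay_s,
                "trial_type": t.cue.cue_type,
                "picture_id": t.cue.picture_id,
                "rewarded": int(t.rewarded),
                "probe_delay": t.probe_delay_s,
                "probe_duration": t.probe_duration_ms / 1000.0,
            }
        )
    return pd.DataFrame(rows)


def write_schedule(schedule: TrialSchedule, outdir, prefix: str = "schedule") -> list[Path]:
    """One BIDS-style events TSV per block."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for b in range(1, schedule.n_blocks + 1):
        p = outdir / f"{prefix}_block-{b}_events.tsv"
        _schedule_frame(schedule, b).to_csv(p, sep="\t", index=False, na_rep="n/a")
        paths.append(p)
    return paths


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])


def write_subject(log: SubjectLog, outdir) -> dict:
    """Write a subject's events TSVs, ratings CSV and JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = log.subject_id
    event_paths = []
    for b in range(1, log.schedule.n_blocks + 1):
        p = outdir / f"{sid}_block-{b}_events.tsv"
        log.events_frame(b).to_csv(p, sep="\t", index=False, na_rep="n/a")
        event_paths.append(str(p))
    ratings_path = outdir / f"{sid}_ratings.csv"
    log.ratings_frame().to_csv(ratings_path, index=False)
    sidecar = {
        "subject_id": sid,
        "high_feature": log.version.high_feature,
        "mean_rt_ms": log.calibration.mean_rt_ms,
        "sdf_ms": log.calibration.sdf_ms,
        "aberrant_offset": log.aberrant_offset,
        "seed": log.seed,
        "schedule_seed": log.schedule.seed,
    }
    sidecar_path = outdir / f"{sid}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    return {"events": event_paths, "ratings": str(ratings_path), "sidecar": str(sidecar_path)}


def subject_from_frames(
    subject_id: str,
    version: TaskVersion,
    events_frames: Sequence[pd.DataFrame],
    ratings: pd.DataFrame,
    calibration: Optional[CalibrationProfile] = None,
    aberrant_offset: float = 0.0,
    seed: Optional[int] = None,
    schedule_seed: int = 0,
) -> SubjectLog:
    """Rebuild a :class:`SubjectLog` from events tables plus a ratings table."""
    if calibration is None:
        calibration = CalibrationProfile(mean_rt_ms=300.0, sdf_ms=20.0)
    blocks, results = [], []
    for b, ev in enumerate(events_frames, start=1):
        trials, block_results = [], []
        for i, row in enumerate(ev.itertuples(index=False), start=1):
            color, shape = row.trial_type.split("_")
            pic = int(getattr(row, "picture_id", 1))
            trials.append(
                TrialSpec(
                    block=b,
                    index_in_block=i,
                    cue=CueStimulus(color, shape, pic),
                    rewarded=bool(row.rewarded),
                    probe_delay_s=float(row.probe_delay),
                    probe_duration_ms=float(row.probe_duration) * 1000.0,
                    onset_s=float(row.onset) - 1.0,
                )
            )
            rt = getattr(row, "rt_ms", None)
            rt = None if rt is None or (isinstance(rt, float) and np.isnan(rt)) else float(rt)
            block_results.append(
                TrialResult(
                    rt_ms=rt,
                    classification=str(getattr(row, "classification", "valid")),
                    payout_pence=int(getattr(row, "payout", 0)),
                    feedback=str(getattr(row, "feedback", "NoMoney")),
                )
            )
        blocks.append(trials)
        results.append(block_results)
    schedule = TrialSchedule(version=version, blocks=blocks, seed=schedule_seed)
    vas = {
        (int(r.block), str(r.cue_type)): float(r.rating_mm)
        for r in ratings.itertuples(index=False)
    }
    return SubjectLog(
        subject_id=subject_id,
        version=version,
        calibration=calibration,
        schedule=schedule,
        trial_results=results,
        vas_ratings=vas,
        aberrant_offset=aberrant_offset,
        seed=seed,
    )


def read_subject(outdir, subject_id: str) -> SubjectLog:
    """Round-trip a subject written by :func:`write_subject`."""
    outdir = Path(outdir)
    meta = json.loads((outdir / f"{subject_id}.json").read_text())
    version = TaskVersion.from_high_feature(meta["high_feature"])
    calibration = CalibrationProfile(meta["mean_rt_ms"], meta["sdf_ms"])
    events = []
    b = 1
    while (outdir / f"{subject_id}_block-{b}_events.tsv").exists():
        events.append(read_events_tsv(outdir / f"{subject_id}_block-{b}_events.tsv"))
        b += 1
    if not events:
        raise FileNotFoundError(f"no events TSVs for {subject_id} in {outdir}")
    ratings = pd.read_csv(outdir / f"{subject_id}_ratings.csv")
    return subject_from_frames(
        subject_id,
        version,
        events,
        ratings,
        calibration=calibration,
        aberrant_offset=meta.get("aberrant_offset", 0.0),
        seed=meta.get("seed"),
        schedule_seed=meta.get("schedule_seed", 0),
    )


def save_map(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a 3D statistic map as NIfTI."""
    nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine).to_filename(str(path))
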