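"""Tab-separated on-disk formats for raw recordings, events and result tables.

Sample logs mirror an Eyelink-style sample stream: one file per participant,
columns ``trial_id, t_ms, pupil_mm, gaze_x_deg, gaze_y_deg``, integer
milliseconds in 2 ms steps, the literal ``NA`` for missing samples, values
written to 4 decimals (round-trip is lossless at 1e-4). Event files carry
the stimulus and report timelines: ``trial_id, event_type, t_ms, payload``
where ``event_type`` is one of trial_start, trial_end, ramp_onset,
ramp_end, keypress. Times are integer ms on disk and seconds in memory.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .config import RunConfig
from .synth import Cohort, Recording, StimulusTimeline

__all__ = [
    "write_sample_log", "read_sample_log", "write_event_file",
    "read_event_file", "write_cohort", "read_cohort",
    "write_manifest", "FormatError",
]

SAMPLE_COLUMNS = ["trial_id", "t_ms", "pupil_mm", "gaze_x_deg", "gaze_y_deg"]
EVENT_COLUMNS = ["trial_id", "event_type", "t_ms", "payload"]
EVENT_TYPES = {"trial_start", "trial_end", "ramp_onset", "ramp_end", "keypress"}


class FormatError(ValueError):
    """Malformed or inconsistent on-disk data."""


def _fmt(v: float) -> str:
    return "NA" if not np.isfinite(v) else f"{v:.4f}"


def write_sample_log(rec: Recording, path) -> None:
    """Write one participant's raw samples as a TSV sample log."""
    step_ms = 1000.0 / rec.sample_rate
    n_s = rec.pupil.shape[1]
    t_ms = np.rint(np.arange(n_s) * step_ms).astype(int)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SAMPLE_COLUMNS) + "\n")
        for i in range(rec.n_trials):
            p, gx, gy = rec.pupil[i], rec.gaze_x[i], rec.gaze_y[i]
            for k in range(n_s):
                fh.write(f"{i}\t{t_ms[k]}\t{_fmt(p[k])}\t{_fmt(gx[k])}\t{_fmt(gy[k])}\n")


def read_sample_log(path) -> Dict[int, Dict[str, np.ndarray]]:
    """Read a sample log into per-trial arrays keyed by trial id.

    Each trial maps to ``{"t": s, "pupil": mm, "gaze_x": deg, "gaze_y": deg}``
    with NaN for NA cells. Raises FormatError (with the offending line
    number where applicable) on malformed rows or non-monotone timestamps.
    """
    try:
        df = pd.read_csv(path, sep="\t", na_values="NA",
                         dtype={"trial_id": int, "t_ms": int})
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: malformed sample log: {exc}") from exc
    if list(df.columns) != SAMPLE_COLUMNS:
        raise FormatError(f"{path}: expected columns {SAMPLE_COLUMNS}")
    for col in SAMPLE_COLUMNS[2:]:
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna() & df[col].notna()
        if bad.any():
            raise FormatError(f"{path}: non-numeric cell in column {col} "
                              f"at line {int(bad.idxmax()) + 2}")
        df[col] = num
    out: Dict[int, Dict[str, np.ndarray]] = {}
    for tid, g in df.groupby("trial_id", sort=True):
        t_ms = g["t_ms"].to_numpy()
        if np.any(np.diff(t_ms) <= 0):
            k = int(np.flatnonzero(np.diff(t_ms) <= 0)[0])
            raise FormatError(f"{path}: non-monotone t_ms in trial {tid} "
                              f"near line {g.index[k] + 2}")
        out[int(tid)] = {
            "t": t_ms / 1000.0,
            "pupil": g["pupil_mm"].to_numpy(dtype=float),
            "gaze_x": g["gaze_x_deg"].to_numpy(dtype=float),
            "gaze_y": g["gaze_y_deg"].to_numpy(dtype=float),
        }
    return out


def write_event_file(rec: Recording, path) -> None:
    """Write stimulus and keypress events for one participant."""
    rows: List[Tuple[int, str, int, str]] = []
    for i, tl in enumerate(rec.timelines):
        rows.append((i, "trial_start", 0,
                     f"{tl.black_direction},{tl.initial_foreground}"))
        for onset, end, color in tl.swap_events:
            rows.append((i, "ramp_onset", int(round(onset * 1000)), color))
            rows.append((i, "ramp_end", int(round(end * 1000)), color))
        if rec.reports:
            for t0, key in rec.reports[i]:
                rows.append((i, "keypress", int(round(t0 * 1000)), key))
        rows.append((i, "trial_end", int(round(tl.trial_duration * 1000)), ""))
    rows.sort(key=lambda r: (r[0], r[2], r[1] != "trial_start"))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(EVENT_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(str(v) for v in r) + "\n")


def read_event_file(path, trial_duration: float = 60.0,
                    ramp_duration: float = 1.2,
                    disparity_amp: float = 15.0):
    """Reconstruct timelines and report events from an event file.

    Returns ``(timelines, reports)`` with one entry per trial. Validates
    event vocabulary, ramp pairing and trial_start precedence.
    """
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"trial_id": int, "t_ms": int, "payload": str})
    if list(df.columns) != EVENT_COLUMNS:
        raise FormatError(f"{path}: expected columns {EVENT_COLUMNS}")
    unknown = set(df["event_type"]) - EVENT_TYPES
    if unknown:
        raise FormatError(f"{path}: unknown event types {sorted(unknown)}")
    timelines: List[StimulusTimeline] = []
    reports: List[List[Tuple[float, str]]] = []
    for tid, g in df.groupby("trial_id", sort=True):
        starts = g[g.event_type == "trial_start"]
        if len(starts) != 1 or g["t_ms"].iloc[0] != 0 \
                or g["event_type"].iloc[0] != "trial_start":
            raise FormatError(f"{path}: trial {tid} must open with one trial_start")
        direction, initial = starts["payload"].iloc[0].split(",")
        onsets = g[g.event_type == "ramp_onset"]["t_ms"].to_numpy() / 1000.0
        ends = g[g.event_type == "ramp_end"]["t_ms"].to_numpy() / 1000.0
        if len(onsets) != len(ends) or np.any(ends - onsets <= 0):
            raise FormatError(f"{path}: trial {tid}: ramp events do not pair")
        timelines.append(StimulusTimeline(
            trial_id=int(tid), black_direction=direction,
            ramp_onsets=np.sort(onsets), ramp_duration=ramp_duration,
            trial_duration=trial_duration, disparity_amp=disparity_amp,
            initial_foreground=initial))
        kp = g[g.event_type == "keypress"]
        reports.append([(row.t_ms / 1000.0, row.payload)
                        for row in kp.itertuples()])
    return timelines, reports


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write the full cohort: participant table + per-participant logs/events."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.participants.to_csv(out / "participants.tsv", sep="\t", index=False)
    for rec in cohort.recordings:
        write_sample_log(rec, out / f"samples_{rec.participant}.tsv")
        write_event_file(rec, out / f"events_{rec.participant}.tsv")


def read_cohort(in_dir, run: RunConfig) -> Cohort:
    """Load a cohort written by :func:`write_cohort` back into memory."""
    in_dir = Path(in_dir)
    table = pd.read_csv(in_dir / "participants.tsv", sep="\t")
    stim = run.stimulus
    recordings = []
    for row in table.itertuples():
        pid = row.participant
        trials = read_sample_log(in_dir / f"samples_{pid}.tsv")
        tls, reports = read_event_file(
            in_dir / f"events_{pid}.tsv", stim.trial_duration,
            stim.ramp_duration, stim.disparity_amp)
        n_tr = len(tls)
        n_s = len(trials[0]["pupil"])
        pupil = np.stack([trials[i]["pupil"] for i in range(n_tr)])
        gx = np.stack([trials[i]["gaze_x"] for i in range(n_tr)])
        gy = np.stack([trials[i]["gaze_y"] for i in range(n_tr)])
        recordings.append(Recording(
            participant=str(pid), mode=str(row.mode), timelines=tls,
            pupil=pupil, gaze_x=gx, gaze_y=gy, reports=reports,
            sample_rate=stim.sample_rate, aq=int(row.aq)))
    mode = str(table["mode"].iloc[0]) if len(table) else "report"
    return Cohort(recordings=recordings, participants=table, mode=mode)


def write_manifest(out_dir, run: RunConfig, seed: int, stage: str) -> None:
    """Record the config hash and seed alongside a stage's outputs."""
    flat = run.to_flat_dict()
    digest = hashlib.sha256(
        json.dumps(flat, sort_keys=True, default=str).encode()).hexdigest()
    with open(Path(out_dir) / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump({"stage": stage, "seed": seed, "config_sha256": digest},
                  fh, indent=2)
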