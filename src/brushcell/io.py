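"""Readers and writers for the package's plain-text tabular dialects.

Three CSV dialects (all times in seconds, decimal text):

* **Spike table** — header ``cell_id,protocol_id,condition,trial,spike_time_s``;
  one row per spike. A row with an empty ``spike_time_s`` declares a trial
  with no spikes. ``condition`` is a ``+``-joined drug-token list
  (``LY``, ``NBQX``, ``JNJ``, ``CPP``) or ``baseline``.
* **Stimulus table** — header ``protocol_id,stimulus_time_s``; annotations in
  a sidecar ``<name>.annotations.csv`` with header
  ``protocol_id,kind,t0_s,t1_s,nominal_rate``.
* **Metrics table** — one row per (cell, condition, protocol, scope) with a
  deterministic column order; missing values are written as empty fields.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    Annotation,
    CellRecording,
    SpikeTrain,
    StimulusPattern,
    ValidationError,
    blocked_to_condition,
    condition_to_blocked,
)

__all__ = [
    "read_recording",
    "read_recordings",
    "write_recording",
    "read_stimulus_pattern",
    "write_stimulus_pattern",
    "write_metrics_table",
    "read_metrics_table",
]

SPIKE_COLUMNS = ["cell_id", "protocol_id", "condition", "trial", "spike_time_s"]
STIMULUS_COLUMNS = ["protocol_id", "stimulus_time_s"]
ANNOTATION_COLUMNS = ["protocol_id", "kind", "t0_s", "t1_s", "nominal_rate"]

#: Preferred metrics-table column order; unknown columns follow alphabetically.
METRICS_COLUMN_ORDER = [
    "cell_id",
    "protocol_id",
    "condition",
    "scope",
    "c",
    "n_stimuli",
    "baseline_rate",
    "peak_rate",
    "peak_change",
    "half_width",
    "pause_duration",
    "evoked_spikes",
    "response_start",
    "step_rate",
    "spikes_during",
    "spikes_after",
    "amplitude",
    "mu",
    "sigma",
    "time_to_peak",
    "half_decay",
    "fit_ok",
    "order_index",
]


def _read_csv(path, columns: Sequence[str], dtypes: Mapping[str, type]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path}: malformed CSV ({exc})") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    out = {}
    for col, typ in dtypes.items():
        if col not in df.columns:
            continue
        raw = df[col].str.strip()
        if typ is float or typ is int:
            vals = pd.to_numeric(raw.where(raw != "", other=np.nan),
                                 errors="coerce")
            bad = raw.ne("") & vals.isna()
            if bad.any():
                line = int(bad.idxmax()) + 2  # header is line 1
                raise ValidationError(
                    f"{path}: line {line}: cannot parse {col}={raw[bad.idxmax()]!r}"
                )
            out[col] = vals
        else:
            out[col] = raw
    for col in df.columns:
        out.setdefault(col, df[col])
    return pd.DataFrame(out)


def _annotations_path(path) -> str:
    base, ext = os.path.splitext(os.fspath(path))
    return base + ".annotations" + (ext or ".csv")


def read_stimulus_pattern(path) -> StimulusPattern:
    """Read a stimulus table (and its annotation sidecar if present)."""
    df = _read_csv(path, STIMULUS_COLUMNS, {"stimulus_time_s": float})
    protocol_ids = df["protocol_id"].unique()
    if len(protocol_ids) > 1:
        raise ValidationError(
            f"{path}: multiple protocol_ids {list(protocol_ids)}; one per file"
        )
    protocol_id = str(protocol_ids[0]) if len(protocol_ids) else ""
    times = df["stimulus_time_s"].to_numpy(dtype=float)
    annotations: list[Annotation] = []
    ann_path = _annotations_path(path)
    if os.path.exists(ann_path):
        adf = _read_csv(
            ann_path,
            ANNOTATION_COLUMNS,
            {"t0_s": float, "t1_s": float, "nominal_rate": float},
        )
        for _, row in adf.iterrows():
            rate = row["nominal_rate"]
            annotations.append(
                Annotation(
                    kind=str(row["kind"]),
                    t0=float(row["t0_s"]),
                    t1=float(row["t1_s"]),
                    nominal_rate=None if pd.isna(rate) else float(rate),
                )
            )
    return StimulusPattern(
        stimulus_times=times,
        annotations=tuple(annotations),
        protocol_id=protocol_id,
    )


def write_stimulus_pattern(pattern: StimulusPattern, path) -> None:
    """Write a stimulus table; annotations go to the sidecar file."""
    df = pd.DataFrame(
        {
            "protocol_id": [pattern.protocol_id] * pattern.stimulus_times.size,
            "stimulus_time_s": pattern.stimulus_times,
        }
    )
    df.to_csv(path, index=False)
    if pattern.annotations:
        adf = pd.DataFrame(
            {
                "protocol_id": [pattern.protocol_id] * len(pattern.annotations),
                "kind": [a.kind for a in pattern.annotations],
                "t0_s": [a.t0 for a in pattern.annotations],
                "t1_s": [a.t1 for a in pattern.annotations],
                "nominal_rate": [a.nominal_rate for a in pattern.annotations],
            }
        )
        adf.to_csv(_annotations_path(path), index=False)


def _default_t_stop(last_spike: float | None, pattern: StimulusPattern | None) -> float:
    candidates = []
    if last_spike is not None:
        candidates.append(last_spike + 1e-9)
    if pattern is not None and pattern.stimulus_times.size:
        candidates.append(pattern.t_last + 10.0)
    return max(candidates) if candidates else 1.0


def read_recordings(
    path,
    stimulus: StimulusPattern | Mapping[str, StimulusPattern] | None = None,
    t_start: float = 0.0,
    t_stop: float | None = None,
) -> list[CellRecording]:
    """Read a spike table that may contain several (cell, protocol,
    condition) groups; returns one :class:`CellRecording` per group.

    ``stimulus`` may be a single pattern (applied to every group) or a
    mapping from protocol_id. When ``t_stop`` is absent it defaults to the
    later of the last spike and the last stimulus + 10 s, per group.
    """
    df = _read_csv(path, SPIKE_COLUMNS, {"trial": int, "spike_time_s": float})
    bad_trial = df["trial"].isna()
    if bad_trial.any():
        line = int(bad_trial.idxmax()) + 2
        raise ValidationError(f"{path}: line {line}: missing trial id")
    recordings = []
    for (cell_id, protocol_id, condition), grp in df.groupby(
        ["cell_id", "protocol_id", "condition"], sort=True
    ):
        blocked = condition_to_blocked(str(condition))
        if isinstance(stimulus, Mapping):
            pattern = stimulus.get(str(protocol_id))
        else:
            pattern = stimulus
        if pattern is None:
            pattern = StimulusPattern(
                stimulus_times=np.array([]), protocol_id=str(protocol_id)
            )
        spikes_by_trial: dict[int, list[float]] = {}
        for _, row in grp.iterrows():
            tid = int(row["trial"])
            spikes_by_trial.setdefault(tid, [])
            if not pd.isna(row["spike_time_s"]):
                spikes_by_trial[tid].append(float(row["spike_time_s"]))
        last_spike = max(
            (s[-1] for s in spikes_by_trial.values() if s), default=None
        )
        stop = t_stop if t_stop is not None else _default_t_stop(last_spike, pattern)
        trials = []
        for tid in sorted(spikes_by_trial):
            times = np.asarray(spikes_by_trial[tid], dtype=float)
            if times.size > 1 and not np.all(np.diff(times) > 0):
                raise ValidationError(
                    f"{path}: cell {cell_id} trial {tid}: spike times not "
                    "strictly increasing"
                )
            trials.append(
                SpikeTrain(
                    spike_times=times, trial_id=tid, t_start=t_start, t_stop=stop
                )
            )
        recordings.append(
            CellRecording(
                cell_id=str(cell_id),
                protocol_id=str(protocol_id),
                blocked=blocked,
                trials=tuple(trials),
                stimulus=pattern,
            )
        )
    return recordings


def read_recording(path, **kwargs) -> CellRecording:
    """Read a spike table expected to hold exactly one (cell, protocol,
    condition) group."""
    recs = read_recordings(path, **kwargs)
    if len(recs) != 1:
        raise ValidationError(
            f"{path}: expected one (cell, protocol, condition) group, "
            f"found {len(recs)}; use read_recordings()"
        )
    return recs[0]


def write_recording(recording: CellRecording, path) -> None:
    """Write one recording in the spike-table dialect.

    Trials with no spikes are kept as a single row with an empty
    ``spike_time_s`` field so they survive a round trip.
    """
    rows = []
    condition = blocked_to_condition(recording.blocked)
    for trial in recording.trials:
        if trial.n_spikes == 0:
            rows.append((recording.cell_id, recording.protocol_id, condition,
                         trial.trial_id, None))
        for t in trial.spike_times:
            rows.append((recording.cell_id, recording.protocol_id, condition,
                         trial.trial_id, t))
    pd.DataFrame(rows, columns=SPIKE_COLUMNS).to_csv(path, index=False)


def write_recordings(recordings: Iterable[CellRecording], path) -> None:
    """Write several recordings into one spike table."""
    frames = []
    for rec in recordings:
        condition = blocked_to_condition(rec.blocked)
        for trial in rec.trials:
            times = trial.spike_times if trial.n_spikes else np.array([np.nan])
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": rec.cell_id,
                        "protocol_id": rec.protocol_id,
                        "condition": condition,
                        "trial": trial.trial_id,
                        "spike_time_s": times,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _canonical_columns(columns: Iterable[str]) -> list[str]:
    columns = list(columns)
    known = [c for c in METRICS_COLUMN_ORDER if c in columns]
    extra = sorted(c for c in columns if c not in METRICS_COLUMN_ORDER)
    return known + extra


def write_metrics_table(records, path) -> None:
    """Write per-cell metric records as CSV with deterministic column order.

    ``records`` is a DataFrame or an iterable of mappings sharing a schema.
    Missing values (None/NaN) are written as empty fields.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        records = list(records)
        if not records:
            raise ValidationError("no records to write")
        keys = set(records[0])
        for r in records[1:]:
            if set(r) != keys:
                raise ValidationError("metric records do not share a schema")
        df = pd.DataFrame.from_records(records)
    df = df[_canonical_columns(df.columns)]
    df.to_csv(path, index=False, na_rep="")


def read_metrics_table(path) -> pd.DataFrame:
    """Read a metrics table back; empty fields become NaN."""
    return pd.read_csv(path)
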