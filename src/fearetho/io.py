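"""CSV dialects for frame-label tables and operant event logs.

Frame-label files are long-format CSV, one row per frame:

    rat_id,session_id,session_type,trial_index,frame_index,observer_id,label
    [,group,sex,intensity_mA]

The three metadata columns are optional on read (they default to a paired
conditioning trial at 0.5 mA, useful for observer-only reliability files)
and always written. Event logs are two-column CSV: ``time_s,event``.

Violations raise — an incomplete trial or unknown label never truncates.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Sequence

import pandas as pd

from .behaviors import ALL_LABELS, N_FRAMES
from .errors import CompletenessError, ConflictError, ParseError
from .model import EVENT_KINDS, EventLog, TrialFrames

FRAME_COLUMNS = (
    "rat_id",
    "session_id",
    "session_type",
    "trial_index",
    "frame_index",
    "observer_id",
    "label",
)
META_COLUMNS = ("group", "sex", "intensity_mA")
_META_DEFAULTS = {"group": "paired", "sex": "female", "intensity_mA": 0.5}

EVENT_COLUMNS = ("time_s", "event")


def read_frame_labels(path: str | os.PathLike) -> list[TrialFrames]:
    """Parse a frame-label CSV into one ``TrialFrames`` per (trial, observer).

    Raises :class:`ParseError` on unknown labels (naming the row),
    :class:`ConflictError` on duplicate (trial, frame, observer) rows, and
    :class:`CompletenessError` listing missing frames for any trial with
    fewer than 87.
    """
    df = pd.read_csv(
        path,
        dtype={"rat_id": str, "session_id": str, "observer_id": str},
        float_precision="round_trip",
    )
    missing_cols = [c for c in FRAME_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing required column(s) {missing_cols}")
    for col, default in _META_DEFAULTS.items():
        if col not in df.columns:
            df[col] = default

    bad = ~df["label"].isin(ALL_LABELS)
    if bad.any():
        row = df.index[bad][0]
        raise ParseError(
            f"{path}: row {row + 2} has unknown label {df.loc[row, 'label']!r} "
            f"(closed alphabet: {ALL_LABELS})"
        )

    key_cols = ["rat_id", "session_id", "trial_index", "observer_id"]
    dup = df.duplicated(subset=key_cols + ["frame_index"], keep=False)
    if dup.any():
        first = df.loc[df.index[dup][0], key_cols + ["frame_index"]]
        raise ConflictError(
            f"{path}: duplicate frame rows for trial "
            f"{tuple(first[key_cols])} frame {first['frame_index']}"
        )

    trials: list[TrialFrames] = []
    for key, g in df.groupby(key_cols, sort=True):
        got = set(g["frame_index"].astype(int))
        gaps = sorted(set(range(1, N_FRAMES + 1)) - got)
        extra = sorted(got - set(range(1, N_FRAMES + 1)))
        if gaps or extra:
            msg = f"{path}: trial {key} "
            if gaps:
                msg += f"is missing frame(s) {gaps}"
            if extra:
                msg += f"{'; ' if gaps else ''}has out-of-range frame(s) {extra}"
            raise CompletenessError(msg)
        g = g.sort_values("frame_index")
        row0 = g.iloc[0]
        trials.append(
            TrialFrames(
                rat_id=str(key[0]),
                session_id=str(key[1]),
                session_type=str(row0["session_type"]),
                trial_index=int(key[2]),
                group=str(row0["group"]),
                sex=str(row0["sex"]),
                intensity_mA=float(row0["intensity_mA"]),
                labels=tuple(g["label"]),
                observer_id=str(key[3]),
            )
        )
    return trials


def write_frame_labels(trials: Iterable[TrialFrames], path: str | os.PathLike) -> None:
    """Write trials to the frame-label CSV dialect (metadata columns included)."""
    rows = []
    for tr in trials:
        for i, lab in enumerate(tr.labels, start=1):
            rows.append(
                (
                    tr.rat_id,
                    tr.session_id,
                    tr.session_type,
                    tr.trial_index,
                    i,
                    tr.observer_id,
                    lab,
                    tr.group,
                    tr.sex,
                    tr.intensity_mA,
                )
            )
    pd.DataFrame(rows, columns=list(FRAME_COLUMNS + META_COLUMNS)).to_csv(path, index=False)


def read_event_log(path: str | os.PathLike, **metadata) -> EventLog:
    """Parse a ``time_s,event`` CSV into an :class:`EventLog`.

    Structural violations (cue_off before cue_on, negative or decreasing
    times, unknown event kinds) raise via ``EventLog`` validation.
    """
    # round_trip parsing: written times must re-read bit-exactly
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    bad = ~df["event"].isin(EVENT_KINDS)
    if bad.any():
        row = df.index[bad][0]
        raise ParseError(f"{path}: row {row + 2} has unknown event {df.loc[row, 'event']!r}")
    events = tuple(zip(df["time_s"].astype(float), df["event"].astype(str)))
    return EventLog(events=events, **metadata)


def write_event_log(log: EventLog, path: str | os.PathLike) -> None:
    pd.DataFrame(log.events, columns=list(EVENT_COLUMNS)).to_csv(path, index=False)


def write_suppression(records: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write per-trial suppression records (undefined ratios as empty fields)."""
    records.to_csv(path, index=False)


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a combined session-feature table, validating metadata columns."""
    df = pd.read_csv(
        path, dtype={"rat_id": str, "session_id": str}, float_precision="round_trip"
    )
    required = ["rat_id", "session_id", "session_type", "group", "sex", "intensity_mA"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: feature table missing metadata column(s) {missing}")
    return df


def _as_list(trials: Iterable[TrialFrames]) -> Sequence[TrialFrames]:
    return trials if isinstance(trials, Sequence) else list(trials)
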