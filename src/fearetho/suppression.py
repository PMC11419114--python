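"""Conditioned suppression ratios from operant event logs.

For each 10-s cue presentation, the baseline poke rate is the poke count in
the 20-s pre-cue window times 3 (pokes/min) and the cue poke rate is the
poke count during the 10-s cue times 6. Suppression is

    ratio = (baseline_rate - cue_rate) / (baseline_rate + cue_rate)

so 1 is complete suppression of poking during the cue, 0 equivalent rates,
and negative values increased poking during the cue. A trial with no pokes
in either window (0/0) is undefined: it is reported as NaN and excluded
from session means rather than imputed, since imputing 0 or 1 would bias
group means in opposite directions.

Windows are half-open ``[start, end)``: a poke at exactly cue onset counts
toward the cue window.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import StructureError
from .model import EventLog

BASELINE_WINDOW_S = 20.0
CUE_WINDOW_S = 10.0


def poke_rate(log: EventLog, window: tuple[float, float], scale_to_per_min: float | None = None) -> float:
    """Poke count in half-open ``[start, end)`` scaled to pokes/min.

    When ``scale_to_per_min`` is omitted it is derived from the window
    length (20 s -> 3, 10 s -> 6).
    """
    start, end = window
    if end <= start:
        raise ValueError(f"inverted or empty window [{start}, {end})")
    if scale_to_per_min is None:
        scale_to_per_min = 60.0 / (end - start)
    times = log.poke_times
    count = int(np.count_nonzero((times >= start) & (times < end)))
    return count * scale_to_per_min


def suppression_ratio(baseline_rate: float, cue_rate: float) -> float:
    """(b - c)/(b + c); NaN (undefined) when both rates are zero."""
    if baseline_rate < 0 or cue_rate < 0:
        raise ValueError("poke rates must be non-negative")
    total = baseline_rate + cue_rate
    if total == 0:
        return math.nan
    return (baseline_rate - cue_rate) / total


def session_suppression(log: EventLog) -> pd.DataFrame:
    """Per-trial suppression records for every cue interval of a session.

    Returns a DataFrame with columns ``trial_index, baseline_rate,
    cue_rate, ratio`` (ratio NaN when undefined). Raises
    :class:`StructureError` if a trial's 20-s baseline window overlaps the
    previous cue interval, or if the log has no cue interval.
    """
    intervals = log.cue_intervals
    if not intervals:
        raise StructureError("event log contains no cue interval")
    rows = []
    prev_off = -math.inf
    for i, (on, off) in enumerate(intervals, start=1):
        base_start = on - BASELINE_WINDOW_S
        if base_start < prev_off:
            raise StructureError(
                f"baseline window of trial {i} (starting {base_start:.1f}s) "
                f"overlaps the previous cue interval ending {prev_off:.1f}s"
            )
        b = poke_rate(log, (base_start, on))
        c = poke_rate(log, (on, off), scale_to_per_min=60.0 / CUE_WINDOW_S)
        rows.append((i, b, c, suppression_ratio(b, c)))
        prev_off = off
    return pd.DataFrame(rows, columns=["trial_index", "baseline_rate", "cue_rate", "ratio"])


def session_mean(records: pd.DataFrame) -> float:
    """Mean ratio over defined (non-NaN) trials; NaN if none are defined."""
    defined = records["ratio"].dropna()
    return float(defined.mean()) if len(defined) else math.nan


def suppression_table(logs: list[EventLog]) -> pd.DataFrame:
    """Long-format per-trial records for many sessions, with identifiers."""
    frames = []
    for log in logs:
        rec = session_suppression(log)
        rec.insert(0, "rat_id", log.rat_id)
        rec.insert(1, "session_id", log.session_id)
        for k, v in log.metadata.items():
            rec[k] = v
        frames.append(rec)
    return pd.concat(frames, ignore_index=True)
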