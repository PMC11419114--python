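"""Ethogram construction: indicator matrices, session arrays, group percents.

The scored trial is lifted to a 13 x 87 one-hot indicator (12 behaviors +
background, one column per 200-ms frame). Averaging a rat-session's 4 trial
indicators (behavior rows only) gives the 12 x 87 session ethogram whose
row-major flattening is the 1044-element feature vector used for
classification: behavior-major order, i.e. behavior 1 frames 1-87, then
behavior 2, and so on. Group ethograms are % behavior per bin across all
selected trials and retain the background row so that every column sums to
100.
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behaviors import (
    ALL_LABELS,
    BEHAVIORS,
    LABEL_INDEX,
    N_BEHAVIORS,
    N_FRAMES,
    N_LABELS,
    TRIALS_PER_SESSION,
    period_slice,
)
from .errors import SelectionError
from .model import TrialFrames

N_FEATURES = N_BEHAVIORS * N_FRAMES  # 1044


def indicator(trial: TrialFrames) -> np.ndarray:
    """13 x 87 one-hot indicator; every column sums to exactly 1."""
    mat = np.zeros((N_LABELS, N_FRAMES), dtype=np.int8)
    for col, label in enumerate(trial.labels):
        mat[LABEL_INDEX[label], col] = 1
    return mat


@dataclass(frozen=True)
class SessionEthogram:
    """12 x 87 across-trial mean of one-hot indicators for one rat-session.

    With 4 trials every cell lies in {0, 0.25, 0.5, 0.75, 1}. ``flatten``
    is behavior-major (row-major) and has length 1044.
    """

    matrix: np.ndarray
    n_trials: int
    rat_id: str
    session_id: str
    session_type: str
    group: str
    sex: str
    intensity_mA: float

    def __post_init__(self) -> None:
        if self.matrix.shape != (N_BEHAVIORS, N_FRAMES):
            raise ValueError(f"session matrix must be {N_BEHAVIORS} x {N_FRAMES}, got {self.matrix.shape}")

    def flatten(self) -> np.ndarray:
        return np.ascontiguousarray(self.matrix).reshape(-1)


def session_array(trials: Sequence[TrialFrames]) -> SessionEthogram:
    """Session ethogram from exactly 4 trials of one rat-session.

    Raises ``ValueError`` on a wrong trial count or mixed rat/session — no
    silent renormalization.
    """
    trials = list(trials)
    if len(trials) != TRIALS_PER_SESSION:
        raise ValueError(f"a session array requires exactly {TRIALS_PER_SESSION} trials, got {len(trials)}")
    keys = {(t.rat_id, t.session_id) for t in trials}
    if len(keys) != 1:
        raise ValueError(f"trials span multiple rat-sessions: {sorted(keys)}")
    stack = np.stack([indicator(t)[:N_BEHAVIORS].astype(float) for t in trials])
    t0 = trials[0]
    return SessionEthogram(
        matrix=stack.mean(axis=0),
        n_trials=len(trials),
        rat_id=t0.rat_id,
        session_id=t0.session_id,
        session_type=t0.session_type,
        group=t0.group,
        sex=t0.sex,
        intensity_mA=t0.intensity_mA,
    )


def session_arrays(trials: Iterable[TrialFrames]) -> list[SessionEthogram]:
    """Group a trial collection by (rat, session) and build every session array."""
    by_session: dict[tuple[str, str], list[TrialFrames]] = defaultdict(list)
    for t in trials:
        by_session[(t.rat_id, t.session_id)].append(t)
    out = []
    for key in sorted(by_session):
        group = sorted(by_session[key], key=lambda t: t.trial_index)
        out.append(session_array(group))
    return out


def group_ethogram(
    trials: Iterable[TrialFrames],
    *,
    group: str | None = None,
    session_type: str | None = None,
    sex: str | None = None,
    intensity_mA: float | None = None,
) -> np.ndarray:
    """13 x 87 % behavior per bin over all selected trial-frames.

    Rows follow the canonical label order (12 behaviors, then background);
    each column sums to 100. Raises :class:`SelectionError` when the filter
    matches nothing.
    """
    selected = [
        t
        for t in trials
        if (group is None or t.group == group)
        and (session_type is None or t.session_type == session_type)
        and (sex is None or t.sex == sex)
        and (intensity_mA is None or t.intensity_mA == intensity_mA)
    ]
    if not selected:
        raise SelectionError("group-ethogram selector matched no trials")
    stack = np.stack([indicator(t).astype(float) for t in selected])
    return stack.mean(axis=0) * 100.0


def segment(array: SessionEthogram | np.ndarray, period: str) -> np.ndarray:
    """Restrict a session matrix or flat feature vector to a trial period.

    Accepts a ``SessionEthogram``, a (behaviors x 87) matrix, or the
    1044-element flattened vector; returns the same kind restricted to the
    period's frames (flattened input -> flattened output of length
    12 x period frames: 300, 600, 144, or 1044).
    """
    cols = period_slice(period)
    if isinstance(array, SessionEthogram):
        return array.matrix[:, cols]
    arr = np.asarray(array)
    if arr.ndim == 2 and arr.shape[-1] == N_FRAMES:
        return arr[:, cols]
    if arr.ndim == 1 and arr.size == N_FEATURES:
        return arr.reshape(N_BEHAVIORS, N_FRAMES)[:, cols].reshape(-1)
    raise ValueError(f"cannot segment array of shape {arr.shape}")


def stack_sessions(eths: Sequence[SessionEthogram]) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Stack session ethograms into classifier inputs.

    Returns ``(arrays, labels, meta)``: a (n, 12, 87) array, the group label
    per session, and a metadata DataFrame aligned row-for-row.
    """
    arrays = np.stack([e.matrix for e in eths])
    labels = np.array([e.group for e in eths])
    meta = pd.DataFrame(
        {
            "rat_id": [e.rat_id for e in eths],
            "session_id": [e.session_id for e in eths],
            "session_type": [e.session_type for e in eths],
            "group": labels,
            "sex": [e.sex for e in eths],
            "intensity_mA": [e.intensity_mA for e in eths],
        }
    )
    return arrays, labels, meta


def feature_table(eths: Sequence[SessionEthogram]) -> pd.DataFrame:
    """Combined feature table: metadata columns + f0000..f1043 per session."""
    arrays, _, meta = stack_sessions(eths)
    flat = arrays.reshape(len(eths), N_FEATURES)
    feats = pd.DataFrame(flat, columns=[f"f{i:04d}" for i in range(N_FEATURES)])
    return pd.concat([meta.reset_index(drop=True), feats], axis=1)


def plot_ethogram(percent: np.ndarray, ax=None, labels: Sequence[str] = ALL_LABELS):
    """Stacked-area ethogram of a 13 x 87 (or 12 x 87) percent matrix."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    x = (np.arange(N_FRAMES) - 25) * 0.2  # cue onset at 0 s
    ax.stackplot(x, percent, labels=labels[: percent.shape[0]])
    ax.set_xlabel("time from cue onset (s)")
    ax.set_ylabel("% behavior")
    ax.set_xlim(x[0], x[-1])
    ax.set_ylim(0, 100)
    ax.legend(fontsize=6, ncol=2, loc="upper right")
    return ax


def behavior_row(label: str) -> int:
    """Row index of a label in the canonical 13-row ordering."""
    return LABEL_INDEX[label]


__all__ = [
    "N_FEATURES",
    "SessionEthogram",
    "indicator",
    "session_array",
    "session_arrays",
    "group_ethogram",
    "segment",
    "stack_sessions",
    "feature_table",
    "plot_ethogram",
    "behavior_row",
    "BEHAVIORS",
]
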