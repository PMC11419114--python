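"""Core data structures: scored trials and operant event logs.

``TrialFrames`` is the atomic unit of scored behavior: one trial's 87
ordered frame labels plus subject/session metadata. ``EventLog`` holds the
timestamped nose pokes, cue on/off transitions, and shocks recorded for one
session by the operant control program.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behaviors import ALL_LABELS, GROUPS, N_FRAMES, SESSION_TYPES, SEXES
from .errors import ParseError, StructureError

EVENT_KINDS = ("poke", "cue_on", "cue_off", "shock")

_LABEL_SET = frozenset(ALL_LABELS)


@dataclass(frozen=True)
class TrialFrames:
    """One trial's 87 ordered frame labels with metadata.

    ``labels`` must have exactly one entry per captured frame; mutual
    exclusivity of behaviors is structural (one label per frame).
    """

    rat_id: str
    session_id: str
    session_type: str
    trial_index: int
    group: str
    sex: str
    intensity_mA: float
    labels: tuple[str, ...]
    observer_id: str = "obs1"
    frame_period_s: float = 0.2

    def __post_init__(self) -> None:
        if self.session_type not in SESSION_TYPES:
            raise ParseError(
                f"unknown session_type {self.session_type!r}; "
                f"expected one of {SESSION_TYPES}"
            )
        if self.group not in GROUPS:
            raise ParseError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.sex not in SEXES:
            raise ParseError(f"unknown sex {self.sex!r}; expected one of {SEXES}")
        if not (isinstance(self.trial_index, int) and self.trial_index >= 1):
            raise ParseError(f"trial_index must be an integer >= 1, got {self.trial_index!r}")
        if not self.intensity_mA > 0:
            raise ParseError(f"intensity_mA must be positive, got {self.intensity_mA!r}")
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != N_FRAMES:
            raise ParseError(
                f"trial {self.key} has {len(self.labels)} labels; "
                f"exactly {N_FRAMES} frames are required"
            )
        bad = [lab for lab in self.labels if lab not in _LABEL_SET]
        if bad:
            raise ParseError(
                f"trial {self.key} contains unknown label(s) {sorted(set(bad))!r}; "
                f"the alphabet is closed over {ALL_LABELS}"
            )

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.rat_id, self.session_id, self.trial_index, self.observer_id)

    @property
    def trial_key(self) -> tuple[str, str, int]:
        """Identity of the scored trial, ignoring who scored it."""
        return (self.rat_id, self.session_id, self.trial_index)


@dataclass(frozen=True)
class EventLog:
    """Timestamped operant events for one session.

    Events are (time_s, kind) pairs sorted by time; ties keep input order.
    Cue on/off events must strictly alternate starting with ``cue_on``.
    """

    events: tuple[tuple[float, str], ...]
    rat_id: str = ""
    session_id: str = ""
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        evs = tuple((float(t), str(k)) for t, k in self.events)
        object.__setattr__(self, "events", evs)
        last = -np.inf
        state_on = False
        for t, kind in evs:
            if kind not in EVENT_KINDS:
                raise ParseError(f"unknown event kind {kind!r}; expected one of {EVENT_KINDS}")
            if t < 0:
                raise ParseError(f"negative event time {t}")
            if t < last:
                raise ParseError(f"event times must be non-decreasing (saw {t} after {last})")
            last = t
            if kind == "cue_on":
                if state_on:
                    raise StructureError(f"cue_on at t={t} while cue already on")
                state_on = True
            elif kind == "cue_off":
                if not state_on:
                    raise StructureError(f"cue_off at t={t} without preceding cue_on")
                state_on = False
        if state_on:
            raise StructureError("log ends with cue on (missing cue_off)")

    @property
    def cue_intervals(self) -> list[tuple[float, float]]:
        """Well-formed (on, off) cue intervals in temporal order."""
        out, on_t = [], None
        for t, kind in self.events:
            if kind == "cue_on":
                on_t = t
            elif kind == "cue_off":
                out.append((on_t, t))
                on_t = None
        return out

    @property
    def poke_times(self) -> np.ndarray:
        return np.array([t for t, k in self.events if k == "poke"], dtype=float)

    @property
    def shock_times(self) -> np.ndarray:
        return np.array([t for t, k in self.events if k == "shock"], dtype=float)
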