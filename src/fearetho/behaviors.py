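"""Behavior alphabet, category map, and trial timeline constants.

A trial is 87 frames captured at 5 frames/s (200 ms per frame): 5 s of
baseline, a 10-s cue-light presentation, and 2.5 s following cue offset.
Every frame carries exactly one of 12 mutually exclusive scored behaviors,
or ``background`` when no specific behavior can be discerned.
"""

from __future__ import annotations

#: The 12 scored behaviors, in canonical output order.
BEHAVIORS: tuple[str, ...] = (
    "freeze",
    "stretch",
    "rear",
    "light_rear",
    "scale",
    "light_scale",
    "jump",
    "locomote",
    "backpedal",
    "cup",
    "port",
    "groom",
)

#: Label assigned when no specific behavior can be discerned.
BACKGROUND: str = "background"

#: Full closed alphabet: 12 behaviors + background = 13 labels.
ALL_LABELS: tuple[str, ...] = BEHAVIORS + (BACKGROUND,)

LABEL_INDEX: dict[str, int] = {name: i for i, name in enumerate(ALL_LABELS)}

N_BEHAVIORS = len(BEHAVIORS)  # 12
N_LABELS = len(ALL_LABELS)  # 13

#: Multi-behavior categories used for feature-subset classification.
#: ``groom`` belongs to no category.
CATEGORIES: dict[str, tuple[str, ...]] = {
    "Immobile": ("freeze", "stretch"),
    "Horizontal": ("locomote", "backpedal"),
    "Vertical": ("rear", "scale", "jump", "light_rear", "light_scale"),
    "Reward": ("cup", "port"),
}

#: Frames per trial (5 s baseline + 10 s cue + 2.5 s post at 5 frames/s).
N_FRAMES = 87
FRAME_PERIOD_S = 0.2
TRIALS_PER_SESSION = 4
FRAMES_PER_SESSION = N_FRAMES * TRIALS_PER_SESSION  # 348

#: Trial periods as 1-based inclusive frame ranges.
PERIODS: dict[str, tuple[int, int]] = {
    "baseline": (1, 25),
    "cue": (26, 75),
    "post": (76, 87),
    "all": (1, 87),
}

SESSION_TYPES = ("conditioning", "extinction", "preexposure")
GROUPS = ("paired", "unpaired")
SEXES = ("female", "male")


def period_slice(period: str) -> slice:
    """0-based column slice for a named trial period.

    Raises ``ValueError`` for an unknown period name.
    """
    try:
        lo, hi = PERIODS[period]
    except KeyError:
        raise ValueError(
            f"unknown period {period!r}; expected one of {sorted(PERIODS)}"
        ) from None
    return slice(lo - 1, hi)


def frame_time_s(frame_index: int) -> float:
    """Start time of a 1-based frame relative to cue onset (frame 26 = 0 s)."""
    return (frame_index - 26) * FRAME_PERIOD_S
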