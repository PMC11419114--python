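"""Synthetic behavior and nose-poke generator.

Emulates the experiment the analysis expects: 32 rats split evenly into
paired and unpaired groups (balanced over sex and two shock intensities),
two scored sessions (conditioning and extinction) of 4 trials each, 87
frames per trial at 5 frames/s — 22,272 frames in all — plus Poisson
nose-poke event logs with cue-period suppression.

Behavior within a trial follows a semi-Markov process: a state's dwell is
geometric with a per-behavior mean (freeze >= 3 frames, matching the
>= 600 ms scoring definition of a freeze bout), after which the next state
is drawn from the active period's jump distribution. Kinetics are packaged
in ``data/kinetics.yaml`` as a shared base distribution plus zero-sum
group deltas; the effect-size setting scales the deltas (``none`` makes
paired and unpaired generatively identical). At a period boundary the state
is redrawn from the new period's distribution (cue onset and shock are
salient events). Frames 76-87 use shock kinetics for paired conditioning
trials and the group's post kinetics otherwise.

All randomness descends from one root seed through hierarchical
``SeedSequence`` spawning (per rat, session, trial), so any single trial is
reproducible in isolation.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .behaviors import ALL_LABELS, N_FRAMES, N_LABELS, PERIODS
from .errors import ParseError
from .model import EventLog, TrialFrames

EFFECT_SIZES = {"none": 0.0, "moderate": 1.0, "strong": 1.75}

_PERIOD_NAMES = ("baseline", "cue", "shock", "post")


@dataclass(frozen=True)
class BehaviorKinetics:
    """Per-period jump kernels, dwell means, and initial distributions.

    ``transition[period]`` is a 13 x 13 row-stochastic matrix over the
    label alphabet; ``initial[period]`` is the distribution the state is
    redrawn from on entering the period; ``dwell`` holds per-label mean
    dwell in frames (>= 1).
    """

    transition: dict[str, np.ndarray]
    dwell: np.ndarray
    initial: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name in _PERIOD_NAMES:
            if name not in self.transition or name not in self.initial:
                raise ParseError(f"kinetics missing period {name!r}")
        for name, mat in self.transition.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (N_LABELS, N_LABELS) or (mat < 0).any():
                raise ParseError(f"{name}: transition matrix must be {N_LABELS} x {N_LABELS}, non-negative")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-12):
                raise ParseError(f"{name}: transition rows must sum to 1")
        if (np.asarray(self.dwell) < 1).any():
            raise ParseError("mean dwell must be >= 1 frame")
        for name, pi in self.initial.items():
            pi = np.asarray(pi, dtype=float)
            if pi.shape != (N_LABELS,) or (pi < 0).any() or not np.isclose(pi.sum(), 1.0, atol=1e-12):
                raise ParseError(f"{name}: initial distribution must be a {N_LABELS}-simplex")


@dataclass(frozen=True)
class SimConfig:
    """Stated world of the synthetic experiment (defaults = design cardinalities)."""

    n_rats_per_group: int = 16
    intensities: tuple[float, float] = (0.35, 0.5)
    trials_per_session: int = 4
    sessions: tuple[str, ...] = ("conditioning", "extinction")
    frames_per_trial: int = N_FRAMES
    effect_size: str = "moderate"
    poke_rate_per_min: float = 20.0
    poke_suppression: dict = field(
        default_factory=lambda: {"paired": 0.8, "unpaired": 0.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size not in EFFECT_SIZES:
            raise ParseError(f"effect_size must be one of {sorted(EFFECT_SIZES)}")
        if self.n_rats_per_group % 4:
            raise ParseError("n_rats_per_group must be divisible by 4 (sex x intensity balance)")


@dataclass(frozen=True)
class Dataset:
    """Everything one synthetic experiment produces."""

    trials: list[TrialFrames]
    event_logs: list[EventLog]
    config: SimConfig

    @property
    def n_frames(self) -> int:
        return sum(len(t.labels) for t in self.trials)


@lru_cache(maxsize=1)
def _kinetics_spec() -> dict:
    text = resources.files("fearetho.data").joinpath("kinetics.yaml").read_text()
    return yaml.safe_load(text)


def _dist_from(mapping: dict[str, float]) -> np.ndarray:
    vec = np.array([mapping.get(lab, 0.0) for lab in ALL_LABELS], dtype=float)
    return vec


def default_kinetics(group: str, effect_size: str = "moderate") -> BehaviorKinetics:
    """Packaged kinetics for a group at a given effect size.

    Each period's jump distribution is ``clip(base + e * delta, 0)``
    renormalized, broadcast to identical rows (state-independent jumps);
    bout structure comes from the dwell distribution.
    """
    spec = _kinetics_spec()
    e = EFFECT_SIZES[effect_size]
    dwell = _dist_from(spec["dwell"])
    transition: dict[str, np.ndarray] = {}
    initial: dict[str, np.ndarray] = {}
    for period in _PERIOD_NAMES:
        base = _dist_from(spec["base"][period])
        delta = _dist_from(spec["delta"].get(group, {}).get(period, {}))
        pi = np.clip(base + e * delta, 0.0, None)
        pi = pi / pi.sum()
        transition[period] = np.tile(pi, (N_LABELS, 1))
        initial[period] = pi
    return BehaviorKinetics(transition=transition, dwell=dwell, initial=initial)


def simulate_sequence(
    kinetics: BehaviorKinetics, period: str, n_frames: int, rng: np.random.Generator
) -> list[str]:
    """Semi-Markov label sequence under one period's kinetics."""
    if n_frames < 0:
        raise ValueError("n_frames must be non-negative")
    pi = kinetics.initial[period]
    kernel = kinetics.transition[period]
    labels: list[str] = []
    state = int(rng.choice(N_LABELS, p=pi))
    dwell = int(rng.geometric(1.0 / kinetics.dwell[state]))
    while len(labels) < n_frames:
        labels.append(ALL_LABELS[state])
        dwell -= 1
        if dwell <= 0:
            state = int(rng.choice(N_LABELS, p=kernel[state]))
            dwell = int(rng.geometric(1.0 / kinetics.dwell[state]))
    return labels


def _trial_schedule(group: str, session_type: str) -> list[tuple[str, int]]:
    """(period, n_frames) segments for one trial."""
    final = "shock" if (group == "paired" and session_type == "conditioning") else "post"
    b_lo, b_hi = PERIODS["baseline"]
    c_lo, c_hi = PERIODS["cue"]
    p_lo, p_hi = PERIODS["post"]
    return [
        ("baseline", b_hi - b_lo + 1),
        ("cue", c_hi - c_lo + 1),
        (final, p_hi - p_lo + 1),
    ]


def simulate_trial(
    kinetics: BehaviorKinetics,
    group: str,
    session_type: str,
    rng: np.random.Generator,
    **metadata,
) -> TrialFrames:
    """Simulate one 87-frame trial (baseline / cue / shock-or-post segments)."""
    labels: list[str] = []
    for period, n in _trial_schedule(group, session_type):
        labels.extend(simulate_sequence(kinetics, period, n, rng))
    defaults = dict(
        rat_id="r01",
        session_id="s1",
        trial_index=1,
        sex="female",
        intensity_mA=0.5,
        observer_id="obs1",
    )
    defaults.update(metadata)
    return TrialFrames(
        group=group, session_type=session_type, labels=tuple(labels), **defaults
    )


def simulate_pokes(
    rate_per_min: float,
    suppression: float,
    cue_intervals: Sequence[tuple[float, float]],
    duration_s: float,
    rng: np.random.Generator,
) -> list[float]:
    """Poke times from a piecewise-homogeneous Poisson process.

    Rate is ``rate_per_min`` outside cue intervals and
    ``rate_per_min * (1 - suppression)`` inside them.
    """
    if duration_s < 0:
        raise ValueError("duration must be non-negative")
    if rate_per_min < 0 or not 0.0 <= suppression <= 1.0:
        raise ValueError("need rate >= 0 and suppression in [0, 1]")
    edges = [0.0]
    for on, off in sorted(cue_intervals):
        edges += [min(on, duration_s), min(off, duration_s)]
    edges.append(duration_s)
    times: list[float] = []
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        if hi <= lo:
            continue
        in_cue = i % 2 == 1  # segments alternate outside/inside starting outside
        rate = rate_per_min / 60.0 * ((1.0 - suppression) if in_cue else 1.0)
        n = int(rng.poisson(rate * (hi - lo)))
        times.extend(lo + (hi - lo) * rng.random(n))
    return sorted(times)


#: Cue onsets (s) in a 2580-s session; schematic but non-overlapping with
#: the 20-s baseline windows.
CUE_ONSETS_S = (600.0, 1200.0, 1800.0, 2400.0)
CUE_DURATION_S = 10.0
SESSION_DURATION_S = 2580.0


def simulate_session_log(
    config: SimConfig,
    group: str,
    session_type: str,
    rng: np.random.Generator,
    **metadata,
) -> EventLog:
    """One session's event log: cue on/off pairs, pokes, and shocks."""
    intervals = [(on, on + CUE_DURATION_S) for on in CUE_ONSETS_S]
    pokes = simulate_pokes(
        config.poke_rate_per_min,
        config.poke_suppression[group],
        intervals,
        SESSION_DURATION_S,
        rng,
    )
    events = [(t, "poke") for t in pokes]
    for on, off in intervals:
        events += [(on, "cue_on"), (off, "cue_off")]
    if session_type == "conditioning":
        if group == "paired":
            events += [(off, "shock") for _, off in intervals]
        else:
            events += [(on + 430.0, "shock") for on, _ in intervals]
    events.sort(key=lambda e: e[0])
    return EventLog(events=tuple(events), **metadata)


def rat_roster(config: SimConfig) -> list[dict]:
    """Balanced rat assignment: group x intensity x sex, n/4 rats per cell."""
    roster = []
    i = 0
    per_cell = config.n_rats_per_group // 4
    for group in ("paired", "unpaired"):
        for intensity in config.intensities:
            for sex in ("female", "male"):
                for _ in range(per_cell):
                    i += 1
                    roster.append(
                        dict(rat_id=f"r{i:02d}", group=group, sex=sex, intensity_mA=intensity)
                    )
    return roster


def simulate_experiment(config: SimConfig | None = None) -> Dataset:
    """Full factorial synthetic experiment under one root seed.

    Defaults reproduce the design cardinalities: 32 rats, 2 scored sessions
    x 4 trials x 87 frames = 22,272 frames, 64 session arrays.
    """
    config = config or SimConfig()
    root = np.random.SeedSequence(config.seed)
    roster = rat_roster(config)
    rat_seeds = root.spawn(len(roster))

    trials: list[TrialFrames] = []
    logs: list[EventLog] = []
    for rat, rat_ss in zip(roster, rat_seeds):
        kin = default_kinetics(rat["group"], config.effect_size)
        for s_i, session_type in enumerate(config.sessions, start=1):
            sess_ss = rat_ss.spawn(1 + config.trials_per_session)
            session_id = f"s{s_i}"
            logs.append(
                simulate_session_log(
                    config,
                    rat["group"],
                    session_type,
                    np.random.default_rng(sess_ss[0]),
                    rat_id=rat["rat_id"],
                    session_id=session_id,
                    metadata=dict(
                        session_type=session_type,
                        group=rat["group"],
                        sex=rat["sex"],
                        intensity_mA=rat["intensity_mA"],
                    ),
                )
            )
            for t_i in range(1, config.trials_per_session + 1):
                trials.append(
                    simulate_trial(
                        kin,
                        rat["group"],
                        session_type,
                        np.random.default_rng(sess_ss[t_i]),
                        rat_id=rat["rat_id"],
                        session_id=session_id,
                        trial_index=t_i,
                        sex=rat["sex"],
                        intensity_mA=rat["intensity_mA"],
                    )
                )
    return Dataset(trials=trials, event_logs=logs, config=config)


def simulate_observers(
    trials: Sequence[TrialFrames],
    n_observers: int = 6,
    disagree_rate: float = 0.15,
    background_bias: float = 0.7,
    rng: np.random.Generator | None = None,
) -> list[TrialFrames]:
    """Multi-observer relabelings of the same trials, for reliability analysis.

    Observer 1 reproduces the input labels; each further observer replaces
    each frame's label with probability ``disagree_rate`` — usually with
    ``background`` (probability ``background_bias``), otherwise with a
    uniformly random different label. This mirrors real scoring, where
    disagreement is mostly behavior-vs-background rather than
    behavior-vs-behavior.
    """
    rng = rng or np.random.default_rng()
    out: list[TrialFrames] = []
    for trial in trials:
        for obs in range(1, n_observers + 1):
            if obs == 1:
                out.append(replace(trial, observer_id="obs1"))
                continue
            labels = list(trial.labels)
            for i, lab in enumerate(labels):
                if rng.random() >= disagree_rate:
                    continue
                if lab != "background" and rng.random() < background_bias:
                    labels[i] = "background"
                else:
                    others = [x for x in ALL_LABELS if x != lab]
                    labels[i] = others[int(rng.integers(len(others)))]
            out.append(replace(trial, labels=tuple(labels), observer_id=f"obs{obs}"))
    return out


def simulate_comparison_trials(
    config: SimConfig | None = None,
    n_trials: int = 8,
    n_observers: int = 6,
    disagree_rate: float = 0.15,
) -> list[TrialFrames]:
    """The shared comparison set: 8 trials scored by all 6 observers (696 frames)."""
    config = config or SimConfig()
    root = np.random.SeedSequence([config.seed, 696])
    trial_ss, obs_ss = root.spawn(2)
    kin_p = default_kinetics("paired", config.effect_size)
    kin_u = default_kinetics("unpaired", config.effect_size)
    rng = np.random.default_rng(trial_ss)
    base_trials = [
        simulate_trial(
            kin_p if i % 2 == 0 else kin_u,
            "paired" if i % 2 == 0 else "unpaired",
            "conditioning",
            rng,
            rat_id=f"c{i + 1:02d}",
            session_id="cmp",
            trial_index=1,
        )
        for i in range(n_trials)
    ]
    return simulate_observers(
        base_trials,
        n_observers=n_observers,
        disagree_rate=disagree_rate,
        rng=np.random.default_rng(obs_ss),
    )
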