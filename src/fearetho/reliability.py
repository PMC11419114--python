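"""Inter-observer agreement on frame-level behavior labels.

Agreement is raw % identical observations per observer pair (no chance
correction — that is what the scoring procedure reports), optionally
stratified by how many distinct behaviors occurred in a trial, plus a
13 x 13 observer-pair confusion matrix over every single-frame judgment.

Pairs are unordered; within a pair the lexicographically lower observer id
is "observer 1" (the confusion-matrix row). This deterministic orientation
makes outputs bit-exact.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .behaviors import ALL_LABELS, BACKGROUND, LABEL_INDEX, N_LABELS
from .model import TrialFrames


def pairwise_agreement(a: Sequence[str], b: Sequence[str]) -> float:
    """100 x (#identical positions) / length for two equal-length label sequences."""
    if len(a) != len(b):
        raise ValueError(f"label sequences differ in length ({len(a)} vs {len(b)})")
    if len(a) == 0:
        raise ValueError("label sequences must be non-empty")
    same = sum(x == y for x, y in zip(a, b))
    return 100.0 * same / len(a)


@dataclass(frozen=True)
class ConfusionMatrix:
    """13 x 13 observer-pair judgment counts (rows = observer 1)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.counts.shape != (N_LABELS, N_LABELS):
            raise ValueError(f"confusion matrix must be {N_LABELS} x {N_LABELS}")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_percent(self) -> np.ndarray:
        """Counts normalized per row x 100; empty rows stay 0."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(sums > 0, 100.0 * self.counts / sums, 0.0)
        return pct

    @property
    def diagonal_percent(self) -> float:
        """Overall agreement: trace / total x 100."""
        return 100.0 * float(np.trace(self.counts)) / self.total

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        data = self.row_percent if percent else self.counts
        return pd.DataFrame(data, index=list(ALL_LABELS), columns=list(ALL_LABELS))


@dataclass(frozen=True)
class ReliabilityReport:
    """Pairwise % identical observations with frame-weighted summaries."""

    pairwise: dict[tuple[str, str], float]
    mean_percent: float
    by_n_behaviors: dict[int, float]

    def pairwise_frame(self) -> pd.DataFrame:
        observers = sorted({o for pair in self.pairwise for o in pair})
        mat = pd.DataFrame(np.nan, index=observers, columns=observers)
        for (a, b), v in self.pairwise.items():
            mat.loc[a, b] = v
            mat.loc[b, a] = v
        return mat


def _multi_observer_trials(trials: Iterable[TrialFrames]) -> dict[tuple, dict[str, TrialFrames]]:
    """Group by trial identity; drop (with a warning) single-observer trials."""
    by_trial: dict[tuple, dict[str, TrialFrames]] = defaultdict(dict)
    for t in trials:
        by_trial[t.trial_key][t.observer_id] = t
    single = [k for k, v in by_trial.items() if len(v) < 2]
    if single:
        warnings.warn(
            f"excluding {len(single)} single-observer trial(s) from reliability analysis",
            stacklevel=3,
        )
    return {k: v for k, v in by_trial.items() if len(v) >= 2}


def reliability_report(trials: Iterable[TrialFrames]) -> ReliabilityReport:
    """Pairwise and stratified % identical observations over comparison trials.

    ``by_n_behaviors`` buckets each observer-pair x trial comparison by the
    number of distinct non-background behaviors in the union of the
    observers' labels for that trial (an observer-independent count).
    """
    by_trial = _multi_observer_trials(trials)
    pair_same: dict[tuple[str, str], int] = defaultdict(int)
    pair_n: dict[tuple[str, str], int] = defaultdict(int)
    bucket_vals: dict[int, list[float]] = defaultdict(list)
    all_vals: list[float] = []

    for _, observers in sorted(by_trial.items()):
        union = set().union(*(t.labels for t in observers.values()))
        n_beh = len(union - {BACKGROUND})
        for a, b in combinations(sorted(observers), 2):
            la, lb = observers[a].labels, observers[b].labels
            same = sum(x == y for x, y in zip(la, lb))
            pair_same[(a, b)] += same
            pair_n[(a, b)] += len(la)
            pct = 100.0 * same / len(la)
            bucket_vals[n_beh].append(pct)
            all_vals.append(pct)

    pairwise = {p: 100.0 * pair_same[p] / pair_n[p] for p in pair_same}
    return ReliabilityReport(
        pairwise=pairwise,
        mean_percent=float(np.mean(all_vals)) if all_vals else float("nan"),
        by_n_behaviors={n: float(np.mean(v)) for n, v in sorted(bucket_vals.items())},
    )


def agreement_by_behavior_count(trials: Iterable[TrialFrames]) -> dict[int, float]:
    """Mean % identical per number-of-behaviors-present bucket."""
    return reliability_report(trials).by_n_behaviors


def confusion(trials: Iterable[TrialFrames]) -> ConfusionMatrix:
    """Tally every single-frame judgment for every unordered observer pair.

    Within a pair the lower observer id indexes rows. Perfect agreement
    puts all mass on the diagonal; background-vs-behavior disagreement
    lands in the background row/column.
    """
    counts = np.zeros((N_LABELS, N_LABELS), dtype=np.int64)
    for _, observers in sorted(_multi_observer_trials(trials).items()):
        for a, b in combinations(sorted(observers), 2):
            for x, y in zip(observers[a].labels, observers[b].labels):
                counts[LABEL_INDEX[x], LABEL_INDEX[y]] += 1
    return ConfusionMatrix(counts=counts)
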