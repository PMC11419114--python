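"""Linear discriminant classification of learning status from ethograms.

Each rat-session contributes a 12 x 87 ethogram (1044 features after
behavior-major flattening); with 64 sessions the pooled within-class
covariance is necessarily singular, so the default discriminant uses the
Moore-Penrose pseudo-inverse: ``w = S^+ (mu_1 - mu_0)``, with decisions
from the sign of ``w.x + b``. Shrinkage (``S_g = (1-g) S + g (tr S / p) I``)
and diagonal modes are available and recorded on the model.

Accuracy is estimated by repeated stratified 10-fold cross-validation:
each repetition draws a fresh random partition, accuracy is the mean over
folds of the held-out fraction correct (1 minus the loss), and the result
aggregates 100 repetitions as mean +/- SEM. Two nulls mirror the analysis
design: a session shuffle (permute group labels across sessions — destroys
the label-ethogram association) and a temporal shuffle (permute the 87
frame columns within each session — destroys temporal structure while
preserving per-behavior totals).

All randomness descends from one root seed through ``numpy``
``SeedSequence`` spawning, so fold partitions depend only on (seed, labels)
and are therefore shared across feature subsets run at the same seed —
enabling matched-fold comparisons.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behaviors import BEHAVIORS, CATEGORIES, N_FRAMES, PERIODS, period_slice
from .stats import one_sample_t

_REG_MODES = ("pseudo", "shrinkage", "diag")


@dataclass(frozen=True)
class LdaModel:
    """Fitted two-class linear discriminant: predict class from sign(w.x + b)."""

    classes: tuple
    class_means: np.ndarray  # (2, p)
    w: np.ndarray  # (p,)
    b: float
    regularizer: str
    shrinkage: float = 0.0

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = (self.decision(X) > 0).astype(int)
        return np.asarray(self.classes, dtype=object)[idx]


def fit_lda(
    X: np.ndarray,
    y: Sequence,
    regularizer: str = "pseudo",
    shrinkage: float = 0.0,
) -> LdaModel:
    """Fit a two-class LDA with pooled within-class covariance.

    ``regularizer``: ``pseudo`` (Moore-Penrose, the n << p default),
    ``shrinkage`` (convex blend toward a scaled identity, weight
    ``shrinkage`` in [0, 1]), or ``diag``. Equal class priors (the design
    is balanced by construction).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n_samples, n_features) aligned with y")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite (no NaN/inf)")
    if regularizer not in _REG_MODES:
        raise ValueError(f"unknown regularizer {regularizer!r}; expected one of {_REG_MODES}")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"exactly 2 classes required, got {list(classes)}")
    n, p = X.shape
    masks = [y == c for c in classes]
    if any(m.sum() < 2 for m in masks):
        raise ValueError("each class needs at least 2 samples")
    mus = np.stack([X[m].mean(axis=0) for m in masks])
    d = mus[1] - mus[0]
    Xc = np.concatenate([X[m] - mu for m, mu in zip(masks, mus)])
    dof = n - 2

    if regularizer == "diag":
        var = (Xc**2).sum(axis=0) / dof
        w = np.where(var > 0, d / np.where(var > 0, var, 1.0), 0.0)
    elif regularizer == "shrinkage":
        if not 0.0 <= shrinkage <= 1.0:
            raise ValueError("shrinkage weight must be in [0, 1]")
        S = Xc.T @ Xc / dof
        target = np.trace(S) / p
        Sg = (1.0 - shrinkage) * S + shrinkage * target * np.eye(p)
        w = np.linalg.pinv(Sg, hermitian=True) @ d
    else:  # pseudo-inverse, computed in the low-rank basis when p > n
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        tol = s.max(initial=0.0) * max(n, p) * np.finfo(float).eps
        keep = s > tol
        if keep.any():
            # S = V diag(s^2/dof) V^T  =>  S^+ d = V diag(dof/s^2) V^T d
            proj = Vt[keep] @ d
            w = Vt[keep].T @ (proj * dof / s[keep] ** 2)
        else:
            # zero within-class scatter: fall back to the mean-difference direction
            w = d.copy()

    b = -0.5 * float(w @ (mus[0] + mus[1]))  # equal priors
    return LdaModel(
        classes=tuple(classes),
        class_means=mus,
        w=w,
        b=b,
        regularizer=regularizer,
        shrinkage=shrinkage,
    )


@dataclass(frozen=True)
class CvResult:
    """Per-repetition cross-validated accuracies with summary statistics."""

    accuracies: np.ndarray
    condition: str = "intact"
    subset: str = "all/all"
    seed: int | None = None
    k: int = 10
    extra: dict = field(default_factory=dict, compare=False)

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sem(self) -> float:
        return float(self.accuracies.std(ddof=1) / np.sqrt(len(self.accuracies)))

    def t_vs_chance(self, chance: float = 0.5) -> tuple[float, float]:
        return one_sample_t(self.accuracies, chance)


def stratified_folds(y: Sequence, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random stratified fold assignment: per class, shuffled round-robin."""
    y = np.asarray(y)
    folds = np.empty(len(y), dtype=int)
    start = int(rng.integers(k))
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        folds[idx] = (np.arange(len(idx)) + start) % k
    return folds


def _cv_once(
    X: np.ndarray, y: np.ndarray, folds: np.ndarray, k: int, regularizer: str, shrinkage: float
) -> float:
    accs = []
    for f in range(k):
        test = folds == f
        if not test.any():
            continue
        model = fit_lda(X[~test], y[~test], regularizer=regularizer, shrinkage=shrinkage)
        accs.append(float(np.mean(model.predict(X[test]) == y[test])))
    return float(np.mean(accs))


def repeated_cv(
    X: np.ndarray,
    y: Sequence,
    k: int = 10,
    reps: int = 100,
    seed: int | None = None,
    regularizer: str = "pseudo",
    shrinkage: float = 0.0,
    condition: str = "intact",
    subset: str = "all/all",
    shuffle_per_rep: bool = False,
) -> CvResult:
    """Repeated stratified k-fold cross-validation of the LDA.

    Each repetition uses a fresh random stratified partition; accuracy per
    repetition is the unweighted mean over folds of the held-out fraction
    correct. Fully reproducible from ``seed``; partitions depend only on
    (seed, y), never on the features.

    ``shuffle_per_rep=True`` turns the run into a permutation null: each
    repetition first permutes the label vector with its own substream (a
    fresh session shuffle per model), so the mean converges on chance
    rather than on the idiosyncrasy of a single permutation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        import warnings

        warnings.warn(
            f"class counts {dict(counts)} below k={k}; some folds will miss a class",
            stacklevel=2,
        )
    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(reps)]
    accs = []
    for r in rngs:
        y_rep = session_shuffle(y, r) if shuffle_per_rep else y
        accs.append(_cv_once(X, y_rep, stratified_folds(y_rep, k, r), k, regularizer, shrinkage))
    return CvResult(
        accuracies=np.array(accs), condition=condition, subset=subset, seed=seed, k=k
    )


def session_shuffle(y: Sequence, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random permutation of the label vector (counts preserved)."""
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("labels must be non-empty")
    return y[rng.permutation(len(y))]


def temporal_shuffle(arrays: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-session random permutation of frame columns, joint across behaviors.

    ``arrays`` must be unflattened (n_sessions, n_behaviors, 87); one
    permutation per session is applied to all behavior rows at once, so
    per-behavior totals (row sums) are invariant and per-frame mutual
    exclusivity is preserved.
    """
    arrays = np.asarray(arrays)
    if arrays.ndim != 3:
        raise ValueError(
            "temporal shuffle needs unflattened (n_sessions, behaviors, frames) "
            f"arrays, got shape {arrays.shape}"
        )
    n_frames = arrays.shape[-1]
    out = arrays.copy()
    for i in range(len(out)):
        out[i] = out[i][:, rng.permutation(n_frames)]
    return out


def subset_arrays(
    arrays: np.ndarray, period: str = "all", categories: str = "all"
) -> np.ndarray:
    """Unflattened (n, behaviors, frames) restriction of the session arrays.

    ``categories`` is ``all`` or one of Immobile / Horizontal / Vertical /
    Reward; ``groom`` belongs to no category and so never survives a
    category subset.
    """
    arrays = np.asarray(arrays, dtype=float)
    if arrays.ndim != 3 or arrays.shape[1:] != (len(BEHAVIORS), N_FRAMES):
        raise ValueError(f"expected (n, 12, {N_FRAMES}) arrays, got {arrays.shape}")
    if period not in PERIODS:
        raise ValueError(f"unknown period {period!r}")
    if categories == "all":
        rows = list(range(len(BEHAVIORS)))
    elif categories in CATEGORIES:
        rows = [BEHAVIORS.index(b) for b in CATEGORIES[categories]]
    else:
        raise ValueError(f"unknown category {categories!r}; expected all or {sorted(CATEGORIES)}")
    sub = arrays[:, rows, :][:, :, period_slice(period)]
    if sub.size == 0:
        raise ValueError("empty feature subset")
    return sub


def subset_features(
    arrays: np.ndarray, period: str = "all", categories: str = "all"
) -> np.ndarray:
    """Flattened (behavior-major) feature matrix for a period/category subset.

    Feature counts: all/all 1044, Immobile-cue 2 x 50 = 100, Vertical-post
    5 x 12 = 60, etc.
    """
    sub = subset_arrays(arrays, period=period, categories=categories)
    return sub.reshape(len(sub), -1)


#: Default analysis grid: condition x period for the full behavior set
#: (session shuffle for the full-trial cell), plus the four category
#: subsets at cue and post.
DEFAULT_GRID: tuple[tuple[str, str, str], ...] = tuple(
    [("intact", per, "all") for per in ("all", "baseline", "cue", "post")]
    + [("session_shuffled", "all", "all")]
    + [("temporal_shuffled", per, "all") for per in ("all", "baseline", "cue", "post")]
    + [("intact", per, cat) for per in ("cue", "post") for cat in CATEGORIES]
)


def run_full_analysis(
    arrays: np.ndarray,
    y: Sequence,
    seed: int | None = None,
    reps: int = 100,
    k: int = 10,
    regularizer: str = "pseudo",
    grid: Sequence[tuple[str, str, str]] = DEFAULT_GRID,
) -> tuple[pd.DataFrame, list[CvResult]]:
    """Run the full condition x period x category classification grid.

    Returns a summary table (one row per cell: mean, sem, t and p vs the
    50% chance level) plus the underlying :class:`CvResult` objects.
    """
    y = np.asarray(y)
    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.spawn(len(grid))
    cv_seed_root = int(ss.generate_state(1)[0] % (2**31))

    results: list[CvResult] = []
    rows = []
    for (condition, period, cat), cell_ss in zip(grid, cell_seeds):
        sub = subset_arrays(arrays, period=period, categories=cat)
        if condition == "temporal_shuffled":
            # shuffle within the analyzed window so the period cell tests
            # loss of temporal structure, not leakage from other periods
            sub = temporal_shuffle(sub, np.random.default_rng(cell_ss))
        X = sub.reshape(len(sub), -1)
        res = repeated_cv(
            X,
            y,
            k=k,
            reps=reps,
            seed=cv_seed_root,
            regularizer=regularizer,
            condition=condition,
            subset=f"{period}/{cat}",
            shuffle_per_rep=(condition == "session_shuffled"),
        )
        results.append(res)
        t, p = res.t_vs_chance()
        rows.append((condition, period, cat, res.mean, res.sem, t, p, X.shape[1]))
    summary = pd.DataFrame(
        rows,
        columns=["condition", "period", "category", "mean_accuracy", "sem", "t_vs_chance", "p", "n_features"],
    )
    return summary, results


def accuracies_long(results: Sequence[CvResult]) -> pd.DataFrame:
    """Long-format per-repetition accuracies for archiving."""
    rows = []
    for res in results:
        period, cat = res.subset.split("/")
        for rep, acc in enumerate(res.accuracies):
            rows.append((res.condition, period, cat, rep, float(acc)))
    return pd.DataFrame(rows, columns=["condition", "period", "category", "repetition", "accuracy"])
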