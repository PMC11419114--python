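"""Univariate statistical battery for ethogram and suppression data.

Implements the tests exactly as classically defined — pooled-variance
(Student) two-sample t, one-sample t, and the balanced split-plot
(mixed-design) ANOVA by sums-of-squares decomposition — with scipy used
only for the t and F reference distributions. Per-window group comparisons
tile the 87-frame trial into 1-s (5-frame) windows; the trailing 2-frame
window (frames 86-87) is retained and flagged.

Zero-variance conventions (documented, deterministic):
  * two groups / one sample with zero variance and equal means -> t = 0, p = 1
  * zero variance but unequal means -> p = 0 (with a warning for one-sample)
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .behaviors import ALL_LABELS, N_FRAMES
from .errors import DesignError
from .model import TrialFrames

#: 1-s analysis windows as 1-based inclusive frame ranges: seventeen full
#: 5-frame windows (1-5 ... 81-85) plus the trailing 2-frame window 86-87.
WINDOWS: tuple[tuple[int, int], ...] = tuple(
    (s, min(s + 4, N_FRAMES)) for s in range(1, N_FRAMES + 1, 5)
)


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed pooled-variance (Student) t-test; returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        return (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
    t = diff / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def one_sample_t(values: Sequence[float], mu: float) -> tuple[float, float]:
    """Two-tailed one-sample t-test against ``mu``; returns (t, p)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("one-sample t-test needs at least 2 values")
    sd = x.std(ddof=1)
    diff = x.mean() - mu
    if sd == 0:
        if diff == 0:
            return 0.0, 1.0
        warnings.warn("zero variance with mean != mu; p set to 0", stacklevel=2)
        return float(np.inf * np.sign(diff)), 0.0
    t = diff / (sd / np.sqrt(len(x)))
    p = 2.0 * sps.t.sf(abs(t), len(x) - 1)
    return float(t), float(p)


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not (isinstance(m, int) and m >= 1):
        raise ValueError(f"number of tests must be an integer >= 1, got {m!r}")
    return alpha / m


def per_rat_percent(
    trials: Iterable[TrialFrames], behavior: str, window: tuple[int, int]
) -> pd.DataFrame:
    """% behavior per rat over its trials x window frames.

    The unit of analysis is the rat: the mean over that rat's trials and
    the window's frames of the behavior indicator, x 100.
    """
    if behavior not in ALL_LABELS:
        raise ValueError(f"unknown behavior {behavior!r}")
    lo, hi = window
    if not (1 <= lo <= hi <= N_FRAMES):
        raise ValueError(f"window {window} outside frames 1..{N_FRAMES}")
    rows: dict[str, list] = {}
    for t in trials:
        frac = np.mean([lab == behavior for lab in t.labels[lo - 1 : hi]])
        rows.setdefault(t.rat_id, [t.group, []])[1].append(frac)
    return pd.DataFrame(
        [(rat, grp, 100.0 * float(np.mean(v))) for rat, (grp, v) in sorted(rows.items())],
        columns=["rat_id", "group", "percent"],
    )


def window_ttests(
    trials: Sequence[TrialFrames], behavior: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Independent-samples t-test per 1-s window for one behavior.

    Returns one row per window with ``t, p, direction`` where direction is
    ``paired_greater`` / ``unpaired_greater`` when p < alpha, else
    ``none``; ``partial_window`` flags the trailing 2-frame window.
    """
    trials = list(trials)
    groups = {t.group for t in trials}
    if groups != {"paired", "unpaired"}:
        raise ValueError(f"both groups must be present, got {sorted(groups)}")
    out = []
    for lo, hi in WINDOWS:
        per_rat = per_rat_percent(trials, behavior, (lo, hi))
        a = per_rat.loc[per_rat["group"] == "paired", "percent"].to_numpy()
        b = per_rat.loc[per_rat["group"] == "unpaired", "percent"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 rats per group")
        t, p = two_sample_t(a, b)
        if p < alpha:
            direction = "paired_greater" if a.mean() > b.mean() else "unpaired_greater"
        else:
            direction = "none"
        out.append((behavior, lo, hi, t, p, direction, hi - lo + 1 < 5))
    return pd.DataFrame(
        out,
        columns=["behavior", "window_start", "window_end", "t", "p", "direction", "partial_window"],
    )


# ---------------------------------------------------------------------------
# Balanced split-plot (mixed-design) ANOVA
# ---------------------------------------------------------------------------


def split_plot_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: Sequence[str],
) -> pd.DataFrame:
    """Classical sums-of-squares ANOVA for a fully balanced split-plot design.

    One within-subject factor and up to three crossed between-subject
    factors; subjects are nested in the between cells. Between effects are
    tested against the subjects-within-groups error, effects involving the
    within factor against the subject x within residual. No sphericity
    correction is applied.

    Raises :class:`DesignError` on any unbalance (no approximation is
    attempted).
    """
    between = list(between)
    if not 1 <= len(between) <= 3:
        raise DesignError("between factors must number 1..3")
    cols = [dv, within, subject, *between]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise DesignError(f"data is missing column(s) {missing}")
    df = data[cols].copy()

    levels = {f: sorted(df[f].unique()) for f in [within, *between]}
    n_subj = df[subject].nunique()
    w = len(levels[within])

    # Balance: every subject observed once per within level; subject maps to
    # exactly one between cell; equal subjects per cell.
    counts = df.groupby([subject, within], sort=False).size()
    if len(df) != n_subj * w or (counts != 1).any():
        raise DesignError("unbalanced design: each subject needs exactly one observation per within level")
    cell_of_subject = df.groupby(subject)[between].nunique()
    if (cell_of_subject != 1).any().any():
        raise DesignError("each subject must belong to exactly one between-factor cell")
    per_cell = df.drop_duplicates(subject).groupby(between).size()
    if per_cell.nunique() != 1 or len(per_cell) != int(np.prod([len(levels[f]) for f in between])):
        raise DesignError("unbalanced design: unequal subject counts across between cells")

    y = df[dv].to_numpy(dtype=float)
    grand = y.mean()
    n_total = len(df)

    def R(cols_subset: tuple[str, ...]) -> float:
        """Sum over observations of the squared mean of the observation's cell."""
        if not cols_subset:
            return n_total * grand**2
        means = df.groupby(list(cols_subset))[dv].transform("mean").to_numpy()
        return float((means**2).sum())

    factors = [*between, within]
    effects = [
        combo
        for r in range(1, len(factors) + 1)
        for combo in combinations(factors, r)
    ]
    ss = {}
    for eff in effects:
        total = 0.0
        for r in range(len(eff) + 1):
            for sub in combinations(eff, r):
                total += (-1) ** (len(eff) - len(sub)) * R(sub)
        ss[eff] = max(total, 0.0)  # guard tiny negative rounding

    ss_subj = max(R((subject,)) - R(tuple(between)), 0.0)
    ss_total = float(((y - grand) ** 2).sum())
    ss_model = sum(ss.values()) + ss_subj
    ss_resid = max(ss_total - ss_model, 0.0)

    n_cells = int(np.prod([len(levels[f]) for f in between]))
    df_subj = n_subj - n_cells
    df_resid = (w - 1) * df_subj

    def effect_df(eff: tuple[str, ...]) -> int:
        return int(np.prod([len(levels[f]) - 1 for f in eff]))

    rows = []
    for eff in effects:
        d1 = effect_df(eff)
        if within in eff:
            err_ss, err_df, err_name = ss_resid, df_resid, "within-residual"
        else:
            err_ss, err_df, err_name = ss_subj, df_subj, "subjects-within-groups"
        ms = ss[eff] / d1 if d1 else 0.0
        mse = err_ss / err_df if err_df else 0.0
        if mse == 0:
            F, p = (0.0, 1.0) if ms == 0 else (np.inf, 0.0)
        else:
            F = ms / mse
            p = float(sps.f.sf(F, d1, err_df))
        rows.append((" x ".join(eff), float(ss[eff]), d1, err_df, float(F), p, err_name))
    rows.append(("subjects-within-groups", float(ss_subj), df_subj, 0, np.nan, np.nan, ""))
    rows.append(("residual", float(ss_resid), df_resid, 0, np.nan, np.nan, ""))

    table = pd.DataFrame(
        rows, columns=["effect", "SS", "df_num", "df_den", "F", "p", "error_term"]
    )
    # balanced decomposition must account for the total SS
    if not np.isclose(table["SS"].sum(), ss_total, rtol=1e-9, atol=1e-9):
        raise DesignError("sums of squares failed to decompose; design not balanced")
    return table
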