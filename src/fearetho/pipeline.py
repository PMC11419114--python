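"""End-to-end orchestration: simulate -> ethogram -> suppression ->
reliability -> stats -> classify, with provenance.

``run_all`` drives every stage from a :class:`~fearetho.simulate.SimConfig`
and writes plain-CSV outputs plus a provenance record (config echo, seed,
package version) into a run directory. Given the same seed and config the
outputs are byte-identical; inputs are never mutated.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .behaviors import BEHAVIORS
from .classify import accuracies_long, run_full_analysis
from .ethogram import feature_table, session_arrays, stack_sessions
from .io import write_event_log, write_frame_labels
from .reliability import confusion, reliability_report
from .simulate import Dataset, SimConfig, simulate_comparison_trials, simulate_experiment
from .stats import split_plot_anova, window_ttests
from .suppression import session_mean, suppression_table


def run_all(
    out_dir: str | Path,
    config: SimConfig | None = None,
    reps: int = 100,
    alpha: float = 0.05,
) -> dict[str, Path]:
    """Run every analysis stage on one synthetic experiment.

    Returns a name -> path map of everything written. The run directory is
    write-once: an existing non-empty directory raises.
    """
    config = config or SimConfig()
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        raise FileExistsError(f"refusing to write into non-empty run directory {out}")
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    dataset: Dataset = simulate_experiment(config)

    paths["frame_labels"] = out / "frame_labels.csv"
    write_frame_labels(dataset.trials, paths["frame_labels"])
    events_dir = out / "events"
    events_dir.mkdir()
    for log in dataset.event_logs:
        write_event_log(log, events_dir / f"{log.rat_id}_{log.session_id}.csv")
    paths["events_dir"] = events_dir

    # --- suppression -------------------------------------------------------
    records = suppression_table(dataset.event_logs)
    paths["suppression"] = out / "suppression.csv"
    records.to_csv(paths["suppression"], index=False)
    summary = (
        records.groupby(["rat_id", "session_id", "group"], as_index=False)
        .apply(lambda g: pd.Series({"mean_ratio": session_mean(g)}), include_groups=False)
    )
    paths["suppression_summary"] = out / "suppression_summary.csv"
    summary.to_csv(paths["suppression_summary"], index=False)

    # split-plot ANOVA over trials within the conditioning session
    cond = records[records["session_id"] == "s1"].dropna(subset=["ratio"])
    anova_in = cond.rename(columns={"trial_index": "trial"})
    if anova_in.groupby(["rat_id", "trial"]).size().eq(1).all():
        table = split_plot_anova(
            anova_in, dv="ratio", within="trial", subject="rat_id",
            between=["group", "sex", "intensity_mA"],
        )
        paths["anova_suppression"] = out / "anova_suppression.csv"
        table.to_csv(paths["anova_suppression"], index=False)

    # --- ethogram features -------------------------------------------------
    eths = session_arrays(dataset.trials)
    paths["features"] = out / "features.csv"
    feature_table(eths).to_csv(paths["features"], index=False)

    # --- per-window group tests (conditioning session) ---------------------
    cond_trials = [t for t in dataset.trials if t.session_type == "conditioning"]
    tests = pd.concat(
        [window_ttests(cond_trials, b, alpha=alpha) for b in BEHAVIORS],
        ignore_index=True,
    )
    paths["window_tests"] = out / "window_tests.csv"
    tests.to_csv(paths["window_tests"], index=False)

    # --- reliability on the comparison set ---------------------------------
    comparison = simulate_comparison_trials(config)
    report = reliability_report(comparison)
    paths["reliability_pairwise"] = out / "reliability_pairwise.csv"
    report.pairwise_frame().to_csv(paths["reliability_pairwise"])
    paths["reliability_by_n"] = out / "reliability_by_n.csv"
    pd.DataFrame(
        sorted(report.by_n_behaviors.items()), columns=["n_behaviors", "mean_percent"]
    ).to_csv(paths["reliability_by_n"], index=False)
    cm = confusion(comparison)
    paths["confusion_counts"] = out / "confusion_counts.csv"
    cm.to_frame().to_csv(paths["confusion_counts"])
    paths["confusion_row_percent"] = out / "confusion_row_percent.csv"
    cm.to_frame(percent=True).to_csv(paths["confusion_row_percent"])

    # --- classification grid -----------------------------------------------
    arrays, labels, _ = stack_sessions(eths)
    summary_cls, results = run_full_analysis(arrays, labels, seed=config.seed, reps=reps)
    paths["classification_summary"] = out / "classification_summary.csv"
    summary_cls.to_csv(paths["classification_summary"], index=False)
    paths["classification_accuracies"] = out / "classification_accuracies.csv"
    accuracies_long(results).to_csv(paths["classification_accuracies"], index=False)

    # --- provenance ---------------------------------------------------------
    paths["provenance"] = out / "provenance.json"
    paths["provenance"].write_text(
        json.dumps(
            {
                "package": "fearetho",
                "version": __version__,
                "seed": config.seed,
                "config": asdict(config),
                "reps": reps,
                "alpha": alpha,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return paths
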