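"""Classify learning status (paired vs unpaired) from session ethograms.

Runs repeated stratified 10-fold pseudo-inverse LDA on the 64 x 1044
feature table: intact data, the session-shuffle null, the temporal
shuffle, and two behavior-category subsets. Chance is 50%.
"""

import numpy as np

import fearetho as fe

dataset = fe.simulate_experiment(fe.SimConfig(seed=1))
arrays, labels, _ = fe.stack_sessions(fe.session_arrays(dataset.trials))

grid = [
    ("intact", "all", "all"),
    ("session_shuffled", "all", "all"),
    ("temporal_shuffled", "all", "all"),
    ("intact", "cue", "Immobile"),
    ("intact", "cue", "Reward"),
]
summary, _ = fe.run_full_analysis(arrays, labels, seed=7, reps=100, grid=grid)

print("mean +/- SEM held-out accuracy (100 models, 10-fold CV):")
for _, row in summary.iterrows():
    print(f"  {row['condition']:<18s} {row['period']:<9s} {row['category']:<9s} "
          f"{100 * row['mean_accuracy']:5.1f} +/- {100 * row['sem']:.1f}%   "
          f"(p vs chance = {row['p']:.2e})")

print("\nintact ethograms classify learning status far above chance; the")
print("session shuffle collapses to ~50% (no label information), while the")
print("temporal shuffle retains most accuracy: which behaviors occurred")
print("matters more than when they occurred.")
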