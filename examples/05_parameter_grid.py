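"""Sweep a parameter grid over a small cohort and aggregate the results.

A JSON-style grid spec with list-valued fields expands into individual
configurations (Cartesian product); each (input x configuration) task
writes a graph, a membership table, and a stats row under a deterministic
layout, independent of the parallel pool size.
"""

import tempfile
from pathlib import Path

import pandas as pd

from neuromapper import (CohortTable, GridConfig, aggregate_stats,
                         g_schedule, run_cohort, smooth_downsample,
                         synth_circular_bold)
from neuromapper.runner import pass_count_matrix

root = Path(tempfile.mkdtemp())
_, schedule = g_schedule()
for seed in (0, 1):
    data = smooth_downsample(synth_circular_bold(seed=seed), factor=3)
    data.to_tsv(root / f"subj{seed}.tsv", labels_path=root / f"subj{seed}_labels.tsv")
pd.DataFrame({"id": ["subj0", "subj1"],
              "path": ["subj0.tsv", "subj1.tsv"],
              "labels": ["subj0_labels.tsv", "subj1_labels.tsv"],
              "tr": [2.16, 2.16]}).to_csv(root / "cohort.csv", index=False)

grid = GridConfig({
    "dist": {"type": "geodesic_euclidean", "k": 12},
    "embed": {"type": "CMDS", "dims": 2},
    "bin": {"type": "cube", "resolution": [10, 20], "gain": [50, 70]},
    "cluster": {"type": "linkage", "bins": 10},
    "analyses": [{"type": "stats"}],
})
print(f"grid expands to {2 * 2} configurations x 2 inputs = 8 tasks")

run_cohort(CohortTable.from_csv(root / "cohort.csv"), grid,
           data_root=root, out_dir=root / "out", poolsize=1, master_seed=1)
stats = aggregate_stats(root / "out")
cols = ["input", "resolution", "gain", "alpha", "beta", "entropy",
        "valid", "circleness"]
print(stats[cols].round(2).to_string(index=False))
print("valid pass counts per resolution x gain:")
print(pass_count_matrix(stats, flag="valid"))
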