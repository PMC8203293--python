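#!/usr/bin/env python
"""Fit T-cell motility against mean tumor stiffness across the cohort.

Per-group and pooled ordinary least-squares fits of mean speed on mean
stiffness; an inverse relation (negative slope, negative Pearson r) is the
signature the chain is built to detect.  Writes
results/cohort/correlation_report.json.
"""

import argparse
import importlib

import pandas as pd

sim = importlib.import_module("01_simulate_cohort")
from mechanoscape.pipeline import run_pipeline  # noqa: E402
from mechanoscape.stats import stiffness_motility_fit  # noqa: E402

if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    run_pipeline(sim.cohort_config(args.seed, ["correlate"]))
    table = pd.read_csv(sim.RESULTS / "cohort" / "study_table.csv")
    for fit in stiffness_motility_fit(table, "mean_speed_um_per_min", by_group=False):
        print(
            f"pooled: slope {fit.slope:.3f} µm/min per kPa, "
            f"r = {fit.pearson_r:.3f} (n = {fit.n})"
        )
    for fit in stiffness_motility_fit(table, "mean_speed_um_per_min", by_group=True):
        print(f"{fit.group}: slope {fit.slope:.3f}, r = {fit.pearson_r:.3f} (n = {fit.n})")
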