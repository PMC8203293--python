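#!/usr/bin/env python
"""Quantify the simulated cohort and assemble the study table.

Reruns the stiffness-map summary and the track filter/motility chain on the
files written by 01_simulate_cohort.py, producing one row per subject
(mean stiffness, stiff-area fraction, mean speed/displacement/straightness)
in results/cohort/study_table.csv.
"""

import argparse
import importlib

import pandas as pd

sim = importlib.import_module("01_simulate_cohort")
from mechanoscape.pipeline import run_pipeline  # noqa: E402

if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    run_pipeline(sim.cohort_config(args.seed, ["quantify", "tabulate"]))
    table = pd.read_csv(sim.RESULTS / "cohort" / "study_table.csv")
    print(table.groupby("group")[["mean_stiffness_kPa", "stiff_fraction", "mean_speed_um_per_min"]].mean().round(3))
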