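#!/usr/bin/env python
"""Benchmark the Hertz-model fit on synthetic force curves.

Noiseless round trips across the soft-tissue modulus range and the mean
absolute recovery error under 5% multiplicative force noise (100 seeded
replicates at E = 2 kPa).  Writes results/afm_recovery.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mechanoscape import synthetic as syn
from mechanoscape.afm import fit_young_modulus

RESULTS = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    rows = []
    for E_kpa in (0.5, 1.0, 2.0, 5.0, 20.0):
        E = 1000 * E_kpa
        fitted = fit_young_modulus(syn.gen_force_curve(E))
        rows.append({"E_kPa": E_kpa, "noise": "none", "rel_err": abs(fitted - E) / E})
    noisy_err = [
        abs(fit_young_modulus(syn.gen_force_curve(2000.0, noise_frac=0.05, seed=args.seed + s)) - 2000.0)
        / 2000.0
        for s in range(100)
    ]
    rows.append({"E_kPa": 2.0, "noise": "5pct x 100", "rel_err": float(np.mean(noisy_err))})
    RESULTS.mkdir(exist_ok=True)
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "afm_recovery.csv", index=False)
    print(df.to_string(index=False))
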