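"""Pearson colocalization across the foci-phantom overlap sweep.

Generates two-channel foci stacks whose sub-structure overlap runs from
fully partitioned (0) to fully shared (1), 20 seeds each, and computes the
per-cell mean Pearson R inside the foci ROI masks.  The endpoints emulate
the partitioned (~0.45) and fully colocalized (~0.85) marker pairs of
organelle imaging.  Writes results/coloc_sweep.tsv.
"""

import pathlib

import numpy as np
import pandas as pd

from dynapquant.coloc import cell_colocalization
from dynapquant.simulate import FociSimConfig, simulate_foci_pair

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OVERLAPS = (0.0, 0.25, 0.5, 0.75, 1.0)
N_SEEDS = 20


def run() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for overlap in OVERLAPS:
        rs = []
        for seed in range(N_SEEDS):
            stack, masks, _ = simulate_foci_pair(
                FociSimConfig(overlap=overlap, seed=seed)
            )
            rs.append(cell_colocalization(stack, masks))
        rows.append(
            {"overlap": overlap, "mean_r": np.mean(rs), "sd_r": np.std(rs),
             "n_cells": N_SEEDS}
        )
        print(f"overlap={overlap:.2f}: mean per-cell R = {np.mean(rs):.3f} "
              f"(sd {np.std(rs):.3f}, n={N_SEEDS})")
    pd.DataFrame(rows).to_csv(OUT / "coloc_sweep.tsv", sep="\t", index=False,
                              float_format="%.6g")


if __name__ == "__main__":
    run()
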