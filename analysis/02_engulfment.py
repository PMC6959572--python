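#!/usr/bin/env python
"""Microglial engulfment analysis on synthetic cohorts.

Scores triple-channel engulfment (PSD-95 within Iba1 and CD68) for a
baseline arm and a 2.3-fold overexpression-like arm, runs the 12-um
pixel-shift chance-colocalization control on each ROI, and reports the
depth profile and layer-resolved density of the scored cells."""

from pathlib import Path

import numpy as np
import pandas as pd

from neuroquant.engulfment import (
    MicrogliaCell,
    depth_correlation,
    microglia_density,
    score_roi,
    shifted_null,
)
from neuroquant.imaging import binarize
from neuroquant.synth import EngulfmentSceneParams, generate_engulfment_stack

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(parents=True, exist_ok=True)

N_ROIS = 10  # per arm, reduced field size for a fast narrative run
ARMS = {"control": (0.3, 100), "overexpression": (0.69, 500)}

rows = []
all_cells = []
for arm, (rate, seed0) in ARMS.items():
    for i in range(N_ROIS):
        params = EngulfmentSceneParams(
            roi_size_um=(140, 160), n_microglia=10, engulfment_rate=rate,
            lysosomes_per_microglia=4.0, seed=seed0 + i,
        )
        stack, truth = generate_engulfment_stack(params)
        z = stack.shape_zyx[0] // 2
        thr = params.amplitude / 2  # pinned across arms: same settings
        psd = binarize(stack.channel("PSD95")[z], "fixed", thr).mask
        cd68 = binarize(stack.channel("CD68")[z], "fixed", thr).mask
        cells = [
            MicrogliaCell(cell_mask=m.cell_mask, cortical_depth_um=m.depth_um)
            for m in truth.microglia
        ]
        obs = score_roi(cells, psd, cd68, roi_id=f"{arm}_{i}")
        null = shifted_null(psd, cd68, cells, stack.geometry, n_rounds=5, seed=i)
        rows.append(
            {
                "arm": arm,
                "roi": i,
                "n_microglia": obs.n_microglia,
                "pct_positive": obs.pct_positive,
                "mean_engulf_area_pct": obs.mean_engulf_area_pct,
                "shifted_pct_positive": null["pct_positive"].mean(),
            }
        )
        all_cells.extend(cells)

df = pd.DataFrame(rows)
df.to_csv(OUT / "engulfment_rois.csv", index=False)

print("per-arm triple-positivity (mean over ROIs):")
summary = df.groupby("arm")[["pct_positive", "shifted_pct_positive"]].mean()
print(summary.round(2).to_string())
ratio = (
    summary.loc["overexpression", "pct_positive"] / summary.loc["control", "pct_positive"]
)
print(f"\narm ratio (overexpression / control): {ratio:.2f} (generator truth 2.3)")
print(
    f"pixel-shift null: {df['shifted_pct_positive'].mean():.2f}% positive "
    "(chance-colocalization bound: under 3%)"
)

dens = microglia_density(
    all_cells, {"L1": 120 * 140 * 1.0, "L2/3": 40 * 140 * 1.0}
)
print("\nlayer density (cells per um^3 of the demo slab):")
print(dens.round(8).to_string(index=False))
dens.to_csv(OUT / "engulfment_density.csv", index=False)

# depth profile over the engulfment-positive cells of both arms
positive = [c for c in all_cells if c.metrics.get("engulf_positive")]
if len(positive) >= 3:
    res = depth_correlation(positive, max_depth_um=160.0)
    print(
        f"\ndepth correlation over {res['n']} positive cells: "
        f"r = {res['r']:.2f}, p = {res['p']:.3f}"
    )
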