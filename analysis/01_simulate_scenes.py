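#!/usr/bin/env python
"""Generate one example of each synthetic dataset and write it under
results/synth/ with its ground truth, as a worked demonstration of the
generators that drive every downstream analysis."""

import json
from pathlib import Path

from neuroquant import io
from neuroquant.behavior import ArenaConfig
from neuroquant.synth import (
    EngulfmentSceneParams,
    generate_engulfment_stack,
    generate_mpsc_trace,
    generate_spine_image,
    generate_test_pulse,
    generate_trajectory,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "synth"
OUT.mkdir(parents=True, exist_ok=True)

# confocal engulfment ROI at a reduced field size for the demo
params = EngulfmentSceneParams(roi_size_um=(140, 160), n_microglia=10, seed=1)
stack, truth = generate_engulfment_stack(params)
io.write_ome_tiff(stack, OUT / "engulfment_roi.ome.tif")
(OUT / "engulfment_roi.truth.json").write_text(
    json.dumps(
        {
            "n_microglia": len(truth.microglia),
            "n_engulfment_positive": truth.n_engulfment_positive,
            "n_puncta": int(len(truth.puncta)),
        },
        indent=1,
    )
)
print(
    f"engulfment ROI: {len(truth.microglia)} microglia, "
    f"{truth.n_engulfment_positive} engulfment-positive, {len(truth.puncta)} PSD puncta"
)

spine_stack, spine_truth = generate_spine_image(30, seed=2)
io.write_ome_tiff(spine_stack, OUT / "dendrite.ome.tif")
spine_truth.records.to_csv(OUT / "dendrite.truth.csv", index=False)
print(f"dendrite: {len(spine_truth.records)} protrusions on a "
      f"{spine_truth.analyzed_length_um:.0f} um shaft")

trace, ev_truth = generate_mpsc_trace(5.0, duration_s=30, seed=3)
io.write_trace_h5(trace, OUT / "mpsc_trace.h5")
ev_truth.to_csv(OUT / "mpsc_trace.truth.csv", index=False)
print(f"mPSC trace: {len(ev_truth)} events in {trace.duration_s:.0f} s")

pulse = generate_test_pulse(Rs_MOhm=10, Rm_MOhm=150, Cm_pF=100, noise_sd_pA=2.0, seed=4)
io.write_trace_h5(pulse, OUT / "seal_test.h5")
print("seal test: -5 mV pulse, Rs 10 MOhm / Rm 150 MOhm / Cm 100 pF ground truth")

arena = ArenaConfig.square(
    50,
    zones={
        "dam_cup": {"center": [12.5, 12.5], "radius": 10.0},
        "empty_cup": {"center": [37.5, 37.5], "radius": 10.0},
    },
)
traj, occ = generate_trajectory(arena, {"dam_cup": 3.0}, duration_s=120, seed=5)
traj.to_csv(OUT / "trajectory.csv")
print(f"trajectory: occupancy {({k: round(v, 1) for k, v in occ.items()})}")
print(f"\nwrote example datasets to {OUT}")
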