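"""Synthetic arena trajectories with programmed zone preferences."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..behavior import ArenaConfig, Trajectory

__all__ = ["generate_trajectory"]


def generate_trajectory(
    arena: ArenaConfig,
    zone_preference: dict[str, float] | None = None,
    duration_s: float = 300.0,
    fps: float | None = None,
    step_sd_cm: float = 1.0,
    seed: int = 0,
    start_xy: tuple[float, float] | None = None,
    baseline_weight: float = 1.0,
) -> tuple[Trajectory, dict[str, float]]:
    """Biased random walk confined to the arena.

    A Metropolis scheme: Gaussian steps are proposed and accepted with
    probability min(1, w_new/w_cur), where a position's weight is the
    preference of the zone containing it (``baseline_weight`` outside all
    zones).  Uniform weights give a symmetric confined walk.  Returns the
    trajectory and the true per-zone occupancy time computed from the
    generated positions with the same point-in-zone rule the analysis
    uses.
    """
    if zone_preference is None:
        zone_preference = {}
    for name in zone_preference:
        if name not in arena.zones:
            raise ValueError(f"preference names unknown zone {name!r}")
    if any(w < 0 for w in zone_preference.values()):
        raise ValueError("zone preference weights must be non-negative")
    fps = fps or arena.fps
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))

    minx, miny, maxx, maxy = arena.arena.bounds
    if start_xy is None:
        x, y = (minx + maxx) / 2.0, (miny + maxy) / 2.0
    else:
        x, y = start_xy

    def weight(px: float, py: float) -> float:
        z = arena.zone_at(px, py)
        return zone_preference.get(z, baseline_weight) if z else baseline_weight

    w_cur = weight(x, y)
    xs = np.empty(n)
    ys = np.empty(n)
    occupancy: dict[str, float] = {name: 0.0 for name in arena.zones}
    dt = 1.0 / fps
    from shapely.geometry import Point

    for i in range(n):
        for _try in range(10):
            nx_, ny_ = x + rng.normal(0, step_sd_cm), y + rng.normal(0, step_sd_cm)
            if not arena.arena.covers(Point(nx_, ny_)):
                continue
            w_new = weight(nx_, ny_)
            if w_cur <= 0 or rng.uniform() < min(1.0, w_new / w_cur if w_cur > 0 else 1.0):
                x, y, w_cur = nx_, ny_, w_new
                break
        xs[i], ys[i] = x, y
        z = arena.zone_at(x, y)
        if z is not None:
            occupancy[z] += dt

    frames = pd.DataFrame(
        {"frame": np.arange(n), "t_s": np.arange(n) * dt, "x_cm": xs, "y_cm": ys}
    )
    return Trajectory(frames=frames, source={"generator": "biased_walk", "seed": seed}), occupancy
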