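"""Behavioral trajectory metrics and section cell-count interpolation.

Converts centroid trajectories into zone-occupancy times, discrimination
indices, approach latencies/first choice, and kinematics; summarizes
manually annotated grooming intervals; and estimates total transfected
cell counts from every-other-section counts by linear interpolation
against Bregma coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Point, Polygon, box

__all__ = [
    "ArenaConfig",
    "Trajectory",
    "zone_occupancy",
    "discrimination_index",
    "approach_metrics",
    "kinematics",
    "grooming_summary",
    "interpolate_cell_counts",
]


def _zone_geometry(spec: dict):
    """Build a shapely geometry from a zone spec: either a polygon
    (list of [x, y] vertices) or a disc ({center: [x, y], radius: r})."""
    if "polygon" in spec:
        return Polygon(spec["polygon"])
    if "center" in spec:
        cx, cy = spec["center"]
        return Point(cx, cy).buffer(float(spec["radius"]), quad_segs=32)
    raise ValueError("zone spec needs 'polygon' or 'center'+'radius'")


@dataclass
class ArenaConfig:
    """Arena geometry (cm) with named zones and the video frame rate."""

    arena: Polygon
    zones: dict[str, object] = field(default_factory=dict)
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        for name, geom in self.zones.items():
            if not self.arena.buffer(1e-9).covers(geom):
                raise ValueError(f"zone {name!r} is not inside the arena")

    @classmethod
    def square(cls, side_cm: float = 50.0, zones: dict | None = None, fps: float = 30.0):
        """Square open-field arena (default 50 x 50 cm) with optional zone specs."""
        geoms = {k: _zone_geometry(v) for k, v in (zones or {}).items()}
        return cls(arena=box(0, 0, side_cm, side_cm), zones=geoms, fps=fps)

    @classmethod
    def from_yaml(cls, path) -> "ArenaConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        arena = Polygon(cfg["arena"]["polygon"]) if "polygon" in cfg["arena"] else box(
            0, 0, cfg["arena"]["side_cm"], cfg["arena"]["side_cm"]
        )
        zones = {k: _zone_geometry(v) for k, v in cfg.get("zones", {}).items()}
        return cls(arena=arena, zones=zones, fps=float(cfg.get("fps", 30.0)))

    def zone_at(self, x: float, y: float) -> str | None:
        p = Point(x, y)
        for name, geom in self.zones.items():
            if geom.covers(p):  # boundary counts as inside
                return name
        return None

    def check_disjoint(self) -> None:
        names = list(self.zones)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                inter = self.zones[a].intersection(self.zones[b])
                if inter.area > 1e-9:
                    raise ValueError(f"zones {a!r} and {b!r} overlap")


@dataclass
class Trajectory:
    """Time-stamped centroid path. frames: DataFrame(frame, t_s, x_cm, y_cm)."""

    frames: pd.DataFrame
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"frame", "t_s", "x_cm", "y_cm"}
        if not need.issubset(self.frames.columns):
            raise ValueError(f"frames must have columns {sorted(need)}")
        t = self.frames["t_s"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("t_s must be strictly increasing")

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(frames=df, source={"path": str(path)})

    def to_csv(self, path) -> None:
        self.frames.to_csv(path, index=False)

    @property
    def duration_s(self) -> float:
        t = self.frames["t_s"].to_numpy()
        if len(t) < 2:
            return 0.0
        # include the final frame's dwell at the median frame interval
        return float(t[-1] - t[0] + np.median(np.diff(t)))


def _frame_zones(traj: Trajectory, arena: ArenaConfig) -> list[str | None]:
    xs = traj.frames["x_cm"].to_numpy()
    ys = traj.frames["y_cm"].to_numpy()
    return [arena.zone_at(x, y) for x, y in zip(xs, ys)]


def zone_occupancy(traj: Trajectory, arena: ArenaConfig) -> pd.DataFrame:
    """Per-zone dwell time (s) and proportion of session duration.

    A frame belongs to a zone iff the centroid is inside (boundary
    inclusive); each frame contributes one frame interval of dwell.
    Overlapping zones are a configuration error.
    """
    arena.check_disjoint()
    zones = _frame_zones(traj, arena)
    t = traj.frames["t_s"].to_numpy()
    if len(t) < 1:
        raise ValueError("empty trajectory")
    dt = np.median(np.diff(t)) if len(t) > 1 else 1.0 / arena.fps
    total = traj.duration_s if len(t) > 1 else dt
    rows = []
    for name in arena.zones:
        tz = sum(dt for z in zones if z == name)
        rows.append({"zone": name, "time_s": tz, "proportion": tz / total})
    return pd.DataFrame(rows)


def discrimination_index(t_target_s: float, t_other_s: float) -> float:
    """DI = (target - other) / (target + other), in [-1, 1]."""
    if t_target_s < 0 or t_other_s < 0:
        raise ValueError("times must be non-negative")
    total = t_target_s + t_other_s
    if total == 0:
        return float("nan")
    return (t_target_s - t_other_s) / total


def approach_metrics(
    traj: Trajectory, arena: ArenaConfig, zones_of_interest: list[str]
) -> dict:
    """First-entry latency per zone (s from session start) and first choice.

    Latency is missing (NaN) for zones never entered; the first choice is
    the zone entered earliest.
    """
    zones = _frame_zones(traj, arena)
    t = traj.frames["t_s"].to_numpy()
    t0 = t[0] if len(t) else 0.0
    latency: dict[str, float] = {}
    for name in zones_of_interest:
        if name not in arena.zones:
            raise ValueError(f"unknown zone {name!r}")
        hits = [i for i, z in enumerate(zones) if z == name]
        latency[name] = float(t[hits[0]] - t0) if hits else float("nan")
    entered = {k: v for k, v in latency.items() if np.isfinite(v)}
    first_choice = min(entered, key=entered.get) if entered else None
    return {"latency_s": latency, "first_choice": first_choice}


def kinematics(traj: Trajectory, smooth_window_frames: int = 5) -> dict:
    """Max/mean velocity (cm/s) and total path length (cm).

    The path is boxcar-smoothed before centered finite differences, which
    keeps tracking jitter from inflating the maximum velocity.
    """
    df = traj.frames
    if len(df) < 2:
        raise ValueError("need at least 2 frames")
    x = df["x_cm"].to_numpy(float)
    y = df["y_cm"].to_numpy(float)
    t = df["t_s"].to_numpy(float)
    w = max(int(smooth_window_frames), 1)
    if w > 1 and len(x) >= w:
        kernel = np.ones(w) / w
        pad = w // 2
        xs = np.convolve(np.pad(x, pad, mode="edge"), kernel, mode="valid")[: len(x)]
        ys = np.convolve(np.pad(y, pad, mode="edge"), kernel, mode="valid")[: len(y)]
    else:
        xs, ys = x, y
    vx = np.gradient(xs, t)
    vy = np.gradient(ys, t)
    speed = np.hypot(vx, vy)
    dist = float(np.sum(np.hypot(np.diff(xs), np.diff(ys))))
    return {
        "max_velocity_cm_s": float(speed.max()),
        "mean_velocity_cm_s": float(speed.mean()),
        "total_distance_cm": dist,
    }


def grooming_summary(intervals: list[tuple[float, float]]) -> dict:
    """Count, mean duration and total time of non-overlapping grooming bouts."""
    ivs = sorted(intervals)
    for (s0, e0), (s1, _e1) in zip(ivs, ivs[1:]):
        if s1 < e0:
            raise ValueError("grooming intervals overlap")
    durs = [e - s for s, e in ivs]
    if any(d < 0 for d in durs):
        raise ValueError("interval end precedes start")
    return {
        "occurrences": len(ivs),
        "mean_duration_s": float(np.mean(durs)) if durs else float("nan"),
        "total_time_s": float(np.sum(durs)) if durs else 0.0,
    }


def interpolate_cell_counts(
    sections: list[tuple[float, float]],
    missing_bregma_mm: list[float] | None = None,
    section_step_mm: float | None = None,
) -> pd.DataFrame:
    """Estimate uncounted sections' cell counts by linear interpolation
    against Bregma coordinate.

    ``sections`` lists counted (bregma_mm, count) pairs, rostral to caudal
    (strictly decreasing Bregma).  Missing-section positions are either
    given explicitly or derived as the midpoints of consecutive counted
    sections (the every-other-section counting scheme).  Positions outside
    the counted range are refused (no extrapolation).  The returned table
    has the counted and interpolated sections with an ``estimated`` flag;
    the total is ``df['count'].sum()``.
    """
    if len(sections) < 2:
        raise ValueError("need at least 2 counted sections")
    bregma = np.array([b for b, _ in sections], dtype=float)
    counts = np.array([c for _, c in sections], dtype=float)
    if not np.all(np.diff(bregma) < 0):
        raise ValueError("bregma must be strictly decreasing (rostral to caudal)")
    if missing_bregma_mm is None:
        missing_bregma_mm = list((bregma[:-1] + bregma[1:]) / 2.0)
    for m in missing_bregma_mm:
        if m > bregma[0] or m < bregma[-1]:
            raise ValueError(f"section at Bregma {m} mm outside counted range; refusing to extrapolate")
    # np.interp wants ascending x
    est = np.interp(missing_bregma_mm, bregma[::-1], counts[::-1])
    df = pd.concat(
        [
            pd.DataFrame({"bregma_mm": bregma, "count": counts, "estimated": False}),
            pd.DataFrame({"bregma_mm": missing_bregma_mm, "count": est, "estimated": True}),
        ],
        ignore_index=True,
    ).sort_values("bregma_mm", ascending=False, ignore_index=True)
    return df
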