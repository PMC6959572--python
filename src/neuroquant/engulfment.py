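"""Microglial engulfment scoring.

Single-z-plane colocalization of neuronal material with microglia, the
triple-channel (PSD-95 within Iba1 and CD68) engulfment criterion, the
random pixel-shift chance-colocalization null, the engulfment-vs-depth
correlation, layer-resolved microglia density, and CD68 reactivity.

A microglia counts as engulfment-positive when at least one connected
region of the PSD-95 / CD68 / cell-mask triple intersection reaches the
minimum punctum size (3 pixels by default).  The null control translates
each stained channel independently by a fixed physical distance (12 um)
in a random cardinal direction and rescores against the unmoved cell
masks; genuine engulfment collapses under this decorrelation while
chance overlap survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .imaging import BinaryMask, PixelGeometry, connected_regions, pixel_shift

__all__ = [
    "MicrogliaCell",
    "RoiSummary",
    "colocalization_fraction",
    "triple_engulfment",
    "shifted_null",
    "depth_correlation",
    "microglia_density",
    "cd68_reactivity",
    "score_roi",
]

DEFAULT_SHIFT_UM = 12.0
DEFAULT_MIN_PIXELS = 3
LAYER_BINS_UM = {"L1": (0.0, 120.0), "L2/3": (120.0, 300.0)}


@dataclass
class MicrogliaCell:
    """One microglia analyzed in a single z-plane."""

    cell_mask: np.ndarray  # (y, x) bool
    soma_yx_um: tuple[float, float] = (np.nan, np.nan)
    cortical_depth_um: float = np.nan
    z_plane: int = 0
    metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        if not self.cell_mask.any():
            raise ValueError("cell mask is empty")
        if np.isfinite(self.cortical_depth_um) and self.cortical_depth_um < 0:
            raise ValueError("cortical depth must be non-negative")

    @property
    def area_px(self) -> int:
        return int(self.cell_mask.sum())


@dataclass
class RoiSummary:
    roi_id: str
    n_microglia: int
    pct_positive: float
    mean_engulf_area_pct: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_positive <= 100.0):
            raise ValueError("pct_positive out of range")


def _as_mask(m: BinaryMask | np.ndarray) -> np.ndarray:
    return m.mask if isinstance(m, BinaryMask) else np.asarray(m, dtype=bool)


def colocalization_fraction(
    cell: MicrogliaCell,
    signal_mask: BinaryMask | np.ndarray,
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> tuple[float, bool]:
    """Percent of the cell area colocalized with a signal mask.

    Overlap regions smaller than ``min_pixels`` (8-connectivity) are
    discarded; the cell is positive iff at least one region survives.
    """
    signal = _as_mask(signal_mask)
    if signal.shape != cell.cell_mask.shape:
        raise ValueError("signal mask and cell mask shapes differ")
    overlap = cell.cell_mask & signal
    labels, regions = connected_regions(overlap, connectivity=8, min_pixels=min_pixels)
    kept_area = int(regions["area_px"].sum()) if len(regions) else 0
    pct = 100.0 * kept_area / cell.area_px
    return pct, bool(len(regions))


def triple_engulfment(
    cell: MicrogliaCell,
    psd_mask: BinaryMask | np.ndarray,
    cd68_mask: BinaryMask | np.ndarray,
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> tuple[float, bool]:
    """Engulfment area percent and positivity for one microglia.

    Qualifying puncta are connected regions of PSD-95 AND CD68 AND the
    cell mask with at least ``min_pixels`` pixels: synaptic material only
    counts when it sits inside a lysosome inside the microglia.
    """
    psd = _as_mask(psd_mask)
    cd68 = _as_mask(cd68_mask)
    if psd.shape != cell.cell_mask.shape or cd68.shape != cell.cell_mask.shape:
        raise ValueError("mask geometries differ")
    overlap = cell.cell_mask & psd & cd68
    _labels, regions = connected_regions(overlap, connectivity=8, min_pixels=min_pixels)
    kept_area = int(regions["area_px"].sum()) if len(regions) else 0
    pct = 100.0 * kept_area / cell.area_px
    return pct, bool(len(regions))


def score_roi(
    cells: list[MicrogliaCell],
    psd_mask: BinaryMask | np.ndarray,
    cd68_mask: BinaryMask | np.ndarray,
    min_pixels: int = DEFAULT_MIN_PIXELS,
    roi_id: str = "roi",
) -> RoiSummary:
    """Triple-engulfment scoring over all microglia of one ROI."""
    if not cells:
        return RoiSummary(roi_id, 0, 0.0, float("nan"))
    pcts, flags = [], []
    for cell in cells:
        pct, pos = triple_engulfment(cell, psd_mask, cd68_mask, min_pixels)
        cell.metrics["engulf_area_pct"] = pct
        cell.metrics["engulf_positive"] = pos
        pcts.append(pct)
        flags.append(pos)
    return RoiSummary(
        roi_id=roi_id,
        n_microglia=len(cells),
        pct_positive=100.0 * np.mean(flags),
        mean_engulf_area_pct=float(np.mean(pcts)),
    )


def shifted_null(
    psd_mask: BinaryMask | np.ndarray,
    cd68_mask: BinaryMask | np.ndarray,
    cells: list[MicrogliaCell],
    geom: PixelGeometry,
    distance_um: float = DEFAULT_SHIFT_UM,
    n_rounds: int = 100,
    min_pixels: int = DEFAULT_MIN_PIXELS,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Chance-colocalization null distribution by random pixel shifting.

    Per round, the PSD-95 and CD68 masks are each translated by
    ``distance_um`` in an independently drawn cardinal direction
    (toroidal wrap) and triple engulfment is rescored against the
    original, unmoved cell masks.  Returns one row per round with the
    percent of positive microglia and the mean engulfment area percent.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    psd = _as_mask(psd_mask)
    cd68 = _as_mask(cd68_mask)
    rows = []
    for r in range(n_rounds):
        psd_s, d1 = pixel_shift(psd, distance_um, geom, rng=rng)
        cd68_s, d2 = pixel_shift(cd68, distance_um, geom, rng=rng)
        summary = score_roi(cells, psd_s, cd68_s, min_pixels, roi_id=f"shift_{r}")
        rows.append(
            {
                "round": r,
                "pct_positive": summary.pct_positive,
                "mean_engulf_area_pct": summary.mean_engulf_area_pct,
                "direction_psd": d1,
                "direction_cd68": d2,
            }
        )
    return pd.DataFrame(rows)


def depth_correlation(
    cells: list[MicrogliaCell],
    max_depth_um: float = 300.0,
) -> dict:
    """Pearson correlation of engulfment area with cortical depth.

    Restricted to engulfment-positive microglia (cells carrying no triple
    punctum are excluded) at depth <= ``max_depth_um`` (the L1 + L2/3
    band where the analyzed dendrites live).
    """
    pts = [
        (c.cortical_depth_um, c.metrics["engulf_area_pct"])
        for c in cells
        if c.metrics.get("engulf_positive")
        and np.isfinite(c.cortical_depth_um)
        and c.cortical_depth_um <= max_depth_um
    ]
    if len(pts) < 3:
        raise ValueError("need at least 3 engulfment-positive cells within the depth limit")
    depth = np.array([p[0] for p in pts])
    engulf = np.array([p[1] for p in pts])
    if np.ptp(engulf) == 0 or np.ptp(depth) == 0:
        return {"r": float("nan"), "p": float("nan"), "slope": 0.0, "intercept": float(engulf.mean()),
                "slope_ci95": (float("nan"), float("nan")), "n": len(pts), "degenerate": True}
    lr = stats.linregress(depth, engulf)
    tcrit = stats.t.ppf(0.975, len(pts) - 2)
    return {
        "r": float(lr.rvalue),
        "p": float(lr.pvalue),
        "slope": float(lr.slope),
        "intercept": float(lr.intercept),
        "slope_ci95": (float(lr.slope - tcrit * lr.stderr), float(lr.slope + tcrit * lr.stderr)),
        "n": len(pts),
        "degenerate": False,
    }


def microglia_density(
    cells: list[MicrogliaCell],
    layer_volumes_um3: dict[str, float],
    layer_bins_um: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Cells per unit tissue volume per cortical layer.

    A cell belongs to the first bin whose (lo, hi] interval contains its
    soma depth; the first bin is closed at both ends so a cell at exactly
    the L1/L2-3 boundary counts as L1.  Cells deeper than every bin are
    excluded.
    """
    bins = layer_bins_um or LAYER_BINS_UM
    for layer, vol in layer_volumes_um3.items():
        if vol <= 0:
            raise ValueError(f"volume for {layer!r} must be positive")
    counts = {layer: 0 for layer in bins}
    excluded = 0
    ordered = list(bins.items())
    for c in cells:
        d = c.cortical_depth_um
        assigned = False
        for k, (layer, (lo, hi)) in enumerate(ordered):
            inside = (lo <= d <= hi) if k == 0 else (lo < d <= hi)
            if inside:
                counts[layer] += 1
                assigned = True
                break
        if not assigned:
            excluded += 1
    rows = []
    for layer in bins:
        vol = layer_volumes_um3.get(layer)
        rows.append(
            {
                "layer": layer,
                "n_cells": counts[layer],
                "volume_um3": vol,
                "density_per_um3": counts[layer] / vol if vol else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_excluded"] = excluded
    return df


def cd68_reactivity(cell: MicrogliaCell, cd68_mask: BinaryMask | np.ndarray) -> float:
    """Percent of the microglia area covered by CD68 signal (reactivity).

    No minimum-size filter: this is a plain area ratio.
    """
    cd68 = _as_mask(cd68_mask)
    if cd68.shape != cell.cell_mask.shape:
        raise ValueError("mask geometries differ")
    return 100.0 * (cell.cell_mask & cd68).sum() / cell.area_px
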