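"""Expansion-microscopy (ExM) analysis.

Per-cell linear scaling factors from pre/post soma cross-sections,
rule-based lysosome detection in the CD68 channel, PSD-95 positivity
scoring against local-background statistics with a z-profile co-peak
check, and per-cell lysosome summaries with expansion-corrected sizes.

All intensity criteria are relative (ratios to local background), so
detection is invariant to global intensity rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label
from skimage.measure import regionprops
from skimage.morphology import disk as _disk_se

from .imaging import PixelGeometry, pixels_to_um2

__all__ = [
    "SomaAxes",
    "Lysosome",
    "scaling_factor",
    "measure_soma_axes",
    "detect_lysosomes",
    "score_psd_positive",
    "lysosome_stats",
]

DEFAULT_PIXEL_SIZE_POST_UM = 0.155
MIN_LYSOSOME_PX = 9  # 3x3 px, 0.216 um^2 at post-expansion sampling
MIN_PUNCTUM_PX = 4  # 2x2 px, 0.0961 um^2


@dataclass(frozen=True)
class SomaAxes:
    """Long and short cross-sections of a soma on a max-intensity projection."""

    long_um: float
    short_um: float

    def __post_init__(self) -> None:
        if not (self.long_um >= self.short_um > 0):
            raise ValueError("require long_um >= short_um > 0")


@dataclass
class Lysosome:
    roi_mask: np.ndarray  # (y, x) bool at the brightest plane
    brightest_plane: int
    area_px: int
    area_um2_expanded: float
    z_planes_present: tuple[int, ...]
    centroid_yx_px: tuple[float, float]
    psd_positive: bool | None = None
    area_um2_scaled: float | None = None


def scaling_factor(pre: SomaAxes, post: SomaAxes) -> float:
    """Per-cell linear expansion factor: mean of the long- and short-axis
    post/pre ratios.  Values below 1 indicate shrinkage and are returned
    as-is (the caller may flag them)."""
    return 0.5 * (post.long_um / pre.long_um + post.short_um / pre.short_um)


def measure_soma_axes(
    channel: np.ndarray, geom: PixelGeometry, min_area_px: int = 50
) -> pd.DataFrame:
    """Soma axes of every cell in a stack via max-intensity projection.

    The projection is Otsu-binarized; each connected component of at
    least ``min_area_px`` is reduced to its ellipse axes (major/minor
    axis lengths in um).  Rows are sorted by projected centroid position
    (row band, then x) so corresponding cells of a pre/post pair line up.
    """
    arr = np.asarray(channel, dtype=float)
    proj = arr.max(axis=0) if arr.ndim == 3 else arr
    if np.ptp(proj) == 0:
        raise ValueError("projection is constant; no cells to measure")
    mask = proj >= threshold_otsu(proj)
    labels = _cc_label(mask, connectivity=2)
    rows = []
    for prop in regionprops(labels):
        if prop.area < min_area_px:
            continue
        rows.append(
            {
                "cy_frac": prop.centroid[0] / proj.shape[0],
                "cx_frac": prop.centroid[1] / proj.shape[1],
                "long_um": prop.axis_major_length * geom.pixel_size_um,
                "short_um": prop.axis_minor_length * geom.pixel_size_um,
                "area_um2": pixels_to_um2(prop.area, geom),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["row_band"] = (df["cy_frac"] * 8).round().astype(int)
    return df.sort_values(["row_band", "cx_frac"], ignore_index=True)


def _region_annulus(
    footprint: np.ndarray, exclude: np.ndarray | None = None, width_factor: float = 2.0
) -> np.ndarray:
    """Annulus around a 2-D region: dilation by width_factor x the
    equivalent radius, minus the region itself and any exclusions.
    Dilation runs on a cropped window for speed."""
    r_eq = max(np.sqrt(footprint.sum() / np.pi), 1.0)
    rad = max(int(round(width_factor * r_eq)), 2)
    ys, xs = np.nonzero(footprint)
    pad = rad + 2
    y0, y1 = max(ys.min() - pad, 0), min(ys.max() + pad + 1, footprint.shape[0])
    x0, x1 = max(xs.min() - pad, 0), min(xs.max() + pad + 1, footprint.shape[1])
    se = _disk_se(rad)
    ann = np.zeros_like(footprint)
    win = binary_dilation(footprint[y0:y1, x0:x1], structure=se) & ~footprint[y0:y1, x0:x1]
    ann[y0:y1, x0:x1] = win
    if exclude is not None:
        ann &= ~exclude
    return ann


def detect_lysosomes(
    cd68: np.ndarray,
    cell_mask: np.ndarray,
    geom: PixelGeometry,
    min_area_px: int = MIN_LYSOSOME_PX,
    background_factor: float = 2.0,
) -> list[Lysosome]:
    """Rule-based lysosome detection within one cell.

    A CD68 region is scored as a lysosome iff: its area at the brightest
    plane (argmax of region mean intensity over z) is at least
    ``min_area_px``; its mean intensity there is at least
    ``background_factor`` times the local background (annulus around the
    region, candidate pixels excluded); and it is present in at least two
    consecutive z-planes.
    """
    arr = np.asarray(cd68, dtype=float)
    if arr.ndim != 3:
        raise ValueError("cd68 must be a (z, y, x) stack")
    cell = np.asarray(cell_mask, dtype=bool)
    if not cell.any():
        raise ValueError("cell mask is empty")
    inside = arr * cell[None, :, :]
    vals = arr[:, cell]
    if np.ptp(vals) == 0:
        return []
    thr = threshold_otsu(vals)
    cand = (inside >= thr) & cell[None, :, :]
    labels = _cc_label(cand, connectivity=3)
    any_cand = cand.any(axis=0)

    out: list[Lysosome] = []
    for prop in regionprops(labels):
        zs = np.unique(prop.coords[:, 0])
        if len(zs) < 2 or not (np.diff(np.sort(zs)) == 1).any():
            continue  # consecutive-plane rule
        # brightest plane: argmax over z of mean region intensity
        plane_means = {}
        for z in zs:
            sel = prop.coords[prop.coords[:, 0] == z]
            plane_means[z] = arr[z, sel[:, 1], sel[:, 2]].mean()
        zstar = int(max(plane_means, key=plane_means.get))
        sel = prop.coords[prop.coords[:, 0] == zstar]
        if len(sel) < min_area_px:
            continue
        footprint = np.zeros(cell.shape, dtype=bool)
        footprint[sel[:, 1], sel[:, 2]] = True
        ann = _region_annulus(footprint, exclude=any_cand)
        bg = arr[zstar][ann].mean() if ann.any() else 0.0
        roi_mean = arr[zstar][footprint].mean()
        if bg > 0 and roi_mean < background_factor * bg:
            continue
        out.append(
            Lysosome(
                roi_mask=footprint,
                brightest_plane=zstar,
                area_px=int(footprint.sum()),
                area_um2_expanded=pixels_to_um2(footprint.sum(), geom),
                z_planes_present=tuple(int(z) for z in np.sort(zs)),
                centroid_yx_px=(float(sel[:, 1].mean()), float(sel[:, 2].mean())),
            )
        )
    return out


def score_psd_positive(
    lysosome: Lysosome,
    psd: np.ndarray,
    cd68: np.ndarray,
    exclude_mask: np.ndarray | None = None,
    min_punctum_px: int = MIN_PUNCTUM_PX,
    annulus_width_factor: float = 2.0,
    co_peak_tolerance: int = 1,
) -> bool:
    """Score a lysosome positive for engulfed synaptic material.

    Three conditions must all hold at the lysosome's brightest plane:
    (a) the mean PSD-95 signal in the ROI exceeds the local-background
    mean by two background standard deviations; (b) a connected PSD-95
    region of at least ``min_punctum_px`` pixels lies within the ROI with
    mean intensity at least twice the local background; (c) the PSD-95
    and CD68 z-profiles of the ROI peak at the same plane within
    ``co_peak_tolerance``.
    """
    psd = np.asarray(psd, dtype=float)
    cd68 = np.asarray(cd68, dtype=float)
    roi = lysosome.roi_mask
    z = lysosome.brightest_plane
    ann = _region_annulus(roi, exclude=exclude_mask, width_factor=annulus_width_factor)
    if not ann.any():
        raise ValueError("background annulus is empty")
    bg_vals = psd[z][ann]
    bg_mean, bg_sd = float(bg_vals.mean()), float(bg_vals.std())
    thr = bg_mean + 2.0 * bg_sd

    if psd[z][roi].mean() < thr:  # (a)
        return False

    punctum_req = max(2.0 * bg_mean, thr)
    cand = (psd[z] >= thr) & roi
    labels = _cc_label(cand, connectivity=2)
    cond_b = False
    for prop in regionprops(labels):
        if prop.area >= min_punctum_px:
            vals = psd[z][labels == prop.label]
            if vals.mean() >= punctum_req:
                cond_b = True
                break
    if not cond_b:
        return False

    psd_profile = psd[:, roi].mean(axis=1)
    cd_profile = cd68[:, roi].mean(axis=1)
    return abs(int(np.argmax(psd_profile)) - int(np.argmax(cd_profile))) <= co_peak_tolerance  # (c)


def lysosome_stats(
    cells: list[dict],
) -> pd.DataFrame:
    """Per-cell lysosome summaries with expansion-corrected sizes.

    Each entry of ``cells`` is ``{"cell_id", "lysosomes": [Lysosome],
    "factor": float}``.  Measured (expanded) areas are divided by
    factor**2 to recover pre-expansion sizes; positive and negative
    lysosomes are summarized separately.
    """
    rows = []
    for entry in cells:
        factor = entry["factor"]
        if factor is None or not np.isfinite(factor):
            raise ValueError("every cell needs a scaling factor")
        lys = entry["lysosomes"]
        for l in lys:
            l.area_um2_scaled = l.area_um2_expanded / factor**2
        pos = [l for l in lys if l.psd_positive]
        neg = [l for l in lys if not l.psd_positive]
        rows.append(
            {
                "cell_id": entry.get("cell_id"),
                "factor": factor,
                "n_lysosomes": len(lys),
                "n_positive": len(pos),
                "pct_positive": 100.0 * len(pos) / len(lys) if lys else np.nan,
                "mean_area_expanded_um2_pos": float(np.mean([l.area_um2_expanded for l in pos])) if pos else np.nan,
                "mean_area_expanded_um2_neg": float(np.mean([l.area_um2_expanded for l in neg])) if neg else np.nan,
                "mean_area_scaled_um2_pos": float(np.mean([l.area_um2_scaled for l in pos])) if pos else np.nan,
                "mean_area_scaled_um2_neg": float(np.mean([l.area_um2_scaled for l in neg])) if neg else np.nan,
            }
        )
    return pd.DataFrame(rows)
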