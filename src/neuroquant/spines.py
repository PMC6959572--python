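"""Dendritic protrusion density and intensity-based spine-type classification.

The brightness statistic (TIB) is the mean intensity of a protrusion ROI
at its brightest focal plane divided by the mean intensity of the
adjacent dendritic shaft; since reporter brightness is monotonically
related to protrusion volume, TIB ranks protrusions by size without a
3-D reconstruction.  Spine types are assigned by percentile cutoffs of a
control-condition TIB reference distribution: below the 25th percentile
thin/filopodia, above the 75th mushroom/stubby, boundaries inclusive to
the medium class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .imaging import PixelGeometry

__all__ = [
    "ProtrusionRecord",
    "DendriteSegment",
    "protrusion_filter",
    "compute_tib",
    "classify_spines",
    "spine_density",
    "CLASS_NAMES",
]

CLASS_NAMES = ("thin_filopodia", "medium", "mushroom_stubby")
MIN_EXTENT_PX = 3  # inclusion rule: protrude beyond the shaft by >= 3 px
LENGTH_BOUNDS_UM = (50.0, 80.0)


@dataclass
class ProtrusionRecord:
    roi_mask: np.ndarray  # (y, x) bool at the brightest plane
    extent_px: float = np.nan
    tib: float = np.nan
    klass: str | None = None
    brightest_plane: int | None = None
    flagged: bool = False


@dataclass
class DendriteSegment:
    analyzed_length_um: float
    protrusions: list[ProtrusionRecord] = field(default_factory=list)
    compartment: str = "apical_tuft"  # or "basal"
    length_bounds_um: tuple[float, float] = LENGTH_BOUNDS_UM

    def __post_init__(self) -> None:
        if self.analyzed_length_um <= 0:
            raise ValueError("analyzed length must be positive")
        lo, hi = self.length_bounds_um
        if not (lo <= self.analyzed_length_um <= hi):
            raise ValueError(
                f"analyzed length {self.analyzed_length_um} um outside bounds {self.length_bounds_um}"
            )


def protrusion_filter(
    candidate_mask: np.ndarray,
    shaft_mask: np.ndarray,
    geom: PixelGeometry | None = None,
    min_extent_px: int = MIN_EXTENT_PX,
    attach_radius_px: float = 3.0,
) -> tuple[bool, float, str]:
    """Inclusion rule for a candidate protrusion ROI.

    Keep iff the candidate clearly protrudes beyond the shaft edge by at
    least ``min_extent_px`` pixels, measured as the maximum Euclidean
    distance of candidate pixels from the shaft mask.  Candidates with no
    pixel within ``attach_radius_px`` of the shaft are rejected as
    detached.  Returns (keep, extent_px, reason).
    """
    cand = np.asarray(candidate_mask, dtype=bool)
    shaft = np.asarray(shaft_mask, dtype=bool)
    if cand.shape != shaft.shape:
        raise ValueError("candidate and shaft masks must share geometry")
    if not cand.any():
        return False, 0.0, "empty candidate"
    dist = distance_transform_edt(~shaft)
    cand_dist = dist[cand]
    if cand_dist.min() > attach_radius_px:
        return False, float(cand_dist.max()), "detached from shaft"
    extent = float(cand_dist.max())
    if extent >= min_extent_px:
        return True, extent, "ok"
    return False, extent, "below minimum extent"


def compute_tib(
    protrusion_mask: np.ndarray,
    shaft_mask: np.ndarray,
    channel: np.ndarray,
) -> tuple[float, int]:
    """TIB of one protrusion: mean ROI intensity over mean adjacent-shaft
    intensity, both at the protrusion's brightest focal plane (argmax over
    z of the ROI mean).  Returns (tib, brightest_plane)."""
    prot = np.asarray(protrusion_mask, dtype=bool)
    shaft = np.asarray(shaft_mask, dtype=bool)
    arr = np.asarray(channel, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if not prot.any() or not shaft.any():
        raise ValueError("protrusion and shaft ROIs must be non-empty")
    means = arr[:, prot].mean(axis=1)
    z = int(np.argmax(means))
    shaft_mean = float(arr[z][shaft].mean())
    if shaft_mean == 0:
        raise ZeroDivisionError("adjacent shaft mean intensity is zero; TIB undefined")
    return float(means[z] / shaft_mean), z


def classify_spines(
    tibs: np.ndarray | list[float],
    reference: np.ndarray | list[float],
    min_reference_n: int = 20,
) -> tuple[list[str], tuple[float, float]]:
    """Assign spine types from reference-distribution percentile cutoffs.

    Cutoffs are the 25th and 75th percentiles (linear interpolation) of
    the control-condition reference sample; they do not depend on the
    sample being classified.  Boundaries are inclusive to the medium
    class.  Returns (labels, (q25, q75)).
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("reference sample is empty")
    if ref.size < min_reference_n:
        raise ValueError(f"reference sample too small (< {min_reference_n})")
    q25, q75 = np.percentile(ref, [25, 75])
    labels = []
    for t in np.asarray(tibs, dtype=float):
        if t < q25:
            labels.append("thin_filopodia")
        elif t > q75:
            labels.append("mushroom_stubby")
        else:
            labels.append("medium")
    return labels, (float(q25), float(q75))


def spine_density(segment: DendriteSegment) -> pd.Series:
    """Protrusions per micrometre of analyzed shaft, overall and per class.

    Per-class densities partition the overall density (unclassified
    protrusions get their own column).
    """
    L = segment.analyzed_length_um
    counts: dict[str, int] = {k: 0 for k in CLASS_NAMES}
    unclassified = 0
    for p in segment.protrusions:
        if p.klass in counts:
            counts[p.klass] += 1
        else:
            unclassified += 1
    out = {"overall": len(segment.protrusions) / L}
    for k in CLASS_NAMES:
        out[k] = counts[k] / L
    out["unclassified"] = unclassified / L
    return pd.Series(out, name="spines_per_um")
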