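"""Shared image data model and primitive operations.

Provides the in-memory stack container with physical voxel geometry,
binarization, connected-component region extraction with physical-unit
size filters, and the random pixel-shift translation used as the
chance-colocalization null control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label
from skimage.measure import regionprops

logger = logging.getLogger(__name__)

__all__ = [
    "PixelGeometry",
    "ImageStack",
    "BinaryMask",
    "binarize",
    "connected_regions",
    "pixels_to_um",
    "pixels_to_um2",
    "um_to_pixels",
    "pixel_shift",
    "SHIFT_DIRECTIONS",
]


@dataclass(frozen=True)
class PixelGeometry:
    """Physical sampling of an image: in-plane pixel size and z-step, in micrometres."""

    pixel_size_um: float
    z_step_um: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel_size_um and z_step_um must be positive")


@dataclass
class ImageStack:
    """Multi-channel 3-D intensity stack indexed (channel, z, y, x).

    Physical geometry travels with the voxels so that every size rule
    (minimum punctum area, shift distances, densities) can be stated in
    micrometres and converted at the point of use.
    """

    voxels: np.ndarray
    pixel_size_um: float
    z_step_um: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be 4-D (channel, z, y, x)")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel sizes must be positive")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError("channel_names length must match channel axis")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names must be unique")

    @property
    def geometry(self) -> PixelGeometry:
        return PixelGeometry(self.pixel_size_um, self.z_step_um)

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return the (z, y, x) array for a named channel."""
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}") from None
        return self.voxels[i]


@dataclass
class BinaryMask:
    """Boolean mask with a record of how it was produced."""

    mask: np.ndarray
    method: str
    threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def binarize(channel: np.ndarray, method: str = "otsu", value: float | None = None) -> BinaryMask:
    """Threshold an intensity image into a boolean mask.

    method='fixed' uses `value` directly; 'percentile' uses the given
    percentile of the intensity distribution; 'otsu' picks the threshold
    automatically.  The mask is True where intensity >= threshold.  For
    group comparisons the caller pins a single fixed threshold across all
    images of a batch so that both conditions are binarized with the same
    settings.
    """
    channel = np.asarray(channel)
    if channel.ndim not in (2, 3):
        raise ValueError("channel must be 2-D or 3-D")
    if method == "fixed":
        if value is None:
            raise ValueError("fixed method requires a threshold value")
        thr = float(value)
    elif method == "percentile":
        if value is None:
            raise ValueError("percentile method requires a percentile value")
        thr = float(np.percentile(channel, value))
    elif method == "otsu":
        if np.ptp(channel) == 0:
            warnings.warn(
                "otsu threshold undefined on a constant image; returning empty mask",
                stacklevel=2,
            )
            return BinaryMask(np.zeros(channel.shape, dtype=bool), "otsu", np.inf)
        thr = float(threshold_otsu(channel))
    else:
        raise ValueError(f"unknown method {method!r}")
    return BinaryMask(channel >= thr, method, thr)


_CONNECTIVITY_2D = {4: 1, 8: 2}
_CONNECTIVITY_3D = {6: 1, 18: 2, 26: 3}


def connected_regions(
    mask: BinaryMask | np.ndarray,
    connectivity: int = 8,
    min_pixels: int = 1,
    geom: PixelGeometry | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Label connected regions and filter them by a minimum pixel area.

    Connectivity is given in the imaging convention (4/8 in-plane,
    6/18/26 volumetric).  Regions smaller than `min_pixels` are removed
    from the label image.  Returns the filtered label image and a table
    with per-region pixel areas, plus physical areas when `geom` is given.
    """
    arr = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    table = _CONNECTIVITY_2D if arr.ndim == 2 else _CONNECTIVITY_3D
    if connectivity not in table:
        raise ValueError(f"connectivity must be one of {sorted(table)} for {arr.ndim}-D input")
    labels = _cc_label(arr, connectivity=table[connectivity])
    rows = []
    for prop in regionprops(labels):
        if prop.area < min_pixels:
            labels[tuple(prop.coords.T)] = 0
            continue
        row = {
            "label": prop.label,
            "area_px": int(prop.area),
            "centroid": prop.centroid,
        }
        if geom is not None:
            row["area_um2"] = pixels_to_um2(prop.area, geom)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["label", "area_px", "centroid"] + (["area_um2"] if geom else []))
    return labels, df


def pixels_to_um(n_pixels: float, geom: PixelGeometry) -> float:
    """Convert a pixel length to micrometres."""
    if n_pixels < 0:
        raise ValueError("pixel count must be non-negative")
    return n_pixels * geom.pixel_size_um


def pixels_to_um2(n_pixels: float, geom: PixelGeometry) -> float:
    """Convert a pixel area to square micrometres."""
    if n_pixels < 0:
        raise ValueError("pixel count must be non-negative")
    return n_pixels * geom.pixel_size_um**2


def um_to_pixels(length_um: float, geom: PixelGeometry) -> int:
    """Round a physical length to the nearest whole number of pixels."""
    if length_um < 0:
        raise ValueError("length must be non-negative")
    return int(round(length_um / geom.pixel_size_um))


# Cardinal in-plane directions as (dy, dx) unit steps.
SHIFT_DIRECTIONS = {"+x": (0, 1), "-x": (0, -1), "+y": (1, 0), "-y": (-1, 0)}


def pixel_shift(
    channel: np.ndarray,
    distance_um: float,
    geom: PixelGeometry,
    rng: np.random.Generator | int | None = None,
    direction: str | None = None,
    wrap: bool = True,
) -> tuple[np.ndarray, str]:
    """Translate a whole channel by a fixed physical distance in a random
    cardinal direction.

    The null-control construction: each channel shifted independently by
    `distance_um` along one of {+x, -x, +y, -y} chosen uniformly at random,
    decorrelating it from the others while preserving its internal
    structure.  With `wrap` (default) the translation is toroidal so total
    signal is conserved; otherwise vacated pixels are zero-filled.
    """
    arr = np.asarray(channel)
    if arr.ndim not in (2, 3):
        raise ValueError("channel must be a 2-D plane or 3-D stack")
    if distance_um < 0:
        raise ValueError("distance_um must be non-negative")
    shift_px = um_to_pixels(distance_um, geom)
    if direction is None:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        direction = str(rng.choice(sorted(SHIFT_DIRECTIONS)))
    if direction not in SHIFT_DIRECTIONS:
        raise ValueError(f"direction must be one of {sorted(SHIFT_DIRECTIONS)}")
    dy, dx = SHIFT_DIRECTIONS[direction]
    ax_y, ax_x = arr.ndim - 2, arr.ndim - 1
    if shift_px >= arr.shape[ax_y] or shift_px >= arr.shape[ax_x]:
        raise ValueError("shift exceeds image extent")
    if shift_px == 0:
        return arr.copy(), direction
    if wrap:
        out = np.roll(arr, (dy * shift_px, dx * shift_px), axis=(ax_y, ax_x))
    else:
        out = np.zeros_like(arr)
        sly_src, sly_dst = _crop_slices(dy * shift_px, arr.shape[ax_y])
        slx_src, slx_dst = _crop_slices(dx * shift_px, arr.shape[ax_x])
        if arr.ndim == 2:
            out[sly_dst, slx_dst] = arr[sly_src, slx_src]
        else:
            out[:, sly_dst, slx_dst] = arr[:, sly_src, slx_src]
    return out, direction


def _crop_slices(shift: int, size: int) -> tuple[slice, slice]:
    if shift > 0:
        return slice(0, size - shift), slice(shift, size)
    if shift < 0:
        return slice(-shift, size), slice(0, size + shift)
    return slice(None), slice(None)
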