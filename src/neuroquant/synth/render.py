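"""Rasterization primitives for the synthetic scene generators.

Objects are anti-aliased discs, ellipses and capsules evaluated on pixel
centers: per-pixel coverage is approximated from the signed distance to
the shape boundary, giving controllable sub-pixel geometry without a
full supersampling pass.
"""

from __future__ import annotations

import numpy as np

__all__ = ["draw_disk", "draw_ellipse", "draw_capsule", "coverage_to_mask"]


def _bbox(shape: tuple[int, int], y0: float, y1: float, x0: float, x1: float, pad: float):
    ylo = max(int(np.floor(y0 - pad)), 0)
    yhi = min(int(np.ceil(y1 + pad)) + 1, shape[0])
    xlo = max(int(np.floor(x0 - pad)), 0)
    xhi = min(int(np.ceil(x1 + pad)) + 1, shape[1])
    if ylo >= yhi or xlo >= xhi:
        return None
    yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
    return ylo, yhi, xlo, xhi, yy.astype(float), xx.astype(float)


def _paint(img: np.ndarray, window, coverage: np.ndarray, value: float) -> None:
    ylo, yhi, xlo, xhi = window
    patch = img[ylo:yhi, xlo:xhi]
    np.maximum(patch, value * coverage, out=patch)


def draw_disk(img: np.ndarray, center_yx: tuple[float, float], radius: float, value: float = 1.0) -> None:
    """Paint an anti-aliased disc (pixel units) into `img` via max-compositing."""
    cy, cx = center_yx
    box = _bbox(img.shape, cy - radius, cy + radius, cx - radius, cx + radius, 1.5)
    if box is None:
        return
    ylo, yhi, xlo, xhi, yy, xx = box
    d = np.hypot(yy - cy, xx - cx) - radius
    cov = np.clip(0.5 - d, 0.0, 1.0)
    _paint(img, (ylo, yhi, xlo, xhi), cov, value)


def draw_ellipse(
    img: np.ndarray,
    center_yx: tuple[float, float],
    semi_axes: tuple[float, float],
    angle_rad: float = 0.0,
    value: float = 1.0,
) -> None:
    """Paint an anti-aliased ellipse with semi-axes (a, b) in pixels, `a`
    along the direction given by `angle_rad` (measured from +x toward +y)."""
    cy, cx = center_yx
    a, b = semi_axes
    r = max(a, b)
    box = _bbox(img.shape, cy - r, cy + r, cx - r, cx + r, 1.5)
    if box is None:
        return
    ylo, yhi, xlo, xhi, yy, xx = box
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    # approximate signed distance: scaled implicit function, good enough for AA
    q = np.hypot(u / a, v / b)
    d = (q - 1.0) * min(a, b)
    cov = np.clip(0.5 - d, 0.0, 1.0)
    _paint(img, (ylo, yhi, xlo, xhi), cov, value)


def draw_capsule(
    img: np.ndarray,
    p0_yx: tuple[float, float],
    p1_yx: tuple[float, float],
    radius: float,
    value: float = 1.0,
) -> None:
    """Paint an anti-aliased capsule (thick segment) between two points (pixels)."""
    y0, x0 = p0_yx
    y1, x1 = p1_yx
    box = _bbox(
        img.shape,
        min(y0, y1) - radius,
        max(y0, y1) + radius,
        min(x0, x1) - radius,
        max(x0, x1) + radius,
        1.5,
    )
    if box is None:
        return
    ylo, yhi, xlo, xhi, yy, xx = box
    vy, vx = y1 - y0, x1 - x0
    L2 = vy * vy + vx * vx
    if L2 == 0:
        t = np.zeros_like(yy)
    else:
        t = np.clip(((yy - y0) * vy + (xx - x0) * vx) / L2, 0.0, 1.0)
    d = np.hypot(yy - (y0 + t * vy), xx - (x0 + t * vx)) - radius
    cov = np.clip(0.5 - d, 0.0, 1.0)
    _paint(img, (ylo, yhi, xlo, xhi), cov, value)


def coverage_to_mask(img: np.ndarray, level: float = 0.5) -> np.ndarray:
    """Boolean mask of pixels at least half-covered."""
    return img >= level
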