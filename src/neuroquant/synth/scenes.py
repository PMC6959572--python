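"""Ground-truthed synthetic fluorescence scenes.

Three generators emulate the imaging experiments the quantification
pipelines were built for:

* ``generate_engulfment_stack`` — a confocal field of microglia (Iba1)
  with DAPI nuclei, CD68+ lysosomes, and PSD-95 puncta that are either
  engulfed (strictly inside a lysosome) or free in the neuropil.
* ``generate_spine_image`` — a dendritic shaft with protrusions whose
  integrated brightness is proportional to a drawn volume, the premise
  behind intensity-based spine-type classification.
* ``generate_exm_pair`` — pre/post expansion-microscopy image pairs of
  the same scene with all physical coordinates scaled by a known linear
  expansion factor.

Every generator is deterministic given its seed and returns a ground
truth object holding the rendered object masks and labels, so each
downstream measurement can be checked against what was actually drawn.
Rendering is anti-aliased rasterization followed by a Gaussian blur
standing in for the PSF, plus additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ..imaging import ImageStack, PixelGeometry
from .render import coverage_to_mask, draw_capsule, draw_disk, draw_ellipse

__all__ = [
    "EngulfmentSceneParams",
    "MicrogliaTruth",
    "EngulfmentTruth",
    "generate_engulfment_stack",
    "SpineTruth",
    "generate_spine_image",
    "default_volume_mixture",
    "ExmTruth",
    "generate_exm_pair",
]


@dataclass(frozen=True)
class EngulfmentSceneParams:
    """Scene parameters for a synthetic engulfment ROI.

    Defaults reproduce the analyzed imaging conditions: a 280 x 350 um
    transfected-region ROI sampled at 0.27 um/pixel containing on the
    order of 14 microglia.
    """

    roi_size_um: tuple[float, float] = (280.0, 350.0)  # (x, y) extent
    n_planes: int = 3
    pixel_size_um: float = 0.27
    z_step_um: float = 0.3
    n_microglia: int = 14
    lysosomes_per_microglia: float = 3.0
    engulfment_rate: float = 0.3
    free_puncta_density: float = 0.005  # puncta per um^2 outside microglia
    psf_sigma_um: float = 0.25
    noise_sd: float = 4.0
    amplitude: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.engulfment_rate <= 1.0):
            raise ValueError("engulfment_rate must be in [0, 1]")
        if self.free_puncta_density < 0 or self.lysosomes_per_microglia < 0:
            raise ValueError("densities must be non-negative")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel sizes must be positive")
        if min(self.roi_size_um) <= 0 or self.n_planes < 1 or self.n_microglia < 0:
            raise ValueError("scene dimensions must be positive")

    @property
    def geometry(self) -> PixelGeometry:
        return PixelGeometry(self.pixel_size_um, self.z_step_um)

    @property
    def shape_yx(self) -> tuple[int, int]:
        nx = int(round(self.roi_size_um[0] / self.pixel_size_um))
        ny = int(round(self.roi_size_um[1] / self.pixel_size_um))
        return ny, nx


@dataclass
class MicrogliaTruth:
    """One rendered microglia: masks and labels as drawn."""

    cell_mask: np.ndarray  # (y, x) bool, soma + processes
    lysosome_mask: np.ndarray  # (y, x) bool, union of lysosomes
    soma_yx_um: tuple[float, float]
    depth_um: float  # distance from the pia edge (y = 0)
    n_lysosomes: int
    engulfed: bool  # contains >= 1 engulfed PSD punctum
    lysosomes: list[dict] = field(default_factory=list)  # center_yx_um, radius_um


@dataclass
class EngulfmentTruth:
    microglia: list[MicrogliaTruth]
    puncta: pd.DataFrame  # columns y_um, x_um, radius_um, engulfed

    @property
    def n_engulfment_positive(self) -> int:
        return sum(m.engulfed for m in self.microglia)


def _replicate_planes(base: np.ndarray, n_planes: int) -> np.ndarray:
    return np.repeat(base[None, :, :], n_planes, axis=0)


def generate_engulfment_stack(
    params: EngulfmentSceneParams,
) -> tuple[ImageStack, EngulfmentTruth]:
    """Render a synthetic engulfment ROI with channels DAPI/PSD95/Iba1/CD68.

    Microglia are somata (ellipses) with 3-6 straight processes; CD68
    lysosomes are discs inside the soma; engulfed PSD-95 puncta are placed
    strictly inside a lysosome, free puncta outside every cell mask.  The
    pia is the y = 0 edge so a cell's cortical depth is its soma y
    coordinate.
    """
    rng = np.random.default_rng(params.seed)
    ny, nx = params.shape_yx
    px = params.pixel_size_um
    amp = params.amplitude

    dapi = np.zeros((ny, nx), dtype=np.float32)
    psd = np.zeros((ny, nx), dtype=np.float32)
    iba1 = np.zeros((ny, nx), dtype=np.float32)
    cd68 = np.zeros((ny, nx), dtype=np.float32)

    margin = 12.0 / px
    centers: list[tuple[float, float]] = []
    min_sep = 22.0 / px
    for _ in range(params.n_microglia):
        for _try in range(200):
            cy = rng.uniform(margin, ny - margin)
            cx = rng.uniform(margin, nx - margin)
            if all((cy - oy) ** 2 + (cx - ox) ** 2 >= min_sep**2 for oy, ox in centers):
                centers.append((cy, cx))
                break
        else:  # crowded field: accept the last draw
            centers.append((cy, cx))

    scratch = np.zeros((ny, nx), dtype=np.float32)
    cells: list[MicrogliaTruth] = []
    puncta_rows: list[dict] = []

    for cy, cx in centers:
        a_um = rng.uniform(5.0, 8.0)
        b_um = rng.uniform(4.0, a_um)
        angle = rng.uniform(0, np.pi)
        n_proc = int(rng.integers(3, 7))

        scratch[:] = 0.0
        draw_ellipse(scratch, (cy, cx), (a_um / px, b_um / px), angle, 1.0)
        proc_dirs = rng.uniform(0, 2 * np.pi, size=n_proc)
        for th in proc_dirs:
            length = rng.uniform(10.0, 22.0) / px
            r0 = 0.8 * min(a_um, b_um) / px
            p0 = (cy + r0 * np.sin(th), cx + r0 * np.cos(th))
            p1 = (cy + (r0 + length) * np.sin(th), cx + (r0 + length) * np.cos(th))
            draw_capsule(scratch, p0, p1, 0.75 / px, 1.0)
        cell_mask = coverage_to_mask(scratch)
        np.maximum(iba1, amp * scratch, out=iba1)

        draw_ellipse(dapi, (cy, cx), (0.6 * a_um / px, 0.6 * b_um / px), angle, amp)

        # lysosomes inside the soma
        n_lys = int(rng.poisson(params.lysosomes_per_microglia))
        scratch[:] = 0.0
        lys_list: list[dict] = []
        for _ in range(n_lys):
            rad_um = rng.uniform(0.9, 1.5)
            rho = rng.uniform(0, 0.55)
            th = rng.uniform(0, 2 * np.pi)
            ly = cy + rho * b_um / px * np.sin(th)
            lx = cx + rho * a_um / px * np.cos(th)
            draw_disk(scratch, (ly, lx), rad_um / px, 1.0)
            lys_list.append({"center_yx_um": (ly * px, lx * px), "radius_um": rad_um})
        lys_mask = coverage_to_mask(scratch)
        np.maximum(cd68, amp * scratch, out=cd68)

        engulfed = bool(lys_list) and rng.uniform() < params.engulfment_rate
        if engulfed:
            n_pun = 1 + int(rng.poisson(0.7))
            for _ in range(n_pun):
                lys = lys_list[int(rng.integers(len(lys_list)))]
                p_rad = rng.uniform(0.35, min(0.55, lys["radius_um"] - 0.35))
                off = rng.uniform(0, max(lys["radius_um"] - p_rad - 0.2, 0.0))
                th = rng.uniform(0, 2 * np.pi)
                py_um = lys["center_yx_um"][0] + off * np.sin(th)
                px_um = lys["center_yx_um"][1] + off * np.cos(th)
                draw_disk(psd, (py_um / px, px_um / px), p_rad / px, amp)
                puncta_rows.append(
                    {"y_um": py_um, "x_um": px_um, "radius_um": p_rad, "engulfed": True}
                )

        cells.append(
            MicrogliaTruth(
                cell_mask=cell_mask,
                lysosome_mask=lys_mask,
                soma_yx_um=(cy * px, cx * px),
                depth_um=cy * px,
                n_lysosomes=n_lys,
                engulfed=engulfed,
                lysosomes=lys_list,
            )
        )

    # free PSD puncta outside every cell
    any_cell = np.zeros((ny, nx), dtype=bool)
    for c in cells:
        any_cell |= c.cell_mask
    free_area_um2 = (any_cell.size - any_cell.sum()) * px**2
    n_free = int(rng.poisson(params.free_puncta_density * free_area_um2))
    placed = 0
    for _try in range(20 * max(n_free, 1)):
        if placed >= n_free:
            break
        fy = rng.uniform(2.0 / px, ny - 2.0 / px)
        fx = rng.uniform(2.0 / px, nx - 2.0 / px)
        if any_cell[int(fy), int(fx)]:
            continue
        p_rad = rng.uniform(0.35, 0.55)
        draw_disk(psd, (fy, fx), p_rad / px, amp)
        puncta_rows.append(
            {"y_um": fy * px, "x_um": fx * px, "radius_um": p_rad, "engulfed": False}
        )
        placed += 1

    sigma_px = params.psf_sigma_um / px
    channels = []
    for base in (dapi, psd, iba1, cd68):
        blurred = gaussian_filter(base, sigma_px)
        stack = _replicate_planes(blurred, params.n_planes)
        if params.noise_sd > 0:
            stack = stack + rng.normal(0.0, params.noise_sd, size=stack.shape).astype(np.float32)
        channels.append(stack.astype(np.float32))

    stack = ImageStack(
        voxels=np.stack(channels, axis=0),
        pixel_size_um=px,
        z_step_um=params.z_step_um,
        channel_names=("DAPI", "PSD95", "Iba1", "CD68"),
    )
    puncta = pd.DataFrame(puncta_rows, columns=["y_um", "x_um", "radius_um", "engulfed"])
    return stack, EngulfmentTruth(microglia=cells, puncta=puncta)


# ---------------------------------------------------------------------------
# dendritic spines


def default_volume_mixture() -> list[tuple[float, float, float]]:
    """Tri-modal (weight, mean, sd) spine-volume mixture in arbitrary units:
    thin/filopodia, medium, and large mushroom/stubby modes with 25/50/25 mass."""
    return [(0.25, 0.45, 0.07), (0.50, 1.0, 0.12), (0.25, 1.9, 0.25)]


@dataclass
class SpineTruth:
    shaft_mask: np.ndarray  # (y, x) bool
    spine_masks: list[np.ndarray]  # per-protrusion (y, x) bool at its brightest plane
    records: pd.DataFrame  # x_um, side, extent_px, volume, brightest_plane, klass
    analyzed_length_um: float


def _volume_quantile_classes(volumes: np.ndarray) -> list[str]:
    """Label each drawn volume by its quantile in the sample: bottom quartile
    thin/filopodia, top quartile mushroom/stubby, the rest medium."""
    if len(volumes) == 0:
        return []
    lo, hi = np.percentile(volumes, [25, 75])
    out = []
    for v in volumes:
        if v < lo:
            out.append("thin_filopodia")
        elif v > hi:
            out.append("mushroom_stubby")
        else:
            out.append("medium")
    return out


def generate_spine_image(
    n_spines: int,
    volume_distribution: list[tuple[float, float, float]] | None = None,
    shaft_length_um: float = 60.0,
    pixel_size_um: float = 0.12,
    seed: int = 0,
    n_planes: int = 3,
    min_extent_um: float = 0.4,
    max_extent_um: float = 1.1,
    noise_sd: float = 2.0,
    shaft_amplitude: float = 100.0,
) -> tuple[ImageStack, SpineTruth]:
    """Render a dendritic shaft with protrusions of graded brightness.

    Each protrusion's peak intensity is proportional to its drawn volume
    (brightness as a volume proxy), so the intensity-over-shaft ratio
    measured downstream is monotonically related to the true volume.
    Protrusions alternate sides of the shaft and each is brightest at one
    focal plane, dimmer in the adjacent planes.
    """
    if n_spines < 0:
        raise ValueError("n_spines must be non-negative")
    if shaft_length_um <= 0:
        raise ValueError("shaft length must be positive")
    mixture = volume_distribution or default_volume_mixture()
    weights = np.array([w for w, _, _ in mixture], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("mixture weights must sum to a positive value")
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    px = pixel_size_um
    margin_um = 4.0
    nx = int(round((shaft_length_um + 2 * margin_um) / px))
    ny = int(round(16.0 / px))
    y_mid = ny / 2.0
    shaft_r_um = 0.5

    base = np.zeros((ny, nx), dtype=np.float32)
    draw_capsule(
        base,
        (y_mid, margin_um / px),
        (y_mid, (margin_um + shaft_length_um) / px),
        shaft_r_um / px,
        1.0,
    )
    shaft_mask = coverage_to_mask(base)

    comp = rng.choice(len(mixture), size=n_spines, p=weights)
    volumes = np.array(
        [max(rng.normal(mixture[c][1], mixture[c][2]), 0.05) for c in comp], dtype=float
    )
    mean_vol = float(np.average([m for _, m, _ in mixture], weights=weights))

    xs_um = np.sort(rng.uniform(margin_um + 1.0, margin_um + shaft_length_um - 1.0, n_spines))
    planes = [base.copy() for _ in range(n_planes)]
    scratch = np.zeros((ny, nx), dtype=np.float32)
    spine_masks: list[np.ndarray] = []
    rows: list[dict] = []

    for i in range(n_spines):
        side = 1 if i % 2 == 0 else -1
        ext_um = rng.uniform(min_extent_um, max_extent_um)
        amp_rel = volumes[i] / mean_vol
        bright_plane = int(rng.integers(n_planes))
        x_px = xs_um[i] / px
        y0 = y_mid + side * shaft_r_um / px
        y1 = y_mid + side * (shaft_r_um + ext_um) / px

        scratch[:] = 0.0
        draw_capsule(scratch, (y0, x_px), (y1, x_px), 0.22 / px, 1.0)
        draw_disk(scratch, (y1, x_px), 0.3 / px, 1.0)
        spine_masks.append(coverage_to_mask(scratch))
        # extent beyond shaft in whole pixels, as the inclusion rule counts it
        extent_px = int(round(ext_um / px))

        for z in range(n_planes):
            zfac = max(1.0 - 0.4 * abs(z - bright_plane), 0.0)
            np.maximum(planes[z], amp_rel * zfac * scratch, out=planes[z])

        rows.append(
            {
                "x_um": xs_um[i],
                "side": side,
                "extent_px": extent_px,
                "extent_um": ext_um,
                "volume": volumes[i],
                "brightest_plane": bright_plane,
            }
        )

    records = pd.DataFrame(
        rows, columns=["x_um", "side", "extent_px", "extent_um", "volume", "brightest_plane"]
    )
    records["klass"] = _volume_quantile_classes(volumes)

    vol = np.stack(planes, axis=0) * shaft_amplitude
    vol = gaussian_filter(vol, (0, 0.18 / px, 0.18 / px))
    if noise_sd > 0:
        vol = vol + rng.normal(0.0, noise_sd, size=vol.shape)

    stack = ImageStack(
        voxels=vol[None, :, :, :].astype(np.float32),
        pixel_size_um=px,
        z_step_um=0.3,
        channel_names=("GFP",),
    )
    return stack, SpineTruth(
        shaft_mask=shaft_mask,
        spine_masks=spine_masks,
        records=records,
        analyzed_length_um=shaft_length_um,
    )


# ---------------------------------------------------------------------------
# expansion microscopy


@dataclass
class ExmTruth:
    cells: pd.DataFrame  # long/short axes pre and post (um), engulfment truth counts
    lysosomes: pd.DataFrame  # cell, center (post um), radius_post_um, peak_plane, psd_positive
    expansion_factor: float


def generate_exm_pair(
    expansion_factor: float,
    scene: EngulfmentSceneParams | None = None,
    pixel_size_post_um: float = 0.155,
    seed: int = 0,
    psd_positive_rate: float = 0.4,
    positive_size_factor: float = 1.0,
) -> tuple[ImageStack, ImageStack, ExmTruth]:
    """Render pre/post expansion image pairs of the same microglia scene.

    The post stack is the pre scene with every physical coordinate scaled
    by ``expansion_factor`` and re-rasterized at the post-expansion pixel
    size.  Lysosomes carry a triangular z-intensity profile around a peak
    plane; a ``psd_positive_rate`` fraction contain a PSD-95 punctum
    co-peaked in z.  PSD-positive lysosomes can be drawn larger via
    ``positive_size_factor``.
    """
    if expansion_factor < 1.0:
        raise ValueError("expansion_factor must be >= 1")
    if scene is None:
        scene = EngulfmentSceneParams(
            roi_size_um=(72.0, 72.0), n_planes=5, n_microglia=8, noise_sd=2.0, seed=seed
        )
    rng = np.random.default_rng(seed)
    n_planes = max(scene.n_planes, 3)
    amp = scene.amplitude

    # grid placement keeps cells disjoint in both renderings
    n = scene.n_microglia
    cols = int(np.ceil(np.sqrt(n)))
    rows_n = int(np.ceil(n / cols))
    wx, wy = scene.roi_size_um[0] / cols, scene.roi_size_um[1] / rows_n

    cell_rows: list[dict] = []
    lys_rows: list[dict] = []
    objects: list[dict] = []
    for i in range(n):
        gy, gx = divmod(i, cols)
        cx = (gx + 0.5) * wx + rng.uniform(-0.1, 0.1) * wx
        cy = (gy + 0.5) * wy + rng.uniform(-0.1, 0.1) * wy
        a = rng.uniform(4.0, 6.5)  # semi-axes um
        b = rng.uniform(3.0, a)
        angle = rng.uniform(0, np.pi)
        lys = []
        n_lys = max(int(rng.poisson(scene.lysosomes_per_microglia)), 1)
        for _ in range(n_lys):
            positive = rng.uniform() < psd_positive_rate
            rad = rng.uniform(0.45, 0.7) * (positive_size_factor if positive else 1.0)
            rho, th = rng.uniform(0, 0.55), rng.uniform(0, 2 * np.pi)
            ly = cy + rho * b * np.sin(th)
            lx = cx + rho * a * np.cos(th)
            peak = int(rng.integers(1, n_planes - 1))
            lys.append(
                {
                    "cell": i,
                    "y_um": ly,
                    "x_um": lx,
                    "radius_um": rad,
                    "peak_plane": peak,
                    "psd_positive": positive,
                }
            )
        objects.append({"center": (cy, cx), "axes": (a, b), "angle": angle, "lysosomes": lys})
        cell_rows.append(
            {
                "cell": i,
                "long_pre_um": 2 * a,
                "short_pre_um": 2 * b,
                "long_post_um": 2 * a * expansion_factor,
                "short_post_um": 2 * b * expansion_factor,
                "n_lysosomes": n_lys,
                "n_psd_positive": sum(l["psd_positive"] for l in lys),
            }
        )
        lys_rows.extend(lys)

    def _render(scale: float, px: float, noise_key: int) -> ImageStack:
        ny = int(round(scene.roi_size_um[1] * scale / px))
        nx = int(round(scene.roi_size_um[0] * scale / px))
        iba = np.zeros((ny, nx), dtype=np.float32)
        cd68 = np.zeros((n_planes, ny, nx), dtype=np.float32)
        psd = np.zeros((n_planes, ny, nx), dtype=np.float32)
        for obj in objects:
            cy, cx = obj["center"]
            a, b = obj["axes"]
            draw_ellipse(
                iba,
                (cy * scale / px, cx * scale / px),
                (a * scale / px, b * scale / px),
                obj["angle"],
                1.0,
            )
            for lys in obj["lysosomes"]:
                ly, lx = lys["y_um"] * scale / px, lys["x_um"] * scale / px
                rad_px = lys["radius_um"] * scale / px
                for z in range(n_planes):
                    zfac = max(1.0 - 0.35 * abs(z - lys["peak_plane"]), 0.0)
                    if zfac <= 0:
                        continue
                    plane = np.zeros((ny, nx), dtype=np.float32)
                    draw_disk(plane, (ly, lx), rad_px, zfac)
                    np.maximum(cd68[z], plane, out=cd68[z])
                    if lys["psd_positive"]:
                        pplane = np.zeros((ny, nx), dtype=np.float32)
                        draw_disk(pplane, (ly, lx), 0.55 * rad_px, zfac)
                        np.maximum(psd[z], pplane, out=psd[z])
        sigma = scene.psf_sigma_um * scale / px if scale == 1.0 else scene.psf_sigma_um / px
        iba3 = np.repeat((amp * gaussian_filter(iba, sigma))[None], n_planes, axis=0)
        cd68 = amp * np.stack([gaussian_filter(p, sigma) for p in cd68])
        psd = amp * np.stack([gaussian_filter(p, sigma) for p in psd])
        vox = np.stack([psd, iba3, cd68], axis=0)
        if scene.noise_sd > 0:
            nrng = np.random.default_rng(seed * 1000 + noise_key)
            vox = vox + nrng.normal(0.0, scene.noise_sd, size=vox.shape)
        return ImageStack(
            voxels=vox.astype(np.float32),
            pixel_size_um=px,
            z_step_um=scene.z_step_um * scale,
            channel_names=("PSD95", "Iba1", "CD68"),
        )

    pre = _render(1.0, scene.pixel_size_um, 1)
    post = _render(expansion_factor, pixel_size_post_um, 2)

    lys_df = pd.DataFrame(lys_rows)
    if not lys_df.empty:
        lys_df["radius_post_um"] = lys_df["radius_um"] * expansion_factor
    truth = ExmTruth(
        cells=pd.DataFrame(cell_rows),
        lysosomes=lys_df,
        expansion_factor=float(expansion_factor),
    )
    return pre, post, truth
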