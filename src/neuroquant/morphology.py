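"""Neuronal morphometry: Sholl analysis, dendritic-tree metrics, soma
measurements, and transcript soma-coverage quantification.

Trees are consumed as SWC reconstructions (node table with parent
links).  Sholl intersections are counted analytically: for each radius
the crossings of the circle by every polyline segment, so a branch
re-entering a shell is counted once per crossing (the convention of the
tracing plugin the field uses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import BinaryMask, PixelGeometry, binarize, pixels_to_um2

__all__ = [
    "NeuronTree",
    "read_swc",
    "sholl",
    "tree_metrics",
    "soma_metrics",
    "soma_transcript_coverage",
]


@dataclass
class NeuronTree:
    """Reconstruction as a node table: id, parent (-1 root), x/y/z um, type.

    The root (soma) is the tree origin; branch order starts at the soma
    and increases after each branch point.
    """

    nodes: pd.DataFrame  # columns: id, type, x, y, z, radius, parent

    def __post_init__(self) -> None:
        need = {"id", "parent", "x", "y", "z"}
        if not need.issubset(self.nodes.columns):
            raise ValueError(f"nodes needs columns {sorted(need)}")
        ids = set(self.nodes["id"])
        parents = self.nodes.set_index("id")["parent"].to_dict()
        roots = [i for i, p in parents.items() if p == -1 or p not in ids]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        self._root = roots[0]
        # acyclicity: walk each node to the root
        for i in ids:
            seen = set()
            j = i
            while j in parents and parents[j] in ids:
                if j in seen:
                    raise ValueError("cyclic parent links")
                seen.add(j)
                j = parents[j]

    @property
    def root_id(self) -> int:
        return self._root

    @property
    def soma_xyz(self) -> np.ndarray:
        r = self.nodes.set_index("id").loc[self._root]
        return np.array([r["x"], r["y"], r["z"]], dtype=float)

    def segments(self) -> np.ndarray:
        """(n, 2, 3) array of parent->child segments in um."""
        idx = self.nodes.set_index("id")
        segs = []
        for _, row in self.nodes.iterrows():
            p = row["parent"]
            if p == -1 or p not in idx.index:
                continue
            pr = idx.loc[p]
            segs.append([[pr["x"], pr["y"], pr["z"]], [row["x"], row["y"], row["z"]]])
        return np.array(segs, dtype=float)

    def children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {int(i): [] for i in self.nodes["id"]}
        for _, row in self.nodes.iterrows():
            if row["parent"] != -1 and row["parent"] in ch:
                ch[int(row["parent"])].append(int(row["id"]))
        return ch


def read_swc(path: str | Path) -> NeuronTree:
    """Read an SWC file (7 whitespace-separated columns, # comments)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 7:
            raise ValueError(f"malformed SWC line: {line!r}")
        rows.append(
            {
                "id": int(parts[0]),
                "type": int(parts[1]),
                "x": float(parts[2]),
                "y": float(parts[3]),
                "z": float(parts[4]),
                "radius": float(parts[5]),
                "parent": int(parts[6]),
            }
        )
    return NeuronTree(nodes=pd.DataFrame(rows))


def sholl(tree: NeuronTree, radius_step_um: float = 10.0, max_radius_um: float | None = None) -> pd.DataFrame:
    """Sholl profile: dendrite crossings of concentric circles at fixed
    radius increments around the soma.

    A segment crossing radius r contributes one intersection per sign
    change of (distance to soma - r) along it; multiple crossings by a
    re-entrant branch count separately.  The sum over radii is attached
    as ``df.attrs['sum_intersections']``.
    """
    if radius_step_um <= 0:
        raise ValueError("radius step must be positive")
    segs = tree.segments()
    soma = tree.soma_xyz
    if len(segs) == 0:
        return pd.DataFrame({"radius_um": [], "intersections": []})
    d0 = np.linalg.norm(segs[:, 0] - soma, axis=1)
    d1 = np.linalg.norm(segs[:, 1] - soma, axis=1)
    rmax = max_radius_um or float(max(d0.max(), d1.max()))
    radii = np.arange(radius_step_um, rmax + radius_step_um, radius_step_um)
    counts = []
    for r in radii:
        # straight segments: distance to soma varies monotonically-in-parts;
        # a crossing exists iff the endpoints straddle r, plus a double
        # crossing when both endpoints are outside but the closest point dips inside
        lo = np.minimum(d0, d1)
        hi = np.maximum(d0, d1)
        n = int(np.sum((lo < r) & (hi >= r)))
        both_out = (d0 >= r) & (d1 >= r)
        if both_out.any():
            a = segs[both_out, 0] - soma
            b = segs[both_out, 1] - soma
            ab = b - a
            L2 = np.einsum("ij,ij->i", ab, ab)
            t = np.where(L2 > 0, -np.einsum("ij,ij->i", a, ab) / np.where(L2 > 0, L2, 1.0), 0.0)
            interior = (t > 0) & (t < 1)
            dmin = np.linalg.norm(a + t[:, None] * ab, axis=1)
            n += 2 * int(np.sum(interior & (dmin < r)))
        counts.append(n)
    df = pd.DataFrame({"radius_um": radii, "intersections": counts})
    df.attrs["sum_intersections"] = int(np.sum(counts))
    return df


def tree_metrics(tree: NeuronTree) -> dict:
    """Total dendritic length, branch/branch-point/end-tip counts, and
    maximum branch order (order starts at the soma, increases after each
    branch point)."""
    segs = tree.segments()
    total_len = float(np.sum(np.linalg.norm(segs[:, 1] - segs[:, 0], axis=1))) if len(segs) else 0.0
    ch = tree.children()
    root = tree.root_id
    tips = [i for i, c in ch.items() if not c and i != root]
    branch_points = [i for i, c in ch.items() if len(c) >= 2 and i != root]

    # branches: maximal unbranched paths; order increments after each branch point
    orders = []
    n_branches = 0
    stack = [(c, 1) for c in ch[root]]
    visited_starts = set()
    while stack:
        node, order = stack.pop()
        if node in visited_starts:
            continue
        visited_starts.add(node)
        n_branches += 1
        orders.append(order)
        cur = node
        while len(ch[cur]) == 1:
            cur = ch[cur][0]
        for c in ch[cur]:
            stack.append((c, order + 1))
    return {
        "total_length_um": total_len,
        "n_branches": n_branches,
        "n_branch_points": len(branch_points),
        "n_end_tips": len(tips),
        "max_branch_order": max(orders) if orders else 0,
    }


def soma_metrics(
    soma_mask: np.ndarray, geom: PixelGeometry, apical_axis_deg: float = 90.0
) -> dict:
    """Soma area (um^2) and diameter (um) perpendicular to the apical axis.

    The diameter is the mask's extent along the direction perpendicular
    to the apical axis: the spread of pixel-center projections plus one
    pixel of width.
    """
    mask = np.asarray(soma_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty soma mask")
    area = pixels_to_um2(mask.sum(), geom)
    theta = np.deg2rad(apical_axis_deg)
    # perpendicular direction in (y, x) image coordinates
    perp = np.array([np.cos(theta), -np.sin(theta)])  # rotate axis by 90 deg
    ys, xs = np.nonzero(mask)
    proj = ys * perp[0] + xs * perp[1]
    diameter = (proj.max() - proj.min() + 1.0) * geom.pixel_size_um
    return {"area_um2": float(area), "diameter_um": float(diameter)}


def soma_transcript_coverage(
    soma_mask: np.ndarray,
    transcript_channel: np.ndarray,
    method: str = "otsu",
    value: float | None = None,
) -> float:
    """Percent of the soma area covered by binarized transcript signal.

    The same threshold settings must be applied across conditions; pass
    method='fixed' with a pinned value for group comparisons.
    """
    mask = np.asarray(soma_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty soma mask")
    bm = binarize(np.asarray(transcript_channel, dtype=float), method=method, value=value)
    return 100.0 * (bm.mask & mask).sum() / mask.sum()
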