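"""File IO: OME-TIFF stacks with physical metadata, HDF5/CSV traces,
trajectory CSVs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .ephys import SweepTrace
from .imaging import ImageStack

__all__ = [
    "write_ome_tiff",
    "read_ome_tiff",
    "write_trace_h5",
    "read_trace_h5",
    "write_trace_csv",
    "read_trace_csv",
]


def write_ome_tiff(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as OME-TIFF with pixel-size and z-step metadata."""
    data = np.asarray(stack.voxels, dtype=np.float32)  # (C, Z, Y, X)
    tifffile.imwrite(
        str(path),
        data.transpose(1, 0, 2, 3),  # OME order ZCYX
        ome=True,
        metadata={
            "axes": "ZCYX",
            "PhysicalSizeX": stack.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.z_step_um,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )


def read_ome_tiff(path: str | Path, sidecar: str | Path | None = None) -> ImageStack:
    """Read an OME-TIFF (or plain TIFF plus a YAML sidecar with
    pixel_size_um / z_step_um / channel_names)."""
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        ome = tf.ome_metadata
    meta: dict = {}
    if ome:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(ome)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        px = root.find(".//ome:Pixels", ns)
        if px is not None:
            meta["pixel_size_um"] = float(px.get("PhysicalSizeX", 0) or 0)
            meta["z_step_um"] = float(px.get("PhysicalSizeZ", 0) or 0)
            meta["channel_names"] = [
                c.get("Name") or f"ch{i}" for i, c in enumerate(px.findall("ome:Channel", ns))
            ]
    if sidecar is not None:
        with open(sidecar) as fh:
            meta.update(yaml.safe_load(fh))
    if not meta.get("pixel_size_um"):
        raise ValueError("no pixel size metadata found; provide a sidecar YAML")

    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:  # ZYX single channel
        arr = arr[:, None]
    # arr now ZCYX
    voxels = np.transpose(arr, (1, 0, 2, 3))
    names = meta.get("channel_names") or [f"ch{i}" for i in range(voxels.shape[0])]
    return ImageStack(
        voxels=voxels,
        pixel_size_um=meta["pixel_size_um"],
        z_step_um=meta.get("z_step_um") or 1.0,
        channel_names=tuple(names),
    )


def write_trace_h5(trace: SweepTrace, path: str | Path) -> None:
    import h5py

    with h5py.File(str(path), "w") as fh:
        ds = fh.create_dataset("data", data=trace.samples)
        fh.attrs["fs_hz"] = trace.fs_hz
        fh.attrs["mode"] = trace.mode
        fh.attrs["command"] = json.dumps(trace.command)


def read_trace_h5(path: str | Path) -> SweepTrace:
    import h5py

    with h5py.File(str(path), "r") as fh:
        return SweepTrace(
            samples=fh["data"][...],
            fs_hz=float(fh.attrs["fs_hz"]),
            mode=str(fh.attrs.get("mode", "voltage_clamp")),
            command=json.loads(fh.attrs.get("command", "{}")),
        )


def write_trace_csv(trace: SweepTrace, path: str | Path) -> None:
    """CSV fallback: time_s,value columns with metadata in '#' header lines."""
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={trace.fs_hz}\n# mode={trace.mode}\n")
        fh.write(f"# command={json.dumps(trace.command)}\n")
        pd.DataFrame({"time_s": trace.time_s, "value": trace.samples}).to_csv(fh, index=False)


def read_trace_csv(path: str | Path) -> SweepTrace:
    meta = {}
    lines = Path(path).read_text().splitlines()
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        key, _, val = line[1:].strip().partition("=")
        meta[key.strip()] = val
        n_header += 1
    import io as _io

    df = pd.read_csv(_io.StringIO("\n".join(lines[n_header:])))
    return SweepTrace(
        samples=df["value"].to_numpy(),
        fs_hz=float(meta.get("fs_hz", 10_000.0)),
        mode=meta.get("mode", "voltage_clamp"),
        command=json.loads(meta.get("command", "{}")),
    )
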