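"""Readers and writers for the package's standard formats.

- OME-TIFF for 2D two-channel images and 3D two-channel stacks (tifffile,
  channel axis labeled, physical pixel sizes in the metadata);
- SWC for neuron reconstructions (standard 7-column dialect, 1-based ids);
- HDF5 for LFP sessions (datasets ``/lfp`` [channels x samples, int16 with a
  per-channel scale], ``/speed``, ``/rewards``; sampling rates as
  attributes);
- CSV for nested tables, segregation curves and epoch logs (pandas).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .engulfment import VoxelStack
from .lfp import LFPSession
from .morphometry import NeuronTree

__all__ = [
    "write_ome_stack",
    "read_ome_stack",
    "write_ome_image",
    "read_ome_image",
    "write_swc",
    "read_swc",
    "write_lfp_h5",
    "read_lfp_h5",
    "write_curve_csv",
    "read_nested_csv",
]


# ---------------------------------------------------------------- OME-TIFF

def write_ome_stack(path, stack: VoxelStack, channel_names=("GFAP", "SYP")) -> None:
    """Write a two-channel 3D stack as OME-TIFF (axes CZYX, sizes in um)."""
    data = np.stack([stack.astro, stack.puncta]).astype(np.float32)
    dz, dy, dx = stack.voxel_size
    tifffile.imwrite(
        str(path),
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": list(channel_names)},
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
        },
    )


def read_ome_stack(path) -> VoxelStack:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta = tf.ome_metadata or ""
    if data.ndim != 4 or data.shape[0] != 2:
        raise ValueError(f"expected a (2, z, y, x) stack, got shape {data.shape}")
    voxel = _physical_sizes(meta, ("Z", "Y", "X"), (0.12, 0.045, 0.045))
    return VoxelStack(data[0], data[1], voxel)


def write_ome_image(path, ipsi: np.ndarray, contra: np.ndarray) -> None:
    """Write a two-channel 2D image (axes CYX; ipsi then contra)."""
    data = np.stack([ipsi, contra])
    tifffile.imwrite(
        str(path), data, ome=True,
        metadata={"axes": "CYX", "Channel": {"Name": ["ipsi", "contra"]}},
    )


def read_ome_image(path) -> tuple[np.ndarray, np.ndarray]:
    data = tifffile.imread(str(path))
    if data.ndim != 3 or data.shape[0] != 2:
        raise ValueError(f"expected a (2, h, w) image, got shape {data.shape}")
    return data[0], data[1]


def _physical_sizes(ome_xml: str, axes, defaults):
    import re

    out = []
    for ax, default in zip(axes, defaults):
        m = re.search(rf'PhysicalSize{ax}="([0-9.eE+-]+)"', ome_xml)
        out.append(float(m.group(1)) if m else default)
    return tuple(out)


# -------------------------------------------------------------------- SWC

def write_swc(path, tree: NeuronTree, comment: str = "") -> None:
    """Standard 7-column SWC (id, type, x, y, z, radius, parent), 1-based ids."""
    lines = []
    if comment:
        lines.append(f"# {comment}")
    lines.append("# id type x y z radius parent")
    for i in range(tree.n_nodes):
        x, y, z = tree.positions[i]
        parent = tree.parents[i] + 1 if tree.parents[i] >= 0 else -1
        lines.append(
            f"{i + 1} {tree.types[i]} {x:.6g} {y:.6g} {z:.6g} "
            f"{tree.radii[i]:.6g} {parent}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path) -> NeuronTree:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"malformed SWC line: {line!r}")
        rows.append(parts)
    if not rows:
        raise ValueError("SWC file contains no nodes")
    ids = np.array([int(r[0]) for r in rows])
    order = np.argsort(ids)
    rows = [rows[i] for i in order]
    index = {int(r[0]): i for i, r in enumerate(rows)}
    positions = np.array([[float(r[2]), float(r[3]), float(r[4])] for r in rows])
    radii = np.array([float(r[5]) for r in rows])
    types = np.array([int(r[1]) for r in rows])
    parents = np.array(
        [index[int(r[6])] if int(r[6]) != -1 else -1 for r in rows], dtype=int
    )
    return NeuronTree(positions, parents, radii, types)


# ------------------------------------------------------------------- HDF5

def write_lfp_h5(path, session: LFPSession) -> None:
    """LFP session to HDF5; samples stored as int16 with per-channel scale."""
    import h5py

    names = list(session.channels)
    data = np.stack([session.channels[n] for n in names])
    peak = np.abs(data).max(axis=1, keepdims=True)
    scale = np.where(peak > 0, peak / 32000.0, 1.0)
    coded = np.round(data / scale).astype(np.int16)
    with h5py.File(str(path), "w") as f:
        d = f.create_dataset("lfp", data=coded)
        d.attrs["channel_names"] = names
        d.attrs["scale"] = scale[:, 0]
        d.attrs["fs"] = session.fs
        s = f.create_dataset("speed", data=session.speed)
        s.attrs["fs"] = session.speed_fs
        f.create_dataset("rewards", data=session.rewards)


def read_lfp_h5(path) -> LFPSession:
    import h5py

    with h5py.File(str(path), "r") as f:
        coded = f["lfp"][...]
        names = [n if isinstance(n, str) else n.decode() for n in f["lfp"].attrs["channel_names"]]
        scale = np.asarray(f["lfp"].attrs["scale"], dtype=float)
        fs = float(f["lfp"].attrs["fs"])
        speed = f["speed"][...]
        speed_fs = float(f["speed"].attrs["fs"])
        rewards = f["rewards"][...]
    channels = {n: coded[i] * scale[i] for i, n in enumerate(names)}
    return LFPSession(channels=channels, fs=fs, speed=speed,
                      speed_fs=speed_fs, rewards=rewards)


# -------------------------------------------------------------------- CSV

def write_curve_csv(path, curve) -> None:
    curve.to_frame().to_csv(path, index=False)


def read_nested_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = {"group", "animal", "value"} - set(frame.columns)
    if missing:
        raise ValueError(f"nested CSV missing columns: {sorted(missing)}")
    return frame


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
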