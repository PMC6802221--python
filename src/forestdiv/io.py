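"""File formats: columnar point clouds, raster bundles, communities, trees.

Point clouds travel as CSV (x, y, z, cls with cls in {ground, vegetation});
backscatter stacks as NPZ array bundles carrying the grid metadata and
ISO-formatted acquisition dates; communities as plot x species CSV plus a
region-label CSV and a Newick tree.  Every ``write_*`` returns the path it
wrote so callers can assemble a manifest.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .synthetic import BackscatterStack, PointCloud, GROUND, VEGETATION

__all__ = [
    "write_point_cloud_csv",
    "read_point_cloud_csv",
    "write_backscatter_bundle",
    "read_backscatter_bundle",
    "write_newick",
    "read_newick",
    "write_manifest",
]

_CLS_TO_NAME = {GROUND: "ground", VEGETATION: "vegetation"}
_NAME_TO_CLS = {v: k for k, v in _CLS_TO_NAME.items()}


def write_point_cloud_csv(pc: PointCloud, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "x": pc.x,
            "y": pc.y,
            "z": pc.z,
            "cls": [_CLS_TO_NAME[c] for c in pc.classification],
        }
    )
    df.to_csv(path, index=False)
    return path


def read_point_cloud_csv(path: str | Path, plot_size: float = 100.0) -> PointCloud:
    df = pd.read_csv(path)
    missing = {"x", "y", "z", "cls"} - set(df.columns)
    if missing:
        raise ValueError(f"point-cloud CSV missing columns: {sorted(missing)}")
    cls = np.array([_NAME_TO_CLS[c] for c in df["cls"]], dtype=np.uint8)
    return PointCloud(
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        z=df["z"].to_numpy(float),
        classification=cls,
        plot_size=plot_size,
    )


def write_backscatter_bundle(stack: BackscatterStack, path: str | Path) -> Path:
    path = Path(path)
    np.savez_compressed(
        path,
        values=stack.values,
        dates=np.array([d.isoformat() for d in stack.dates]),
        pols=np.array(stack.pols),
        origin=np.array(stack.origin),
        cell_size=np.array(stack.cell_size),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_backscatter_bundle(path: str | Path) -> BackscatterStack:
    with np.load(path, allow_pickle=False) as data:
        return BackscatterStack(
            dates=[_dt.date.fromisoformat(str(s)) for s in data["dates"]],
            values=data["values"],
            origin=tuple(float(v) for v in data["origin"]),
            cell_size=float(data["cell_size"]),
            pols=tuple(str(p) for p in data["pols"]),
        )


def write_newick(tree: dendropy.Tree, path: str | Path) -> Path:
    path = Path(path)
    tree.write(path=str(path), schema="newick")
    return path


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_manifest(entries: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
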