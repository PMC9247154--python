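"""Reading and writing volumes, curves and weight logs.

Volumes travel as multi-page TIFF stacks (one page per z-slice) with a JSON
sidecar carrying voxel size, bit depth and provenance; phantom label maps as
8-bit TIFF.  Curves and weight logs are plain CSV with header rows.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .phantom import PhantomResult, Volume

CURVE_COLUMNS = ["time_s", "force_N", "displacement_mm"]
WEIGHT_COLUMNS = ["specimen", "time_h", "stage", "weight_g"]


def save_volume(
    directory: str | Path,
    volume: Volume,
    label_map: np.ndarray | None = None,
    metadata: dict | None = None,
    stem: str = "volume",
) -> Path:
    """Write volume.tif (+ labels.tif) and a JSON sidecar; returns the dir."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / f"{stem}.tif", volume.data)
    sidecar = {
        "voxel_size_um": volume.voxel_size,
        "bit_depth": volume.bit_depth,
        "provenance": volume.provenance,
        "shape_zyx": list(volume.shape),
    }
    if metadata:
        sidecar["metadata"] = metadata
    if label_map is not None:
        tifffile.imwrite(directory / f"{stem}_labels.tif", label_map.astype(np.uint8))
        sidecar["label_map"] = f"{stem}_labels.tif"
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def load_volume(directory: str | Path, stem: str = "volume") -> tuple[Volume, np.ndarray | None, dict]:
    """Inverse of :func:`save_volume`; returns (volume, label_map, metadata)."""
    directory = Path(directory)
    sidecar = json.loads((directory / f"{stem}.json").read_text())
    data = tifffile.imread(directory / f"{stem}.tif")
    volume = Volume(
        data=data,
        voxel_size=float(sidecar["voxel_size_um"]),
        bit_depth=int(sidecar["bit_depth"]),
        provenance=sidecar.get("provenance", str(directory)),
    )
    labels = None
    if "label_map" in sidecar:
        labels = tifffile.imread(directory / sidecar["label_map"])
    return volume, labels, sidecar.get("metadata", {})


def save_phantom(directory: str | Path, result: PhantomResult) -> Path:
    """Persist a phantom result: volume, label map, phase table, metadata."""
    meta = dict(result.metadata)
    meta["phase_table"] = result.phase_table
    return save_volume(directory, result.volume, result.label_map, meta)


def save_curve(path: str | Path, curve_df: pd.DataFrame) -> Path:
    path = Path(path)
    curve_df.to_csv(path, index=False, columns=CURVE_COLUMNS)
    return path


def load_curve(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"curve CSV missing columns: {sorted(missing)}")
    return df


def save_weights(path: str | Path, weights_df: pd.DataFrame) -> Path:
    path = Path(path)
    weights_df.to_csv(path, index=False, columns=WEIGHT_COLUMNS)
    return path


def load_weights(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(WEIGHT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weight CSV missing columns: {sorted(missing)}")
    return df
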