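"""Bone volume fraction (BV/TV) from X-ray-style tomographic volumes.

Pipeline: 3D median filter (radius 2 by default) → global grey-value
threshold interval for bone → BV/TV = bone voxels / specimen voxels, with
the specimen mask (total volume, TV) taken from the background-exclusion
segmentation, since plugs do not fill the field of view.

Two named threshold presets carry the instrument-specific 16-bit intervals:
``next`` = (30375, 65535) and ``4dlab`` = (53500, 65535).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .phantom import Volume

#: Instrument-named bone grey-value intervals for 16-bit images.
THRESHOLD_PRESETS: dict[str, tuple[int, int]] = {
    "next": (30375, 65535),
    "4dlab": (53500, 65535),
}


@dataclass
class BvtvResult:
    bvtv: float
    bone_voxels: int
    total_voxels: int
    threshold: tuple[float, float] | None = None
    filter_radius: int | None = None


def median_filter_volume(
    volume: Volume, radius: int = 2, element: str = "cube"
) -> Volume:
    """3D median filter with a cube (side 2r+1) or ball structuring element.

    Radius 0 is the identity.  The cube element matches common plugin
    behaviour and is the default; ``element='ball'`` uses a digital sphere.
    """
    if radius < 0 or int(radius) != radius:
        raise ValueError("radius must be a non-negative integer")
    if radius == 0:
        return volume
    if element == "cube":
        filtered = ndimage.median_filter(volume.data, size=2 * radius + 1)
    elif element == "ball":
        filtered = ndimage.median_filter(volume.data, footprint=ball(radius))
    else:
        raise ValueError("element must be 'cube' or 'ball'")
    return replace(volume, data=filtered,
                   provenance=f"{volume.provenance}|median_r{radius}_{element}")


def threshold_segment(
    volume: Volume, interval: tuple[float, float] | str
) -> np.ndarray:
    """Boolean bone mask of voxels with low <= grey <= high (inclusive).

    ``interval`` may be a preset name ('next', '4dlab') or an explicit
    (low, high) pair within the volume's bit-depth range.
    """
    if isinstance(interval, str):
        try:
            interval = THRESHOLD_PRESETS[interval]
        except KeyError:
            raise KeyError(
                f"unknown preset {interval!r}; presets: {sorted(THRESHOLD_PRESETS)}"
            ) from None
    low, high = interval
    if low > high:
        raise ValueError(f"inverted threshold interval ({low}, {high})")
    if low < 0 or high > volume.grey_max:
        raise ValueError(
            f"interval ({low}, {high}) outside {volume.bit_depth}-bit range"
        )
    data = volume.data
    return (data >= low) & (data <= high)


def bvtv(
    bone_mask: np.ndarray,
    specimen_mask: np.ndarray,
    threshold: tuple[float, float] | None = None,
    filter_radius: int | None = None,
) -> BvtvResult:
    """Bone volume fraction: bone ∩ specimen voxels over specimen voxels."""
    if bone_mask.shape != specimen_mask.shape:
        raise ValueError("bone and specimen masks must share a shape")
    total = int(specimen_mask.sum())
    if total == 0:
        raise ValueError("specimen mask is empty")
    bone = int((bone_mask & specimen_mask).sum())
    return BvtvResult(
        bvtv=bone / total,
        bone_voxels=bone,
        total_voxels=total,
        threshold=threshold,
        filter_radius=filter_radius,
    )


def bvtv_pipeline(
    volume: Volume,
    specimen_mask: np.ndarray,
    preset: str | tuple[float, float] = "next",
    filter_radius: int = 2,
    element: str = "cube",
) -> BvtvResult:
    """Median filter → threshold → BV/TV in one call."""
    filtered = median_filter_volume(volume, radius=filter_radius, element=element)
    bone = threshold_segment(filtered, preset)
    interval = THRESHOLD_PRESETS[preset] if isinstance(preset, str) else preset
    return bvtv(bone, specimen_mask, threshold=interval, filter_radius=filter_radius)
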