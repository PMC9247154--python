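"""Contrast-to-noise ratio between material phases and noise estimation.

CNR between two regions of interest S1, S2 is

    CNR = |mean(S1) − mean(S2)| / sqrt(sd(S1)² + sd(S2)²)

with sample (n−1) standard deviations.  Image noise is estimated as the
grey-value SD of a region containing only background.  ROIs are rectangular
boxes in named slices so that every number is auditable against the phantom
label map or a real-image screenshot.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import Volume

DEFAULT_MIN_VOXELS = 30


class InsufficientRoiError(ValueError):
    """ROI smaller than the configured voxel floor."""


@dataclass
class RoiSample:
    """Grey values of one single-phase region of interest."""

    label: str
    slice_index: int
    box: tuple[tuple[int, int], tuple[int, int]] | None  # ((r0, r1), (c0, c1)), half-open
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1)) if self.n > 1 else 0.0


@dataclass
class CnrResult:
    pair: tuple[str, str]
    cnr: float
    mean_1: float
    mean_2: float
    sd_1: float
    sd_2: float
    n_1: int
    n_2: int
    slice_index: int | None = None
    degenerate: bool = False


def roi_from_box(
    volume: Volume,
    label: str,
    slice_index: int,
    box: tuple[tuple[int, int], tuple[int, int]],
) -> RoiSample:
    """Extract an ROI from a rectangular box in one z-slice (half-open bounds)."""
    (r0, r1), (c0, c1) = box
    nz, nr, nc = volume.shape
    if not 0 <= slice_index < nz:
        raise IndexError(f"slice_index {slice_index} outside volume")
    if r0 < 0 or c0 < 0 or r1 > nr or c1 > nc or r0 >= r1 or c0 >= c1:
        raise IndexError(f"box {box} outside slice of shape {(nr, nc)}")
    values = np.asarray(volume.data[slice_index, r0:r1, c0:c1], dtype=float)
    return RoiSample(label=label, slice_index=slice_index, box=box, values=values)


def roi_from_labels(
    volume: Volume,
    label_map: np.ndarray,
    phase_index: int,
    label: str,
    slice_index: int,
    erode: int = 2,
) -> RoiSample:
    """ROI of all voxels of one phase in a slice, eroded away from boundaries.

    Convenient on phantoms where the ground-truth label map is available:
    ``erode`` iterations of 3D binary erosion keep the sample clear of the
    blur-affected boundary band (the point spread leaks across slices, so
    the erosion must act in 3D before the slice is taken).
    """
    phase_mask = label_map == phase_index
    if erode > 0:
        phase_mask = ndimage.binary_erosion(phase_mask, iterations=erode)
    mask = phase_mask[slice_index]
    if not mask.any():
        raise InsufficientRoiError(
            f"phase {phase_index} has no interior voxels in slice {slice_index}"
        )
    values = np.asarray(volume.data[slice_index], dtype=float)[mask]
    return RoiSample(label=label, slice_index=slice_index, box=None, values=values)


def _check_floor(roi: RoiSample, min_voxels: int):
    if roi.n < min_voxels:
        raise InsufficientRoiError(
            f"ROI '{roi.label}' has {roi.n} voxels; floor is {min_voxels}"
        )


def estimate_noise(background_roi: RoiSample, min_voxels: int = DEFAULT_MIN_VOXELS) -> float:
    """Noise level as the sample SD of a background-only region."""
    if background_roi.label != "background":
        raise ValueError("noise must be estimated on an ROI labelled 'background'")
    _check_floor(background_roi, min_voxels)
    return background_roi.sd


def cnr(s1: RoiSample, s2: RoiSample, min_voxels: int = DEFAULT_MIN_VOXELS) -> CnrResult:
    """Contrast-to-noise ratio between two ROIs (symmetric in its arguments).

    Degenerate case: both SDs zero — returns 0 for equal means, +inf with
    ``degenerate=True`` for unequal means.
    """
    _check_floor(s1, min_voxels)
    _check_floor(s2, min_voxels)
    num = abs(s1.mean - s2.mean)
    denom = np.hypot(s1.sd, s2.sd)
    if denom == 0:
        value, degenerate = (0.0, False) if num == 0 else (float("inf"), True)
    else:
        value, degenerate = num / denom, False
    slice_index = s1.slice_index if s1.slice_index == s2.slice_index else None
    return CnrResult(
        pair=(s1.label, s2.label),
        cnr=float(value),
        mean_1=s1.mean, mean_2=s2.mean,
        sd_1=s1.sd, sd_2=s2.sd,
        n_1=s1.n, n_2=s2.n,
        slice_index=slice_index,
        degenerate=degenerate,
    )


def cnr_panel(
    volume: Volume,
    rois: list[RoiSample],
    pairs: list[tuple[str, str]],
    min_voxels: int = DEFAULT_MIN_VOXELS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CNR for each requested label pair in every slice holding both labels.

    Returns ``(per_slice, summary)``: one row per (pair, slice), and the
    across-slice aggregation (mean and sample SD over slices) per pair —
    mirroring CNR panels computed over a few representative slices.
    """
    labels_present = {r.label for r in rois}
    for a, b in pairs:
        for lab in (a, b):
            if lab not in labels_present:
                raise KeyError(f"label '{lab}' not present among the supplied ROIs")
    by_slice: dict[int, dict[str, RoiSample]] = {}
    for r in rois:
        by_slice.setdefault(r.slice_index, {})[r.label] = r

    rows = []
    for a, b in pairs:
        for s, here in sorted(by_slice.items()):
            if a in here and b in here:
                res = cnr(here[a], here[b], min_voxels=min_voxels)
                rows.append(
                    {
                        "pair": f"{a}:{b}",
                        "slice": s,
                        "cnr": res.cnr,
                        "mean_1": res.mean_1, "mean_2": res.mean_2,
                        "sd_1": res.sd_1, "sd_2": res.sd_2,
                        "n_1": res.n_1, "n_2": res.n_2,
                        "degenerate": res.degenerate,
                    }
                )
    per_slice = pd.DataFrame(rows)
    if per_slice.empty:
        raise KeyError("no slice contains both labels of any requested pair")
    summary = (
        per_slice.groupby("pair")["cnr"]
        .agg(cnr_mean="mean", cnr_sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
             n_slices="count")
        .reset_index()
    )
    return per_slice, summary
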