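"""Grey-value phase-histogram analysis of plug volumes.

Histograms (250 bins by default) are computed over the specimen interior —
everything that is not exterior background — and inspected for the phase
peaks of neutron images of trabecular bone plugs: void (darkest), bone
tissue, marrow (brightest).  Hydration state shows up as peak presence and
separation: soaked specimens lack the void peak, dried specimens can show a
merging of the bone and marrow peaks.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu

from .phantom import Volume

DEFAULT_BINS = 250
DEFAULT_LABELS = ("void", "bone", "marrow")


class SegmentationError(RuntimeError):
    """Specimen/background separation failed (e.g. background-only volume)."""


@dataclass
class Peak:
    label: str | None
    location: float          # grey value, at a bin center
    bin_index: int
    count: float
    prominence: float


@dataclass
class PhaseHistogram:
    """Grey-value histogram of the specimen interior with peak annotations."""

    bin_edges: np.ndarray
    counts: np.ndarray
    excluded_background: int              # voxels outside the mask
    n_bins: int = DEFAULT_BINS
    peaks: list[Peak] = field(default_factory=list)
    absent: list[str] = field(default_factory=list)
    merged_pairs: list[tuple[str, str]] = field(default_factory=list)
    separation: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def peak(self, label: str) -> Peak | None:
        for p in self.peaks:
            if p.label == label:
                return p
        return None


def specimen_mask(
    volume: Volume,
    closing_radius: int = 2,
    max_valley_frac: float = 0.5,
) -> np.ndarray:
    """Boolean mask of the specimen interior (everything but exterior background).

    Default procedure: take the lowest threshold of a 3-class multi-Otsu
    split (so that a dark specimen rim phase, e.g. marrow in X-ray volumes,
    is not lumped with the background); connected components of the
    below-threshold voxels that touch the volume border form the exterior
    background; the mask is the complement, reduced to its largest connected
    component and morphologically closed.  Interior low-grey structure (air
    voids, dark marrow) stays inside the mask.

    A genuine specimen/background split sits in a histogram valley; if the
    smoothed grey-value density at the chosen threshold exceeds
    ``max_valley_frac`` of the modal density the volume is deemed
    background-only (noise splits a unimodal histogram near its mode) and
    :class:`SegmentationError` is raised.
    """
    data = np.asarray(volume.data, dtype=float)
    if data.size == 0:
        raise SegmentationError("empty volume")
    if data.max() == data.min():
        raise SegmentationError("constant volume; no specimen/background contrast")
    try:
        t = float(threshold_multiotsu(data, classes=3)[0])
    except ValueError:
        t = float(threshold_otsu(data))

    counts, edges = np.histogram(data, bins=256)
    density = np.convolve(counts.astype(float), np.ones(5) / 5.0, mode="same")
    t_bin = int(np.clip(np.searchsorted(edges, t) - 1, 0, len(density) - 1))
    if density[t_bin] > max_valley_frac * density.max():
        raise SegmentationError(
            "no histogram valley at the background threshold; volume appears "
            "to contain background only"
        )

    below = data < t
    if not below.any() or below.all():
        raise SegmentationError("degenerate threshold split")
    lab, n = ndimage.label(below)
    border_labels = set(np.unique(lab[0, :, :])) | set(np.unique(lab[-1, :, :]))
    border_labels |= set(np.unique(lab[:, 0, :])) | set(np.unique(lab[:, -1, :]))
    border_labels |= set(np.unique(lab[:, :, 0])) | set(np.unique(lab[:, :, -1]))
    border_labels.discard(0)
    exterior = np.isin(lab, sorted(border_labels))
    mask = ~exterior

    lab2, n2 = ndimage.label(mask)
    if n2 == 0:
        raise SegmentationError("empty specimen mask")
    sizes = ndimage.sum_labels(np.ones_like(lab2), lab2, index=np.arange(1, n2 + 1))
    mask = lab2 == (1 + int(np.argmax(sizes)))
    if closing_radius > 0:
        size = 2 * closing_radius + 1
        # pad so specimens touching the volume faces are not eroded there
        padded = np.pad(mask, closing_radius, mode="edge")
        padded = ndimage.binary_closing(padded, structure=np.ones((size,) * 3))
        mask = padded[(slice(closing_radius, -closing_radius),) * 3]
    if not mask.any():
        raise SegmentationError("empty specimen mask")
    return mask


def phase_histogram(
    volume: Volume,
    mask: np.ndarray,
    n_bins: int = DEFAULT_BINS,
    value_range: tuple[float, float] | None = None,
) -> PhaseHistogram:
    """Histogram of masked grey values (range = masked min..max by default).

    ``value_range`` fixes the bin range for cross-specimen overlays.
    Conservation holds by construction: counts sum to the mask voxel count.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if mask.shape != volume.shape:
        raise ValueError("mask shape must match the volume")
    vals = np.asarray(volume.data, dtype=float)[mask]
    if vals.size == 0:
        raise ValueError("mask is empty")
    if value_range is None:
        value_range = (float(vals.min()), float(vals.max()))
        if value_range[0] == value_range[1]:
            value_range = (value_range[0] - 0.5, value_range[1] + 0.5)
    counts, edges = np.histogram(vals, bins=n_bins, range=value_range)
    # voxels outside a fixed range would escape the bins; clamp them in
    if counts.sum() != vals.size:
        counts[0] += int((vals < value_range[0]).sum())
        counts[-1] += int((vals > value_range[1]).sum())
    return PhaseHistogram(
        bin_edges=edges,
        counts=counts,
        excluded_background=int(mask.size - mask.sum()),
        n_bins=n_bins,
    )


def _order_preserving_assignment(peak_locs, expected):
    """Order-preserving minimum-distance matching of detected peaks to
    expected labels; surplus peaks stay unlabelled, surplus labels unmatched.

    Returns a dict {peak index -> label index}.
    """
    from itertools import combinations

    k, m = len(peak_locs), len(expected)
    r = min(k, m)
    best, best_cost = {}, np.inf
    for peak_combo in combinations(range(k), r):
        for label_combo in combinations(range(m), r):
            cost = sum(
                abs(peak_locs[pi] - expected[li][1])
                for pi, li in zip(peak_combo, label_combo)
            )
            if cost < best_cost:
                best = dict(zip(peak_combo, label_combo))
                best_cost = cost
    return best


def detect_peaks(
    hist: PhaseHistogram,
    prominence_frac: float = 0.05,
    expected_labels: tuple[str, ...] = DEFAULT_LABELS,
    expected_locations: dict[str, float] | None = None,
    smooth_bins: int = 5,
    merge_max_distance_frac: float = 0.10,
) -> PhaseHistogram:
    """Detect and label phase peaks; annotate absent and merged peaks.

    Local maxima with prominence ≥ ``prominence_frac`` × the modal count are
    kept (counts are lightly box-smoothed over ``smooth_bins`` bins first to
    suppress single-bin shot noise; reported locations remain bin centers).

    Labelling: if the number of detected peaks equals the number of expected
    labels they are assigned in grey-value order (void < bone < marrow).
    Otherwise ``expected_locations`` (e.g. generator phase means, or nominal
    levels from a config) drives an order-preserving minimum-distance
    assignment; unassigned labels are *absent*, except that an unassigned
    label whose expected location lies within ``merge_max_distance_frac`` of
    the histogram range of an assigned peak is reported as *merged* with that
    peak's label.  Zero peaks is a valid result.

    Returns a new PhaseHistogram with peaks/absent/merged/separation filled.
    """
    counts = hist.counts.astype(float)
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        smoothed = np.convolve(counts, kernel, mode="same")
    else:
        smoothed = counts
    from scipy.signal import find_peaks

    if smoothed.max() <= 0:
        idx = np.array([], dtype=int)
        prom = np.array([])
    else:
        idx, props = find_peaks(smoothed, prominence=prominence_frac * smoothed.max())
        prom = props["prominences"]
    centers = hist.bin_centers
    locs = centers[idx] if len(idx) else np.array([])

    peaks = [
        Peak(label=None, location=float(locs[i]), bin_index=int(idx[i]),
             count=float(counts[idx[i]]), prominence=float(prom[i]))
        for i in range(len(idx))
    ]
    absent: list[str] = []
    merged: list[tuple[str, str]] = []

    if len(peaks) == len(expected_labels):
        for p, lab in zip(peaks, expected_labels):
            p.label = lab
    elif expected_locations is not None:
        expected = sorted(
            ((lab, expected_locations[lab]) for lab in expected_labels
             if lab in expected_locations),
            key=lambda t: t[1],
        )
        assign = _order_preserving_assignment([p.location for p in peaks], expected)
        assigned_labels = set()
        for pi, li in assign.items():
            peaks[pi].label = expected[li][0]
            assigned_labels.add(expected[li][0])
        hist_range = float(hist.bin_edges[-1] - hist.bin_edges[0])
        labelled_peaks = [p for p in peaks if p.label is not None]
        for lab, loc in expected:
            if lab in assigned_labels:
                continue
            if labelled_peaks:
                nearest = min(labelled_peaks, key=lambda p: abs(p.location - loc))
                if abs(nearest.location - loc) <= merge_max_distance_frac * hist_range:
                    merged.append(tuple(sorted((lab, nearest.label))))
                    continue
            absent.append(lab)
    else:
        # no reference levels: leave surplus/deficit peaks unlabelled
        if len(peaks) < len(expected_labels):
            for p, lab in zip(peaks, expected_labels[: len(peaks)]):
                p.label = lab
            absent = list(expected_labels[len(peaks):])

    separation: dict[tuple[str, str], float] = {}
    labelled = [p for p in peaks if p.label is not None]
    for a, b in zip(labelled[:-1], labelled[1:]):
        separation[(a.label, b.label)] = separation_score(a, b, hist)

    return PhaseHistogram(
        bin_edges=hist.bin_edges,
        counts=hist.counts,
        excluded_background=hist.excluded_background,
        n_bins=hist.n_bins,
        peaks=peaks,
        absent=absent,
        merged_pairs=merged,
        separation=separation,
    )


def separation_score(peak_a: Peak, peak_b: Peak, hist: PhaseHistogram) -> float:
    """Valley-to-peak contrast between two histogram peaks, in [0, 1].

    1 − (minimum count between the peaks / smaller peak count): 1 for an
    empty valley (fully separated), 0 for no valley at all.
    """
    i, j = sorted((peak_a.bin_index, peak_b.bin_index))
    if i == j:
        raise ValueError("peaks share a bin; separation undefined")
    valley = float(hist.counts[i : j + 1].min())
    smaller = min(peak_a.count, peak_b.count)
    if smaller <= 0:
        raise ValueError("peak with zero count; separation undefined")
    return float(np.clip(1.0 - valley / smaller, 0.0, 1.0))
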