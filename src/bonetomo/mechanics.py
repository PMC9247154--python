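"""Compression mechanics of trabecular bone plugs.

Force-displacement records from unconfined uniaxial compression are
normalized to stress (force / cross-sectional area, MPa) and strain
(displacement / specimen height) after discarding everything before a 15 N
pre-load; failure is the first clear peak of the stress-strain curve, the
elastic modulus is the maximum slope of a sliding least-squares line fit
over the pre-failure data (the "linear portion"), and toughness is the area
under the curve up to failure (MPa · strain ≡ MJ/m³).  Records without a
clear peak are excluded from analysis, mirroring the experimental inclusion
rule.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .phantom import Geometry

DEFAULT_PRELOAD_N = 15.0
DEFAULT_PROMINENCE_FRAC = 0.05
DEFAULT_MODULUS_WINDOW = 0.01   # strain width of the sliding line fit


class PreloadNotReachedError(ValueError):
    """The force record never reaches the pre-load."""


@dataclass
class StressStrainRecord:
    strain: np.ndarray
    stress: np.ndarray          # MPa
    geometry: Geometry
    preload_N: float = DEFAULT_PRELOAD_N
    provenance: str = ""

    def __post_init__(self):
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape:
            raise ValueError("strain and stress must have equal length")


@dataclass
class FailureResult:
    failure_strain: float
    peak_stress: float
    clear_peak: bool


@dataclass
class MechanicalSummary:
    specimen: str
    clear_peak: bool
    peak_stress: float = float("nan")     # MPa
    failure_strain: float = float("nan")
    modulus: float = float("nan")         # MPa
    toughness: float = float("nan")       # MJ/m³
    modulus_window: tuple[float, float] | None = None


def normalize(
    force_N: np.ndarray,
    displacement_mm: np.ndarray,
    geometry: Geometry,
    preload_N: float = DEFAULT_PRELOAD_N,
    provenance: str = "",
) -> StressStrainRecord:
    """Convert a force-displacement record to stress-strain.

    Samples before the force first reaches ``preload_N`` are discarded and
    displacement is re-zeroed at the pre-load crossing (linearly interpolated
    between the bracketing samples, so the strain origin does not snap to the
    sampling grid).  Stress = F / (π d²/4); strain = Δℓ / h.
    """
    force = np.asarray(force_N, dtype=float)
    disp = np.asarray(displacement_mm, dtype=float)
    if force.shape != disp.shape:
        raise ValueError("force and displacement must have equal length")
    reached = np.nonzero(force >= preload_N)[0]
    if reached.size == 0:
        raise PreloadNotReachedError(
            f"force never reaches the {preload_N} N pre-load "
            f"(max {force.max():.3g} N)"
        )
    i = int(reached[0])
    if i == 0:
        d0 = disp[0]
    else:
        f_lo, f_hi = force[i - 1], force[i]
        frac = (preload_N - f_lo) / (f_hi - f_lo) if f_hi != f_lo else 1.0
        d0 = disp[i - 1] + frac * (disp[i] - disp[i - 1])
    area = geometry.area_mm2
    strain = np.concatenate([[0.0], (disp[i:] - d0) / geometry.height_mm])
    stress = np.concatenate([[preload_N / area], force[i:] / area])
    return StressStrainRecord(
        strain=strain, stress=stress, geometry=geometry,
        preload_N=preload_N, provenance=provenance,
    )


def find_failure(
    record: StressStrainRecord,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> FailureResult:
    """First clear peak of the stress-strain curve.

    A peak is "clear" when its prominence exceeds ``prominence_frac`` times
    the global maximum stress; the *first* such local maximum is returned,
    not the global one.  A monotone (or plateauing) curve has no clear peak:
    ``clear_peak=False`` with NaN location — a valid, reportable outcome that
    excludes the specimen from analysis.

    Peak candidates are located on a lightly smoothed curve (quadratic
    Savitzky-Golay) so that sample-level noise cannot masquerade as failure;
    the reported strain and stress are then refined on the raw samples in
    the candidate's neighbourhood.
    """
    stress = record.stress
    n = stress.size
    if n < 10:
        raise ValueError("need at least 10 samples to locate failure")
    span = max(5, n // 25)
    if span % 2 == 0:
        span += 1
    if span < n:
        from scipy.signal import savgol_filter

        smoothed = savgol_filter(stress, span, polyorder=2)
    else:
        smoothed = stress
    peaks, _ = find_peaks(smoothed, prominence=prominence_frac * float(smoothed.max()))
    if peaks.size == 0:
        return FailureResult(float("nan"), float("nan"), False)
    c = int(peaks[0])
    lo, hi = max(0, c - span // 2), min(n, c + span // 2 + 1)
    i = lo + int(np.argmax(stress[lo:hi]))
    return FailureResult(float(record.strain[i]), float(stress[i]), True)


def modulus(
    record: StressStrainRecord,
    window_strain_width: float = DEFAULT_MODULUS_WINDOW,
    failure_strain: float | None = None,
    presmooth: bool = True,
) -> tuple[float, tuple[float, float]]:
    """Elastic modulus as the maximum sliding-window least-squares slope.

    Windows of the given strain width slide over the pre-failure portion
    (everything, when ``failure_strain`` is None or NaN); the steepest
    fitted slope and its window are returned.  The max-slope criterion
    excludes the concave toe region without needing to locate it explicitly.

    With ``presmooth`` the stress is Savitzky-Golay filtered (quadratic,
    span matched to the window sample count) first: taking a maximum over
    many noisy narrow-window slopes is upward-biased, and the quadratic
    smoother is exact on the linear and gently curved portions it slides
    over, so the noiseless result is unchanged.
    """
    strain, stress = record.strain, record.stress
    if failure_strain is not None and np.isfinite(failure_strain):
        sel = strain <= failure_strain
        strain, stress = strain[sel], stress[sel]
    if presmooth and strain.size >= 7:
        step = float(np.median(np.diff(strain)))
        span = int(window_strain_width / max(step, 1e-12)) + 1
        span = min(span, strain.size)
        if span % 2 == 0:
            span -= 1
        if span >= 5:
            from scipy.signal import savgol_filter

            stress = savgol_filter(stress, span, polyorder=2)
    if strain.size < 3 or strain[-1] - strain[0] < window_strain_width:
        raise ValueError("insufficient pre-failure data for the modulus window")
    best_slope, best_window = -np.inf, None
    n = strain.size
    ends = np.searchsorted(strain, strain + window_strain_width, side="right")
    for i0 in range(n):
        i1 = min(int(ends[i0]), n)
        if i1 - i0 < 3:
            continue
        x, y = strain[i0:i1], stress[i0:i1]
        if x[-1] - x[0] < 0.5 * window_strain_width and i1 < n:
            continue
        xm, ym = x.mean(), y.mean()
        denom = float(np.sum((x - xm) ** 2))
        if denom == 0:
            continue
        slope = float(np.sum((x - xm) * (y - ym)) / denom)
        if slope > best_slope:
            best_slope = slope
            best_window = (float(x[0]), float(x[-1]))
    if best_window is None:
        raise ValueError("no window with enough samples for a line fit")
    return best_slope, best_window


def toughness(record: StressStrainRecord, failure_strain: float) -> float:
    """Area under the stress-strain curve up to failure (trapezoidal rule).

    MPa integrated over dimensionless strain equals MJ/m³ exactly.  The
    failure point is included, interpolated if it falls between samples.
    """
    if failure_strain is None or not np.isfinite(failure_strain):
        raise ValueError("toughness requires a failure point (clear peak)")
    strain, stress = record.strain, record.stress
    if failure_strain < strain[0] or failure_strain > strain[-1]:
        raise ValueError("failure_strain outside the record's strain range")
    sel = strain <= failure_strain
    x = strain[sel]
    y = stress[sel]
    if x[-1] < failure_strain:
        x = np.append(x, failure_strain)
        y = np.append(y, np.interp(failure_strain, strain, stress))
    return float(np.trapezoid(y, x))


def summarize(
    record: StressStrainRecord,
    specimen: str = "",
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    window_strain_width: float = DEFAULT_MODULUS_WINDOW,
) -> MechanicalSummary:
    """Failure, modulus and toughness of one record (NaNs if no clear peak)."""
    fail = find_failure(record, prominence_frac=prominence_frac)
    if not fail.clear_peak:
        return MechanicalSummary(specimen=specimen, clear_peak=False)
    mod, window = modulus(
        record, window_strain_width=window_strain_width,
        failure_strain=fail.failure_strain,
    )
    tough = toughness(record, fail.failure_strain)
    return MechanicalSummary(
        specimen=specimen,
        clear_peak=True,
        peak_stress=fail.peak_stress,
        failure_strain=fail.failure_strain,
        modulus=mod,
        toughness=tough,
        modulus_window=window,
    )


def export_analysis_table(
    summaries: list[MechanicalSummary],
    bvtv_by_specimen: dict[str, float],
    group_by_specimen: dict[str, str],
    campaign_by_specimen: dict[str, str],
    response: str = "peak_stress",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the tidy table for external mixed-model fitting.

    One row per included specimen with columns response, log_response
    (natural log), bvtv, bvtv_sq, group, campaign; specimens without a clear
    peak are listed in the second returned frame with the exclusion reason.
    Model fitting itself is out of scope here — the table is the hand-off.
    """
    if response not in ("peak_stress", "modulus", "toughness"):
        raise ValueError("response must be peak_stress, modulus or toughness")
    rows, excluded = [], []
    for s in summaries:
        if not s.clear_peak:
            excluded.append({"specimen": s.specimen, "reason": "no clear peak"})
            continue
        for table, name in (
            (bvtv_by_specimen, "bvtv"),
            (group_by_specimen, "group"),
            (campaign_by_specimen, "campaign"),
        ):
            if s.specimen not in table:
                raise KeyError(
                    f"specimen '{s.specimen}' missing from the {name} table"
                )
        value = getattr(s, response)
        f = bvtv_by_specimen[s.specimen]
        rows.append(
            {
                "specimen": s.specimen,
                "response": value,
                "log_response": float(np.log(value)),
                "bvtv": f,
                "bvtv_sq": f * f,
                "group": group_by_specimen[s.specimen],
                "campaign": campaign_by_specimen[s.specimen],
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(excluded, columns=["specimen", "reason"])
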