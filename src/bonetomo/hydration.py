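"""Specimen weight changes during drying and rehydration.

The weight change of a specimen relative to its initial (pre-drying) state is

    C = (w_after − w_initial) / w_initial × 100   [%]

and the rehydration kinetics are summarized as the fraction of the lost
weight regained at a given time into rehydration,

    R(t) = (w(t) − w_dry) / (w_initial − w_dry) × 100   [%],

linearly interpolated between discrete weighings.  Cohorts are reported as
mean ± sample SD of the per-specimen percent changes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class NoWeightLossError(ValueError):
    """Initial and dried weights coincide; regained fraction is undefined."""


class InsufficientCohortError(ValueError):
    """Fewer than two specimens carry the requested stage."""


@dataclass
class WeightLog:
    """Ordered weighing events for one specimen.

    ``events`` is a list of (time_h, stage, weight_g) with exactly one
    ``initial`` event; stages follow the protocol: initial → drying →
    post-dry → rehydration.
    """

    specimen: str
    events: list[tuple[float, str, float]]

    def __post_init__(self):
        if not self.events:
            raise ValueError("a weight log needs at least one event")
        times = [e[0] for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event timestamps must be non-decreasing")
        if any(e[2] <= 0 for e in self.events):
            raise ValueError("weights must be strictly positive")
        n_initial = sum(1 for e in self.events if e[1] == "initial")
        if n_initial != 1:
            raise ValueError(f"exactly one 'initial' event required, got {n_initial}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, specimen: str | None = None) -> "WeightLog":
        """Build from a tidy frame with columns time_h, stage, weight_g."""
        if specimen is None:
            ids = df["specimen"].unique()
            if len(ids) != 1:
                raise ValueError("frame holds multiple specimens; pass one id")
            specimen = str(ids[0])
        else:
            df = df[df["specimen"] == specimen]
        df = df.sort_values("time_h")
        events = [
            (float(r.time_h), str(r.stage), float(r.weight_g))
            for r in df.itertuples()
        ]
        return cls(specimen=specimen, events=events)

    def weight_at_stage(self, stage: str) -> float | None:
        for _, s, w in self.events:
            if s == stage:
                return w
        return None

    @property
    def initial_weight(self) -> float:
        return next(w for _, s, w in self.events if s == "initial")


def percent_change(w_initial: float, w_after: float) -> float:
    """Relative weight change in percent: (w_after − w_initial)/w_initial × 100."""
    if w_initial <= 0:
        raise ValueError("w_initial must be strictly positive")
    return (w_after - w_initial) / w_initial * 100.0


def fraction_regained(log: WeightLog, at_time: float) -> float:
    """Percent of drying weight loss regained ``at_time`` hours into rehydration.

    0% at the dried weight, 100% at full recovery of the initial weight;
    linear interpolation between the bracketing weighings (the post-dry event
    anchors rehydration time zero).  Raises :class:`NoWeightLossError` when
    drying removed no weight.
    """
    w0 = log.initial_weight
    w_dry = log.weight_at_stage("post-dry")
    if w_dry is None:
        raise ValueError("log has no 'post-dry' event")
    if w0 == w_dry:
        raise NoWeightLossError("no weight lost during drying; fraction undefined")
    t_dry = next(t for t, s, _ in log.events if s == "post-dry")
    times = [0.0]
    weights = [w_dry]
    for t, s, w in log.events:
        if s.startswith("rehydration") and t >= t_dry:
            times.append(t - t_dry)
            weights.append(w)
    if at_time < 0 or at_time > times[-1]:
        raise ValueError(
            f"at_time {at_time} h outside the rehydration record (0..{times[-1]} h)"
        )
    w_t = float(np.interp(at_time, times, weights))
    return (w_t - w_dry) / (w0 - w_dry) * 100.0


@dataclass
class CohortSummary:
    stage: str
    mean_percent: float
    sd_percent: float
    n: int
    excluded: list[str]


def cohort_summary(logs: list[WeightLog], stage: str) -> CohortSummary:
    """Mean ± sample SD of per-specimen percent weight change at one stage.

    Specimens missing the stage are listed as excluded (not fatal); fewer
    than two usable specimens raises :class:`InsufficientCohortError`.
    """
    changes, excluded = [], []
    for log in logs:
        w = log.weight_at_stage(stage)
        if w is None:
            excluded.append(log.specimen)
            continue
        changes.append(percent_change(log.initial_weight, w))
    if len(changes) < 2:
        raise InsufficientCohortError(
            f"need >= 2 specimens with stage '{stage}', got {len(changes)}"
        )
    arr = np.asarray(changes)
    return CohortSummary(
        stage=stage,
        mean_percent=float(arr.mean()),
        sd_percent=float(arr.std(ddof=1)),
        n=len(changes),
        excluded=excluded,
    )
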