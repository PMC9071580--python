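"""LOH accumulation in nongrowing (starving) cells.

Starving cultures are sampled at a handful of timepoints (days 3, 7, 14,
21 by default); at each, one plating on nonselective medium counts viable
cells and one on selective medium counts LOH mutants. The mutant
frequency among survivors is regressed on time measured in 2-hour units
(one unit ~ one cell doubling under growth conditions), so the slope is
directly comparable to a per-division rate: the growing/starving ratio is
the sum of per-division rates over a segment panel divided by the sum of
per-2 h slopes over the same panel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genome import Segment
from .rates import RateEstimate

__all__ = [
    "StarvationSeries",
    "TimeRateEstimate",
    "UNITS_PER_DAY",
    "days_to_units",
    "mutant_frequency_series",
    "fit_time_rate",
    "starving_growing_ratio",
    "control_stability",
    "StarvationRateModel",
    "StarvationResults",
]

UNITS_PER_DAY = 12  # 2-hour units per day


def days_to_units(days) -> np.ndarray:
    return np.asarray(days, dtype=float) * UNITS_PER_DAY


@dataclass(frozen=True)
class StarvationSeries:
    """Time-stamped viable and mutant colony counts for one strain.

    ``viable_sampled_fraction`` / ``mutant_sampled_fraction`` are the
    fractions of the culture plated on the nonselective and selective
    media respectively; frequencies are ratios of the two independent
    platings after rescaling by these fractions.
    """

    strain: str
    timepoints: tuple[float, ...]  # days since starvation onset
    viable_counts: tuple[int, ...]
    mutant_counts: tuple[int, ...]
    viable_sampled_fraction: float
    mutant_sampled_fraction: float
    segment: Segment | None = None
    segment_name: str = ""
    medium: str = "FG"

    def __post_init__(self) -> None:
        t = self.timepoints
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if len(self.viable_counts) != len(t) or len(self.mutant_counts) != len(t):
            raise ValueError("counts must align with timepoints")
        if any(c < 0 for c in self.viable_counts + self.mutant_counts):
            raise ValueError("counts must be non-negative")
        for frac in (self.viable_sampled_fraction, self.mutant_sampled_fraction):
            if not (0 < frac <= 1):
                raise ValueError("sampled fractions must be in (0, 1]")

    @property
    def label(self) -> str:
        seg = self.segment.name if self.segment is not None else (self.segment_name or "?")
        return f"{self.strain or '?'}:{seg}:{self.medium}"


@dataclass(frozen=True)
class TimeRateEstimate:
    """OLS slope of mutant frequency on time in 2-hour units."""

    slope: float  # frequency gain per 2 h among survivors
    intercept: float
    slope_se: float
    pvalue: float
    n_points: int
    strain: str = ""
    segment_name: str = ""
    medium: str = "FG"


def mutant_frequency_series(series: StarvationSeries) -> np.ndarray:
    """Mutant frequency among viable cells at each timepoint.

    frequency_t = (mutants / mutant fraction) / (viable / viable fraction);
    a zero viable count leaves the frequency undefined and raises.
    """
    viable = np.asarray(series.viable_counts, dtype=float)
    if np.any(viable == 0):
        bad = [t for t, v in zip(series.timepoints, viable) if v == 0]
        raise ValueError(
            f"{series.label}: zero viable count at day(s) {bad}; frequency undefined"
        )
    mutant = np.asarray(series.mutant_counts, dtype=float)
    return (mutant / series.mutant_sampled_fraction) / (
        viable / series.viable_sampled_fraction
    )


def fit_time_rate(
    frequencies: Sequence[float], timepoints_units: Sequence[float]
) -> TimeRateEstimate:
    """OLS of mutant frequency on time in 2-hour units (with intercept:
    mutants accumulated during prior growth exist at t = 0). The slope is
    the per-2 h LOH rate among survivors."""
    f = np.asarray(frequencies, dtype=float)
    t = np.asarray(timepoints_units, dtype=float)
    if f.size != t.size:
        raise ValueError("frequencies and timepoints differ in length")
    if f.size < 3:
        raise ValueError("need at least 3 timepoints for the time regression")
    res = stats.linregress(t, f)
    return TimeRateEstimate(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        pvalue=float(res.pvalue),
        n_points=f.size,
    )


def fit_series(series: StarvationSeries) -> TimeRateEstimate:
    """Convenience: frequencies from the series, days converted to 2-h
    units, then :func:`fit_time_rate`."""
    freqs = mutant_frequency_series(series)
    est = fit_time_rate(freqs, days_to_units(series.timepoints))
    return TimeRateEstimate(
        slope=est.slope,
        intercept=est.intercept,
        slope_se=est.slope_se,
        pvalue=est.pvalue,
        n_points=est.n_points,
        strain=series.strain,
        segment_name=series.segment.name if series.segment else series.segment_name,
        medium=series.medium,
    )


def starving_growing_ratio(
    growing: Mapping[str, RateEstimate],
    starving: Mapping[str, TimeRateEstimate],
    exclude: Sequence[str] = (),
) -> float:
    """Per-unit-time rate ratio between growth and starvation.

    ratio = (sum of per-division growing rates) / (sum of per-2 h starving
    slopes) over the segments common to both panels after exclusions, one
    division ~ 2 h. Negative starving slopes are floored at 0 with a
    warning; an all-zero denominator yields ``inf``.
    """
    excl = set(exclude)
    common = sorted((set(growing) & set(starving)) - excl)
    if not common:
        raise ValueError("no common segments between growing and starving panels")
    num = sum(growing[k].mu for k in common)
    den = 0.0
    for k in common:
        slope = starving[k].slope
        if slope < 0:
            warnings.warn(
                f"segment {k}: negative starvation slope {slope:.3g} floored at 0",
                stacklevel=2,
            )
            slope = 0.0
        den += slope
    if den == 0:
        warnings.warn("all starving slopes zero: ratio is non-finite", stacklevel=2)
        return math.inf
    return num / den


def control_stability(
    ratio_series: Sequence[float],
    timepoints: Sequence[float],
    alpha: float = 0.05,
) -> tuple[float, float, bool]:
    """Slope and p-value of a survival-ratio control series over time.

    Used for the mutant-vs-progenitor survival and plating-efficiency
    controls: a ``stable`` verdict (p > alpha) means no time trend was
    detected. Returns ``(slope, pvalue, stable)``.
    """
    r = np.asarray(ratio_series, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    if r.size != t.size:
        raise ValueError("series and timepoints differ in length")
    if r.size < 3:
        raise ValueError("need at least 3 timepoints")
    if np.allclose(r, r[0]):
        return 0.0, 1.0, True
    res = stats.linregress(t, r)
    return float(res.slope), float(res.pvalue), bool(res.pvalue > alpha)


class StarvationRateModel:
    """Statsmodels-style wrapper for one starvation time course."""

    def __init__(self, series: StarvationSeries):
        self.series = series

    def fit(self) -> "StarvationResults":
        return StarvationResults(self, fit_series(self.series))


@dataclass
class StarvationResults:
    model: StarvationRateModel
    estimate: TimeRateEstimate

    @property
    def slope(self) -> float:
        return self.estimate.slope

    def summary(self) -> str:
        e = self.estimate
        s = self.model.series
        return "\n".join(
            [
                "Starvation LOH time-course fit",
                "=" * 46,
                f"strain/segment/medium : {s.label}",
                f"timepoints (days)     : {list(s.timepoints)}",
                f"slope (per 2 h)       : {e.slope:.4e}  (se {e.slope_se:.2e})",
                f"intercept (frequency) : {e.intercept:.4e}",
                f"slope p-value         : {e.pvalue:.3g}",
            ]
        )
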