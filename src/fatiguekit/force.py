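"""Handgrip-force quantification.

Three primitives drive the fatiguing-task analysis:

* cue-driven segmentation of the force trace into 1 s contraction windows,
* the FWHM-median summary of a maximum voluntary contraction (MVC): the
  median force between the first and last crossings of half the
  baseline-corrected peak, and
* the fatigue slope: the ordinary-least-squares regression coefficient of
  per-contraction area under the curve (AUC) on contraction index, after
  discarding an initial familiarisation block.  A negative slope indicates
  declining force output — the operational marker of muscle fatigue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io import CueSchedule, TimeSeries

__all__ = [
    "ContractionSegment",
    "MVCEstimate",
    "SlopeEstimate",
    "TargetForce",
    "segment_contractions",
    "fwhm_median",
    "mvc_best_of_three",
    "contraction_auc",
    "fatigue_slope",
]


@dataclass(frozen=True)
class ContractionSegment:
    """One cued contraction window sliced out of a force or envelope trace."""

    index: int
    samples: TimeSeries


@dataclass(frozen=True)
class MVCEstimate:
    """FWHM-median summary of a maximal contraction profile.

    ``median_force`` is the median of the baseline-corrected samples between
    the interpolated half-maximum crossings ``fwhm_start``/``fwhm_end``.
    """

    median_force: float
    fwhm_start: float
    fwhm_end: float
    source: str = "single"  # "single" or "best_of_3"


@dataclass(frozen=True)
class SlopeEstimate:
    """OLS fit of per-contraction AUC on contraction index."""

    beta: float
    intercept: float
    n_points: int
    residual_se: float
    stderr: float  # standard error of beta


@dataclass(frozen=True)
class TargetForce:
    """Fatiguing-task force target as a percentage of baseline MVC."""

    pct: int
    absolute: float

    def __post_init__(self) -> None:
        if self.pct not in (5, 50, 75):
            raise ValueError("pct must be one of 5, 50, 75")
        if self.absolute <= 0:
            raise ValueError("absolute target force must be > 0")

    @classmethod
    def from_mvc(cls, pct: int, baseline_mvc: float) -> "TargetForce":
        return cls(pct=pct, absolute=pct / 100.0 * baseline_mvc)


def segment_contractions(trace: TimeSeries, schedule: CueSchedule) -> list[ContractionSegment]:
    """Slice a trace into one segment per cue window.

    Windows come from the schedule (the protocol is visually prompted, so
    segmentation is cue-driven rather than threshold-driven).  Each segment
    holds ``round(rate * on_duration)`` samples starting at the sample nearest
    the cue onset.
    """
    segments: list[ContractionSegment] = []
    for k, (start, end) in enumerate(schedule.cycles):
        i0 = round((start - trace.t0) * trace.rate)
        n = round(trace.rate * (end - start))
        if i0 < 0 or i0 + n > trace.n:
            raise IndexError(
                f"cue window {k} [{start}, {end}] s lies outside the trace "
                f"extent [{trace.t0}, {trace.t_end}] s"
            )
        seg = TimeSeries(
            t0=trace.t0 + i0 / trace.rate,
            rate=trace.rate,
            values=trace.values[i0 : i0 + n],
            units=trace.units,
            channel=trace.channel,
        )
        segments.append(ContractionSegment(index=k, samples=seg))
    return segments


def _edge_baseline(values: np.ndarray, frac: float = 0.10) -> float:
    """Resting-force baseline: minimum over the first and last ``frac`` of samples."""
    k = max(1, int(round(frac * values.size)))
    return float(min(values[:k].min(), values[-k:].min()))


def fwhm_median(profile: TimeSeries) -> MVCEstimate:
    """Median force between the full-width-at-half-maximum points of a contraction.

    The profile is baseline-corrected by the minimum of its leading/trailing
    10% of samples; half-maximum crossings are located by linear interpolation
    between the bracketing samples; the median is taken over the samples lying
    inside the crossings (bracketing inner samples included).

    Raises
    ------
    ValueError
        If the profile has no positive peak above baseline.
    """
    v = np.asarray(profile.values, dtype=float)
    if np.any(~np.isfinite(v)):
        raise ValueError("profile contains non-finite samples")
    baseline = _edge_baseline(v)
    corr = v - baseline
    peak_idx = int(np.argmax(corr))
    peak = corr[peak_idx]
    if peak <= 0:
        raise ValueError("profile has no positive peak above baseline")
    half = peak / 2.0

    def _interp_cross(i_lo: int, i_hi: int) -> float:
        """Fractional index where ``corr`` crosses ``half`` between two samples."""
        lo, hi = corr[i_lo], corr[i_hi]
        if hi == lo:
            return float(i_hi)
        return i_lo + (half - lo) / (hi - lo) * (i_hi - i_lo)

    above = corr >= half
    first = int(np.argmax(above))
    last = int(len(corr) - 1 - np.argmax(above[::-1]))
    x_start = float(first) if first == 0 else _interp_cross(first - 1, first)
    x_end = float(last) if last == len(corr) - 1 else _interp_cross(last + 1, last)
    if x_end < x_start:
        x_start, x_end = x_end, x_start

    i_first = int(math.ceil(x_start - 1e-12))
    i_last = int(math.floor(x_end + 1e-12))
    median = float(np.median(corr[i_first : i_last + 1]))
    dt = 1.0 / profile.rate
    return MVCEstimate(
        median_force=median,
        fwhm_start=profile.t0 + x_start * dt,
        fwhm_end=profile.t0 + x_end * dt,
        source="single",
    )


def mvc_best_of_three(profiles: Sequence[TimeSeries]) -> MVCEstimate:
    """Best-of-three MVC: the highest of the per-contraction FWHM medians."""
    if len(profiles) == 0:
        raise ValueError("need at least one MVC profile")
    estimates = [fwhm_median(p) for p in profiles]
    best = max(estimates, key=lambda e: e.median_force)
    return MVCEstimate(
        median_force=best.median_force,
        fwhm_start=best.fwhm_start,
        fwhm_end=best.fwhm_end,
        source="best_of_3",
    )


def contraction_auc(segment: ContractionSegment) -> float:
    """Trapezoidal area under the raw force curve over one contraction window.

    Units are force x seconds.  No baseline correction is applied.
    """
    v = segment.samples.values
    if v.size == 0:
        raise ValueError("empty segment")
    if np.any(~np.isfinite(v)):
        raise ValueError(f"segment {segment.index} contains non-finite samples")
    return float(np.trapezoid(v, dx=1.0 / segment.samples.rate))


def fatigue_slope(aucs: Sequence[float], discard_first: int = 10) -> SlopeEstimate:
    """OLS slope of per-contraction AUC on contraction index.

    The first ``discard_first`` contractions are treated as familiarisation
    and excluded; for the standard 270-contraction protocol this leaves 260
    points.  The regressor is the original (0-based) contraction index, so the
    slope is in AUC units per contraction.
    """
    y = np.asarray(aucs, dtype=float)
    if discard_first < 0:
        raise ValueError("discard_first must be >= 0")
    if y.size <= discard_first + 1:
        raise ValueError(
            f"need more than {discard_first + 1} AUC values, got {y.size}"
        )
    if np.any(~np.isfinite(y)):
        raise ValueError("AUC series contains non-finite values")
    x = np.arange(y.size, dtype=float)[discard_first:]
    y = y[discard_first:]
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    dof = y.size - 2
    residual_se = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else float("nan")
    return SlopeEstimate(
        beta=float(res.slope),
        intercept=float(res.intercept),
        n_points=int(y.size),
        residual_se=residual_se,
        stderr=float(res.stderr),
    )
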