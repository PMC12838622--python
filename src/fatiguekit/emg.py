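"""Surface-EMG processing: bandpass filtering, envelope extraction and
per-contraction fatigue slopes.

The pipeline mirrors the force analysis: the raw EMG is bandpass filtered
(10-500 Hz, 4th-order Butterworth, applied forward-backward so contraction
windows stay aligned), an amplitude envelope is computed, and during the
fatiguing task the envelope is reduced to per-contraction AUCs whose OLS
slope indexes the drift of muscle activity.  During the assessment task the
envelope is summarised by its median over the task window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .force import SlopeEstimate, contraction_auc, fatigue_slope, segment_contractions
from .io import CueSchedule, TimeSeries

__all__ = [
    "EnvelopeTrace",
    "bandpass_emg",
    "emg_envelope",
    "emg_ft_slope",
    "emg_at_median",
]

#: leading/trailing guard excluded from envelope statistics (filter edge effects)
EDGE_GUARD_S = 0.1


@dataclass
class EnvelopeTrace:
    """Non-negative amplitude envelope of a bandpassed EMG trace."""

    series: TimeSeries
    method: str
    edge_guard_s: float = EDGE_GUARD_S

    def __post_init__(self) -> None:
        if np.any(self.series.values < 0):
            raise ValueError("envelope values must be non-negative")


def bandpass_emg(
    trace: TimeSeries, low: float = 10.0, high: float = 500.0, order: int = 4
) -> TimeSeries:
    """Zero-phase Butterworth bandpass (default 10-500 Hz, 4th order).

    Forward-backward application doubles the effective order but keeps zero
    group delay, so cue windows need no lag compensation.

    Raises
    ------
    ValueError
        If the sampling rate does not satisfy ``rate > 2 * high`` (Nyquist).
    """
    if trace.rate <= 2.0 * high:
        raise ValueError(
            f"sampling rate {trace.rate} Hz too low for a {high} Hz band edge "
            f"(need rate > {2 * high} Hz)"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=trace.rate, output="sos")
    return trace.with_values(signal.sosfiltfilt(sos, trace.values))


def emg_envelope(trace: TimeSeries, method: str = "hilbert") -> EnvelopeTrace:
    """Amplitude envelope of an (already bandpassed) EMG trace.

    ``method="hilbert"`` (default) takes the magnitude of the analytic signal;
    ``method="rectify_lowpass"`` rectifies and low-passes at 6 Hz
    (2nd-order Butterworth, zero-phase), clipping tiny filter undershoot at 0.
    Both are non-negative and preserve the input rate and length.
    """
    v = trace.values
    if method == "hilbert":
        env = np.abs(signal.hilbert(v))
    elif method == "rectify_lowpass":
        sos = signal.butter(2, 6.0, btype="lowpass", fs=trace.rate, output="sos")
        env = np.clip(signal.sosfiltfilt(sos, np.abs(v)), 0.0, None)
    else:
        raise ValueError(f"unknown envelope method {method!r}")
    return EnvelopeTrace(series=trace.with_values(env), method=method)


def emg_ft_slope(
    envelope: EnvelopeTrace, schedule: CueSchedule, discard_first: int = 10
) -> SlopeEstimate:
    """Fatiguing-task EMG slope: per-contraction envelope AUCs regressed on index.

    Runs the identical segmentation/AUC/OLS pipeline used for force, applied
    to the envelope trace.
    """
    segments = segment_contractions(envelope.series, schedule)
    aucs = [contraction_auc(seg) for seg in segments]
    return fatigue_slope(aucs, discard_first=discard_first)


def emg_at_median(envelope: EnvelopeTrace, t_start: float, t_end: float) -> float:
    """Median of the envelope over the assessment-task window.

    The first/last ``edge_guard_s`` of the *session* are excluded (filter and
    Hilbert edge effects); interior windows are unaffected.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    s = envelope.series
    lo = max(t_start, s.t0 + envelope.edge_guard_s)
    hi = min(t_end, s.t_end - envelope.edge_guard_s)
    if hi <= lo:
        raise ValueError("window is empty after edge-guard trimming")
    window = s.slice_time(lo, hi)
    return float(np.median(window.values))
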