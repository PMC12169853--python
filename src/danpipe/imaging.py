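"""dF/F normalization and peak-window quantification of calcium traces.

Raw GCaMP fluorescence recorded at a nominal 30 Hz is normalized to the
mean baseline F0 over the 10 s preceding stimulus onset,

    dF/F = (F - F0) / F0,

and each larva's response is summarized as the mean dF/F over a 5-s
window around the peak of |dF/F| inside the stimulus window.  Taking
the extremum of the absolute trace lets the same operator quantify both
calcium increases and stimulus-evoked reductions.  The group-level test
compares per-larva window means against chance level 0 with a one-sample
t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


class TraceError(ValueError):
    """Raised on malformed fluorescence traces."""


@dataclass(frozen=True)
class FluorescenceTrace:
    """Raw fluorescence of one larva with a marked stimulus window."""

    times: np.ndarray           # s, strictly increasing
    values: np.ndarray          # raw fluorescence, arbitrary units
    stimulus_onset: float       # s
    stimulus_offset: float      # s
    larva_id: str = ""
    stimulus_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or t.shape != v.shape:
            raise TraceError("times and values must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise TraceError("times must be strictly increasing")
        if not self.stimulus_onset < self.stimulus_offset:
            raise TraceError("stimulus_onset must precede stimulus_offset")


@dataclass(frozen=True)
class NormalizedTrace:
    """dF/F time series with the stimulus window carried over."""

    times: np.ndarray
    dff: np.ndarray
    baseline_mean: float        # F0, raw units
    stimulus_onset: float
    stimulus_offset: float
    larva_id: str = ""
    stimulus_label: str = ""


@dataclass(frozen=True)
class ResponseSummary:
    """Per-larva 5-s peak-window response."""

    larva_id: str
    stimulus_label: str
    peak_time: float            # s, within the stimulus window
    window_mean: float          # mean dF/F over the peak window
    direction: str              # "increase" | "decrease"


@dataclass(frozen=True)
class GroupResponse:
    mean: float
    sem: float
    p_value: float
    n: int
    significant: bool
    direction: str


def compute_dff(trace: FluorescenceTrace, baseline_s: float = 10.0) -> NormalizedTrace:
    """Normalize a trace to its pre-stimulus baseline.

    F0 is the mean raw fluorescence over [onset - baseline_s, onset);
    dF/F = (F - F0)/F0 at every sample.  The trace must cover the full
    baseline window and F0 must be positive.
    """
    t0 = trace.stimulus_onset - baseline_s
    if trace.times.size == 0 or trace.times[0] > t0:
        raise TraceError(
            f"trace must cover the baseline window "
            f"[{t0:.3f}, {trace.stimulus_onset:.3f}) s before stimulus onset"
        )
    mask = (trace.times >= t0) & (trace.times < trace.stimulus_onset)
    if not mask.any():
        raise TraceError("no samples fall inside the baseline window")
    f0 = float(np.mean(trace.values[mask]))
    if f0 <= 0:
        raise TraceError(f"baseline mean F0 must be positive, got {f0:.6g}")
    return NormalizedTrace(
        times=trace.times,
        dff=(trace.values - f0) / f0,
        baseline_mean=f0,
        stimulus_onset=trace.stimulus_onset,
        stimulus_offset=trace.stimulus_offset,
        larva_id=trace.larva_id,
        stimulus_label=trace.stimulus_label,
    )


def _window_mean(times: np.ndarray, values: np.ndarray, lo: float, hi: float) -> float:
    """Mean of values over [lo, hi]; time-weighted if sampling is irregular."""
    mask = (times >= lo) & (times <= hi)
    t, v = times[mask], values[mask]
    if t.size == 0:
        raise TraceError(f"no samples inside window [{lo:.3f}, {hi:.3f}] s")
    if t.size == 1:
        return float(v[0])
    dt = np.diff(t)
    if np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        return float(np.mean(v))
    return float(np.trapezoid(v, t) / (t[-1] - t[0]))


def peak_response(ntrace: NormalizedTrace, window_s: float = 5.0) -> ResponseSummary:
    """Summarize a normalized trace by its 5-s peak-window mean.

    The peak is the extremum of |dF/F| within the stimulus window (so
    reductions are captured with the same operator).  The averaging
    window is 5 s around the peak, kept inside the stimulus
    presentation: when the stimulus lasts at least ``window_s`` the
    window is shifted (not truncated) to fit, so a peak near the
    stimulus edge does not pull baseline or washout samples into the
    average; for shorter stimuli it falls back to centered-and-clipped
    with a logged warning.  Direction is the sign of dF/F at the peak.
    """
    mask = (ntrace.times >= ntrace.stimulus_onset) & (
        ntrace.times <= ntrace.stimulus_offset
    )
    if not mask.any():
        raise TraceError("stimulus window contains no samples")
    idx = np.flatnonzero(mask)
    absdff = np.abs(ntrace.dff[idx])
    # ties (e.g. a noise-free plateau) resolve to the middle tied sample,
    # centering the averaging window on the plateau rather than its edge
    tied = np.flatnonzero(absdff == absdff.max())
    peak_idx = idx[tied[len(tied) // 2]]
    peak_time = float(ntrace.times[peak_idx])
    onset, offset = ntrace.stimulus_onset, ntrace.stimulus_offset
    if offset - onset >= window_s:
        lo = max(onset, min(peak_time - window_s / 2.0, offset - window_s))
        hi = lo + window_s
    else:
        logger.warning(
            "stimulus (%.2f s) shorter than the %.2f s averaging window; "
            "falling back to a centered window", offset - onset, window_s,
        )
        lo, hi = peak_time - window_s / 2.0, peak_time + window_s / 2.0
    span_lo, span_hi = float(ntrace.times[0]), float(ntrace.times[-1])
    if lo < span_lo or hi > span_hi:
        logger.warning(
            "peak window [%.2f, %.2f] s clipped to trace span [%.2f, %.2f] s",
            lo, hi, span_lo, span_hi,
        )
        lo, hi = max(lo, span_lo), min(hi, span_hi)
    wmean = _window_mean(ntrace.times, ntrace.dff, lo, hi)
    direction = "increase" if ntrace.dff[peak_idx] >= 0 else "decrease"
    return ResponseSummary(
        larva_id=ntrace.larva_id,
        stimulus_label=ntrace.stimulus_label,
        peak_time=peak_time,
        window_mean=wmean,
        direction=direction,
    )


def group_response_test(
    summaries: list[ResponseSummary], alpha: float = 0.05
) -> GroupResponse:
    """One-sample t-test of per-larva window means against chance level 0."""
    if len(summaries) < 3:
        raise TraceError("at least 3 larvae required for the group test")
    x = np.array([s.window_mean for s in summaries], dtype=float)
    mean = float(np.mean(x))
    sem = float(stats.sem(x))
    p = float(stats.ttest_1samp(x, 0.0).pvalue)
    return GroupResponse(
        mean=mean,
        sem=sem,
        p_value=p,
        n=x.size,
        significant=p < alpha,
        direction="increase" if mean >= 0 else "decrease",
    )
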