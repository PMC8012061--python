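"""Amperometric spike detection and shape analysis.

Catecholamine release from single vesicles is detected as current spikes at
a carbon-fiber electrode.  After subtraction of the flash photoelectric
artifact and Gaussian low-pass filtering (500 Hz cut-off), spikes are
threshold-detected at 5 pA and characterised by peak current (I_max), total
charge (Q, by integration; pA*s = pC), duration at half maximum (t_1/2),
baseline-to-baseline duration, 50-90% rise time, 75-25% decay time, and the
foot signal - the small pre-spike current through the narrow fusion pore
before it dilates - with its duration, mean amplitude and charge.  The
interspike interval of a train is the median spike-to-spike interval.

Compound events (a second peak before the current returns to 25% of the
first peak) are flagged and excluded from shape statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

__all__ = [
    "AmperometryTrace",
    "SpikeWindow",
    "SpikeFeatures",
    "preprocess",
    "detect_spikes",
    "spike_features",
    "train_summary",
]


@dataclass
class AmperometryTrace:
    """Uniformly sampled amperometric current."""

    t: np.ndarray  # s
    i: np.ndarray  # pA
    fs: float  # Hz

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.t.shape != self.i.shape:
            raise ValueError("t and i must have the same shape")
        if not np.all(np.isfinite(self.i)):
            raise ValueError("current values must be finite")
        if self.t.size > 1:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / self.fs, rtol=1e-6, atol=1e-12):
                raise ValueError("time axis must be uniform at 1/fs")


@dataclass(frozen=True)
class SpikeWindow:
    """Index range of one detected spike, extended to baseline crossings."""

    start: int
    end: int  # exclusive
    peak: int
    compound: bool = False


@dataclass
class SpikeFeatures:
    """Shape parameters of a single, non-compound spike.

    Foot fields are ``None`` (absent) when no foot was detected, never 0.
    """

    i_max: float  # pA above baseline
    q: float  # pC, integral of foot + spike
    t_half: float  # ms, width at half maximum
    duration: float  # ms, baseline-to-baseline
    rise_50_90: float  # ms
    decay_75_25: float  # ms
    t_peak: float  # s, absolute spike (peak) time
    foot_duration: float | None = None  # ms
    foot_amplitude: float | None = None  # pA
    foot_charge: float | None = None  # pC


def preprocess(
    trace: AmperometryTrace,
    artifact: AmperometryTrace | None = None,
    cutoff_hz: float = 500.0,
) -> AmperometryTrace:
    """Subtract the flash artifact and Gaussian low-pass filter.

    The 'empty' artifact trace (recorded after removing the cell from the
    fiber) must share the trace's grid and is subtracted sample-wise.  The
    Gaussian filter is parameterised by its -3 dB cut-off frequency:
    sigma_t = sqrt(ln 2) / (2*pi*f_c).
    """
    i = trace.i
    if artifact is not None:
        if (artifact.fs != trace.fs or artifact.t.shape != trace.t.shape
                or not np.allclose(artifact.t, trace.t)):
            raise ValueError("artifact trace must share the recording grid")
        i = i - artifact.i
    sigma_t = math.sqrt(math.log(2.0)) / (2.0 * math.pi * cutoff_hz)
    filtered = gaussian_filter1d(i, sigma=sigma_t * trace.fs, mode="nearest")
    return AmperometryTrace(t=trace.t.copy(), i=filtered, fs=trace.fs)


def detect_spikes(
    trace: AmperometryTrace,
    threshold: float = 5.0,
    baseline: float = 0.0,
) -> list[SpikeWindow]:
    """Threshold detection of spikes on a preprocessed trace.

    Maximal contiguous excursions above ``threshold`` (pA above baseline)
    are extended outward to the surrounding baseline crossings.  An event
    whose current rises above threshold again before falling back to 25% of
    the first peak is a compound event: it is kept in the list but flagged,
    and should be excluded from shape statistics.
    """
    i = trace.i - baseline
    above = i > threshold
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    region_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    region_ends = np.concatenate([idx[breaks], [idx[-1]]]) + 1

    windows: list[SpikeWindow] = []
    for s, e in zip(region_starts, region_ends):
        # extend to baseline crossings
        while s > 0 and i[s - 1] > 0:
            s -= 1
        while e < i.size and i[e] > 0:
            e += 1
        if windows and s < windows[-1].end:
            # merged with previous region after extension -> compound
            prev = windows[-1]
            peak = prev.peak if i[prev.peak] >= i[s:e].max() else int(s + np.argmax(i[s:e]))
            windows[-1] = SpikeWindow(prev.start, int(e), peak, compound=True)
            continue
        seg = i[s:e]
        peak = int(s + np.argmax(seg))
        compound = _is_compound(seg, threshold)
        windows.append(SpikeWindow(int(s), int(e), peak, compound))
    return windows


def _is_compound(seg: np.ndarray, threshold: float) -> bool:
    """Second supra-threshold peak before return to 25% of the first peak."""
    peaks, _ = find_peaks(seg, height=threshold)
    if len(peaks) < 2:
        return False
    first = peaks[np.argmax(seg[peaks])]
    quarter = 0.25 * seg[first]
    for p in peaks:
        if p == first:
            continue
        lo, hi = (p, first) if p < first else (first, p)
        if seg[lo:hi + 1].min() > quarter:
            return True
    return False


def spike_features(
    trace: AmperometryTrace,
    window: SpikeWindow,
    baseline: float | None = None,
    foot_threshold: float = 2.0,
    min_foot_ms: float = 0.3,
) -> SpikeFeatures:
    """Extract shape parameters from a single non-compound spike window.

    ``baseline`` defaults to the median of the 50 ms preceding the window.
    Fractional-level crossings (50/90% rise, 75/25% decay, half maximum)
    are linearly interpolated between samples.  The foot starts at the
    first sustained crossing of ``foot_threshold`` pA above baseline before
    the main upstroke and ends where the extrapolated maximal-slope line of
    the upstroke meets the foot level; if no such crossing precedes the
    upstroke the foot fields are absent.  Apparent feet shorter than
    ``min_foot_ms`` (slivers of the rising flank itself) are discarded.
    """
    if window.compound:
        raise ValueError("compound events are excluded from shape analysis")
    if baseline is None:
        pre = max(0, window.start - int(round(0.050 * trace.fs)))
        if pre == window.start:
            baseline = 0.0
        else:
            baseline = float(np.median(trace.i[pre:window.start]))
    seg = trace.i[window.start:window.end] - baseline
    tseg = trace.t[window.start:window.end]
    dt = 1.0 / trace.fs
    pk = window.peak - window.start
    i_max = float(seg[pk])
    q = float(np.trapezoid(seg, dx=dt))  # pA*s = pC
    duration = (len(seg) - 1) * dt * 1e3

    t_half = _width_at(seg, pk, 0.5 * i_max, dt) * 1e3
    r50 = _cross_rising(seg, pk, 0.50 * i_max, dt)
    r90 = _cross_rising(seg, pk, 0.90 * i_max, dt)
    d75 = _cross_falling(seg, pk, 0.75 * i_max, dt)
    d25 = _cross_falling(seg, pk, 0.25 * i_max, dt)
    rise = (r90 - r50) * 1e3
    decay = (d25 - d75) * 1e3

    foot_dur = foot_amp = foot_q = None
    foot = _find_foot(seg, pk, foot_threshold, dt)
    if foot is not None:
        onset_idx, end_time = foot
        n_sub = max(2, int(math.ceil(end_time / dt)) + 1)
        tt = np.linspace(onset_idx * dt, end_time, n_sub)
        vals = np.interp(tt, np.arange(len(seg)) * dt, seg)
        foot_dur = (end_time - onset_idx * dt) * 1e3
        if foot_dur < min_foot_ms:
            foot_dur = foot_amp = foot_q = None
        else:
            foot_amp = float(vals.mean())
            foot_q = float(np.trapezoid(vals, tt))
    return SpikeFeatures(
        i_max=i_max, q=q, t_half=t_half, duration=duration,
        rise_50_90=rise, decay_75_25=decay, t_peak=float(tseg[pk]),
        foot_duration=foot_dur, foot_amplitude=foot_amp, foot_charge=foot_q,
    )


def _interp_cross(y0: float, y1: float, level: float) -> float:
    return (level - y0) / (y1 - y0)


def _cross_rising(seg: np.ndarray, pk: int, level: float, dt: float) -> float:
    """Time of the last upward crossing of ``level`` before the peak."""
    for j in range(pk, 0, -1):
        if seg[j - 1] < level <= seg[j]:
            return (j - 1 + _interp_cross(seg[j - 1], seg[j], level)) * dt
    return 0.0


def _cross_falling(seg: np.ndarray, pk: int, level: float, dt: float) -> float:
    """Time of the first downward crossing of ``level`` after the peak."""
    for j in range(pk, len(seg) - 1):
        if seg[j] >= level > seg[j + 1]:
            return (j + _interp_cross(seg[j], seg[j + 1], level)) * dt
    return (len(seg) - 1) * dt


def _width_at(seg: np.ndarray, pk: int, level: float, dt: float) -> float:
    return _cross_falling(seg, pk, level, dt) - _cross_rising(seg, pk, level, dt)


def _find_foot(seg: np.ndarray, pk: int, foot_threshold: float, dt: float):
    """Locate the pre-spike foot; returns (onset_index, end_time_s) or None.

    The upstroke's maximal slope is found between the 25% and 90% rising
    crossings; the foot ends where the line through the maximal-slope point
    intersects the foot level (mean current between onset and the 25%
    crossing), and begins at the first sustained crossing of the foot
    threshold before the upstroke.
    """
    if seg[pk] <= foot_threshold:
        return None
    # onset: walk back from peak below foot threshold, then forward
    j = pk
    while j > 0 and seg[j - 1] > foot_threshold:
        j -= 1
    onset = j  # j == 0 means the window edge (a baseline crossing) is the onset
    # 25% crossing marks the start of the main upstroke
    t25 = _cross_rising(seg, pk, 0.25 * seg[pk], dt)
    i25 = t25 / dt
    if i25 <= onset + 1:
        return None  # upstroke immediately follows threshold crossing
    foot_level = float(np.mean(seg[onset:int(i25) + 1]))
    # maximal slope on the upstroke
    lo = max(onset, int(i25) - 1)
    hi = max(lo + 1, int(_cross_rising(seg, pk, 0.90 * seg[pk], dt) / dt) + 1)
    hi = min(hi, pk)
    slopes = np.diff(seg[lo:hi + 1]) / dt
    if slopes.size == 0:
        return None
    kmax = int(np.argmax(slopes))
    s = float(slopes[kmax])
    if s <= 0:
        return None
    t0 = (lo + kmax) * dt
    y0 = float(seg[lo + kmax])
    end_time = t0 + (foot_level - y0) / s
    if end_time <= onset * dt:
        return None
    return onset, end_time


def train_summary(
    features: Sequence[SpikeFeatures],
    excluded_compound: int = 0,
) -> dict:
    """Across-spike summary: median interspike interval plus per-feature
    means and medians.  The interval is absent with fewer than two spikes."""
    out: dict = {"n_spikes": len(features), "excluded_compound": excluded_compound}
    if len(features) >= 2:
        times = np.sort([f.t_peak for f in features])
        out["median_interspike_interval_s"] = float(np.median(np.diff(times)))
    else:
        out["median_interspike_interval_s"] = None
    numeric = ("i_max", "q", "t_half", "duration", "rise_50_90", "decay_75_25",
               "foot_duration", "foot_amplitude", "foot_charge")
    for name in numeric:
        vals = [getattr(f, name) for f in features if getattr(f, name) is not None]
        if vals:
            out[f"{name}_mean"] = float(np.mean(vals))
            out[f"{name}_median"] = float(np.median(vals))
    return out
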