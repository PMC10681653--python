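"""Raw pulse-oximeter and respiratory-bellow traces -> frame-aligned HBI and RVT.

HBI (heartbeat interval series) is computed as the inverse of the mean
beat-to-beat duration inside a 6 s window centered on each imaging frame;
dimensionally this is a rate (Hz), and that inverse form is the default.
Set ``inverse=False`` in :func:`compute_hbi` for the plain mean duration.

RVT (respiration volume per time) is, per breath, (inhalation amplitude -
exhalation amplitude) divided by the spacing between consecutive breath
maxima, assigned at the maximum and linearly interpolated to frame centers.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .series import DegenerateSignalError, EventSeries, SampledSeries


class NoEventsError(ValueError):
    """No detectable events in a trace."""


def detect_pulse_peaks(rec: SampledSeries, min_interval: float = 0.5) -> EventSeries:
    """Systolic peak times from a pulse-oximeter waveform.

    Local maxima with an adaptive prominence threshold (40% of the 10-90
    percentile spread) separated by at least ``min_interval`` seconds.
    """
    if rec.dt > 0.01:
        raise ValueError("pulse trace must be sampled at >= 100 Hz")
    if not 0.25 <= min_interval <= 2.0:
        raise ValueError("min_interval outside the physiological range")
    spread = np.percentile(rec.values, 90) - np.percentile(rec.values, 10)
    if spread == 0:
        raise NoEventsError("flat pulse trace")
    distance = max(1, int(round(min_interval / rec.dt)))
    idx, _ = sps.find_peaks(rec.values, distance=distance, prominence=0.4 * spread)
    if idx.size == 0:
        raise NoEventsError("no pulse peaks found")
    return EventSeries(times=rec.t0 + idx * rec.dt,
                       amplitudes=rec.values[idx], kind="pulse-peak")


def compute_hbi(peaks: EventSeries, frame_times, window: float = 6.0,
                inverse: bool = True) -> SampledSeries:
    """Windowed heartbeat series at each imaging frame.

    A beat-to-beat duration belongs to a frame's window iff its midpoint
    lies within [t - window/2, t + window/2].  Frames whose window holds no
    duration are filled with the nearest valid frame's value; the fill is
    recorded in the returned series' ``qc_flags`` attribute (True = filled).
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if len(peaks) < 2:
        raise NoEventsError("need at least two pulse peaks")
    durations = np.diff(peaks.times)
    midpoints = peaks.times[:-1] + durations / 2.0
    half = window / 2.0
    vals = np.full(frame_times.size, np.nan)
    for i, t in enumerate(frame_times):
        sel = (midpoints >= t - half) & (midpoints <= t + half)
        if np.any(sel):
            mean_dur = durations[sel].mean()
            vals[i] = 1.0 / mean_dur if inverse else mean_dur
    valid = np.flatnonzero(~np.isnan(vals))
    if valid.size == 0:
        raise NoEventsError("no frame window contains a beat duration")
    flags = np.isnan(vals)
    if flags.any():
        nearest = valid[np.argmin(np.abs(np.flatnonzero(flags)[:, None] - valid[None, :]), axis=1)]
        vals[flags] = vals[nearest]
    if frame_times.size > 1:
        dt = float(np.median(np.diff(frame_times)))
    else:
        dt = window
    out = SampledSeries(values=vals, dt=dt, t0=float(frame_times[0]),
                        label="HBI" if inverse else "HBI-duration")
    out.qc_flags = flags
    return out


def detect_breath_extrema(rec: SampledSeries,
                          lowpass_hz: float = 1.0) -> tuple[EventSeries, EventSeries]:
    """Alternating breath maxima and minima from a bellows trace.

    The trace is low-pass filtered with a zero-phase 4th-order Butterworth
    (default 1 Hz) before extrema detection, so sensor ripple cannot create
    spurious breaths and extrema times are not shifted.  Strict alternation
    is enforced by dropping the lesser of two consecutive same-kind extrema.
    """
    if np.ptp(rec.values) == 0:
        raise NoEventsError("constant bellows trace")
    nyq = 0.5 / rec.dt
    if lowpass_hz < nyq:
        sos = sps.butter(4, lowpass_hz / nyq, output="sos")
        filt = sps.sosfiltfilt(sos, rec.values)
    else:
        filt = rec.values
    imax, _ = sps.find_peaks(filt)
    imin, _ = sps.find_peaks(-filt)
    if imax.size == 0 or imin.size == 0:
        raise NoEventsError("fewer than one full breath in trace")
    # merge, enforce alternation keeping the more extreme of same-kind runs
    events = sorted([(i, +1) for i in imax] + [(i, -1) for i in imin])
    kept: list[tuple[int, int]] = []
    for i, kind in events:
        if kept and kept[-1][1] == kind:
            j, _ = kept[-1]
            better = filt[i] > filt[j] if kind > 0 else filt[i] < filt[j]
            if better:
                kept[-1] = (i, kind)
        else:
            kept.append((i, kind))
    t = rec.t0 + rec.dt * np.array([i for i, _ in kept], dtype=float)
    a = filt[[i for i, _ in kept]]
    k = np.array([s for _, s in kept])
    maxima = EventSeries(times=t[k > 0], amplitudes=a[k > 0], kind="breath-max")
    minima = EventSeries(times=t[k < 0], amplitudes=a[k < 0], kind="breath-min")
    return maxima, minima


def compute_rvt(maxima: EventSeries, minima: EventSeries, frame_times) -> SampledSeries:
    """Per-breath (max - following min)/(spacing of consecutive maxima) at frames.

    Each maximum pairs with the next minimum; a trailing maximum without a
    following minimum or successor maximum is dropped.  Values are assigned
    at the maximum's time and linearly interpolated to frame centers, with
    boundary values held beyond the first/last breath.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if len(maxima) < 2:
        raise NoEventsError("need at least two breath maxima")
    bt, bv = [], []
    for i in range(len(maxima) - 1):
        tmax, tnext = maxima.times[i], maxima.times[i + 1]
        after = np.flatnonzero((minima.times > tmax) & (minima.times < tnext))
        if after.size == 0:
            continue
        amp = maxima.amplitudes[i] - minima.amplitudes[after[0]]
        bt.append(tmax)
        bv.append(amp / (tnext - tmax))
    if len(bt) < 1:
        raise NoEventsError("no complete breaths")
    vals = np.interp(frame_times, bt, bv)
    dt = float(np.median(np.diff(frame_times))) if frame_times.size > 1 else 1.0
    return SampledSeries(values=vals, dt=dt, t0=float(frame_times[0]), label="RVT")


def mean_normalize(x: SampledSeries, mode: str = "subtract") -> SampledSeries:
    """Mean-normalize a series: subtract the temporal mean (default) or divide by it."""
    mu = x.values.mean()
    if mode == "subtract":
        return x.with_values(x.values - mu)
    if mode == "divide":
        if mu == 0:
            raise DegenerateSignalError("cannot divide-normalize a zero-mean series")
        return x.with_values(x.values / mu)
    raise ValueError("mode must be 'subtract' or 'divide'")
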