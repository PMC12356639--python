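"""Sharp-wave event detection and per-event measurements.

The LFP proxy (basket-cell current onto pyramidal neurons) is low-pass
filtered to 5 Hz with a zero-phase 2nd-order Butterworth filter; local
maxima more than 50 pA above the baseline (median of the filtered trace)
are sharp-wave events.  Event onset/offset are the nearest crossings of the
half-height level L_0 + (L_p - L_0)/2 around each peak.  Within each event
the athorny (A) and thorny (T) population-rate peaks are located; if a
population shows two peaks more than 50 ms apart both are recorded and the
*first* one is used for the delay statistic

    delay = first T peak time - first A peak time.

A population must reach a minimum peak rate (default 2 spikes/s) for the
event to count toward delay statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks

from .simulation import SimOutput

__all__ = [
    "SpwEvent",
    "lowpass_lfp",
    "detect_events",
    "population_peaks",
    "event_statistics",
    "analyze_simulation",
]


@dataclass
class SpwEvent:
    """One detected sharp wave.  Times in ms on the trace time base."""

    lfp_peak_time: float
    lfp_peak: float                 # L_p - L_0, baseline-subtracted (pA)
    onset: float
    offset: float
    peak_times_A: list = field(default_factory=list)
    peak_times_T: list = field(default_factory=list)
    peak_rate_A: float = np.nan     # spikes/s at the first A peak
    peak_rate_T: float = np.nan
    quarter_cross_A: tuple = (np.nan, np.nan)   # 25%-of-peak crossings (ms)
    quarter_cross_T: tuple = (np.nan, np.nan)
    double_A_peak: bool = False
    double_T_peak: bool = False
    valid_delay: bool = False

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def delay(self) -> float:
        """First-T-peak minus first-A-peak time (ms); NaN if invalid."""
        if not self.valid_delay:
            return np.nan
        return self.peak_times_T[0] - self.peak_times_A[0]


def lowpass_lfp(trace: np.ndarray, fs_hz: float = 1000.0,
                cutoff_hz: float = 5.0, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth low-pass; DC is preserved."""
    n_min = int(5 * fs_hz / cutoff_hz)
    if len(trace) < n_min:
        raise ValueError("trace too short for the requested cutoff")
    b, a = butter(order, cutoff_hz / (0.5 * fs_hz), btype="low")
    return filtfilt(b, a, trace)


def detect_events(filtered: np.ndarray, time: np.ndarray | None = None,
                  threshold_pa: float = 50.0,
                  baseline: float | None = None) -> list[SpwEvent]:
    """Find sharp waves in a low-pass-filtered LFP trace.

    Peaks more than ``threshold_pa`` above the baseline L_0 (median of the
    filtered trace unless given) become events; onset/offset are the nearest
    crossings of the half-height level L_0 + (L_p - L_0)/2.  Events whose
    half-height windows overlap are merged, keeping the higher peak.
    Detection is invariant to adding a constant to the trace.
    """
    f = np.asarray(filtered, dtype=float)
    if time is None:
        time = np.arange(len(f), dtype=float)
    dt = time[1] - time[0] if len(time) > 1 else 1.0
    L0 = float(np.median(f)) if baseline is None else float(baseline)
    idx, _ = find_peaks(f, height=L0 + threshold_pa)
    events: list[SpwEvent] = []
    for p in idx:
        Lp = f[p]
        half = L0 + 0.5 * (Lp - L0)
        i0 = p
        while i0 > 0 and f[i0 - 1] > half:
            i0 -= 1
        i1 = p
        while i1 < len(f) - 1 and f[i1 + 1] > half:
            i1 += 1
        ev = SpwEvent(lfp_peak_time=float(time[p]), lfp_peak=float(Lp - L0),
                      onset=float(time[i0]), offset=float(time[i1]))
        if events and ev.onset <= events[-1].offset:
            if ev.lfp_peak > events[-1].lfp_peak:   # merge at higher peak
                events[-1] = ev
            continue
        events.append(ev)
    # guard duration > 0 at trace edges
    return [e for e in events if e.offset > e.onset]


def _first_peaks(rate: np.ndarray, time: np.ndarray, onset: float,
                 offset: float, min_gap_ms: float,
                 min_rate: float) -> tuple[list[float], float, bool]:
    """Rate peaks inside [onset, offset]: returns (peak times, first-peak
    rate, double-peak flag).  Peaks below ``min_rate`` or less prominent
    than 25% of the window maximum are ignored."""
    m = (time >= onset) & (time <= offset)
    if not m.any():
        return [], np.nan, False
    seg = rate[m]
    tseg = time[m]
    top = float(seg.max())
    if top < min_rate:
        return [], np.nan, False
    pk, _ = find_peaks(seg, height=max(min_rate, 0.25 * top),
                       prominence=0.25 * top)
    if len(pk) == 0:
        pk = np.array([int(np.argmax(seg))])
    times = [float(tseg[i]) for i in pk]
    # peaks closer than min_gap_ms to the first are not "separate"
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] > min_gap_ms:
            kept.append(t)
    double = len(kept) > 1
    first_rate = float(seg[pk[0]])
    return kept, first_rate, double


def _quarter_crossings(rate, time, t_peak, peak_rate):
    """Times where the rate crosses 25% of the peak, nearest around it."""
    level = 0.25 * peak_rate
    i = int(np.searchsorted(time, t_peak))
    i = min(max(i, 0), len(rate) - 1)
    i0 = i
    while i0 > 0 and rate[i0 - 1] > level:
        i0 -= 1
    i1 = i
    while i1 < len(rate) - 1 and rate[i1 + 1] > level:
        i1 += 1
    return (float(time[i0]), float(time[i1]))


def population_peaks(event: SpwEvent, time: np.ndarray, rate_A: np.ndarray,
                     rate_T: np.ndarray, min_gap_ms: float = 50.0,
                     min_rate: float = 2.0) -> SpwEvent:
    """Fill per-population rate-peak fields of ``event`` in place.

    The delay is defined only when both populations reach ``min_rate``
    (validity threshold for delay statistics).
    """
    pts_A, r_A, dbl_A = _first_peaks(rate_A, time, event.onset, event.offset,
                                     min_gap_ms, min_rate)
    pts_T, r_T, dbl_T = _first_peaks(rate_T, time, event.onset, event.offset,
                                     min_gap_ms, min_rate)
    event.peak_times_A, event.peak_rate_A, event.double_A_peak = pts_A, r_A, dbl_A
    event.peak_times_T, event.peak_rate_T, event.double_T_peak = pts_T, r_T, dbl_T
    event.valid_delay = bool(pts_A) and bool(pts_T)
    if pts_A:
        event.quarter_cross_A = _quarter_crossings(rate_A, time, pts_A[0], r_A)
    if pts_T:
        event.quarter_cross_T = _quarter_crossings(rate_T, time, pts_T[0], r_T)
    return event


def event_statistics(events: list[SpwEvent], recording_ms: float,
                     spikes_A: np.ndarray | None = None,
                     spikes_T: np.ndarray | None = None,
                     n_A: int = 0, n_T: int = 0) -> dict:
    """Summary statistics over detected events.

    Non-SPW rates are computed from the spikes falling outside the union of
    [onset, offset] intervals, divided by population size and non-event time.
    """
    out = {"n_events": len(events),
           "incidence_per_s": len(events) / (recording_ms / 1000.0)}
    if events:
        durs = np.array([e.duration for e in events])
        peaks = np.array([e.lfp_peak for e in events])
        delays = np.array([e.delay for e in events if e.valid_delay])
        out.update(mean_duration_ms=float(durs.mean()),
                   sd_duration_ms=float(durs.std()),
                   mean_lfp_peak_pa=float(peaks.mean()),
                   n_valid_delay=int(len(delays)))
        if len(delays):
            out.update(mean_delay_ms=float(delays.mean()),
                       sd_delay_ms=float(delays.std()))
        else:
            out.update(mean_delay_ms=None, sd_delay_ms=None)
    else:
        out.update(mean_duration_ms=None, sd_duration_ms=None,
                   mean_lfp_peak_pa=None, mean_delay_ms=None,
                   sd_delay_ms=None, n_valid_delay=0)

    if spikes_A is not None and n_A and n_T:
        quiet = recording_ms - sum(e.duration for e in events)
        def _outside(sp):
            mask = np.ones(len(sp), dtype=bool)
            for e in events:
                mask &= ~((sp >= e.onset) & (sp <= e.offset))
            return mask.sum()
        if quiet > 0:
            out["non_spw_rate_A"] = _outside(spikes_A) / n_A / (quiet / 1000.0)
            out["non_spw_rate_T"] = _outside(spikes_T) / n_T / (quiet / 1000.0)
    return out


def analyze_simulation(sim: SimOutput, threshold_pa: float = 50.0,
                       min_gap_ms: float = 50.0,
                       min_rate: float = 2.0) -> tuple[list[SpwEvent], dict]:
    """Full event pipeline on one simulation: filter, detect, measure.

    Returns the event list and the summary dict.
    """
    fs = 1000.0 / (sim.time[1] - sim.time[0])
    filt = lowpass_lfp(sim.lfp, fs_hz=fs)
    events = detect_events(filt, sim.time, threshold_pa=threshold_pa)
    rate_A = sim.rate("A")
    rate_T = sim.rate("T")
    for e in events:
        population_peaks(e, sim.time, rate_A, rate_T,
                         min_gap_ms=min_gap_ms, min_rate=min_rate)
    stats = event_statistics(
        events, recording_ms=sim.duration,
        spikes_A=sim.pop_spikes("A"), spikes_T=sim.pop_spikes("T"),
        n_A=int(sim.net.sizes[0]), n_T=int(sim.net.sizes[1]))
    return events, stats


def events_table(events: list[SpwEvent]) -> pd.DataFrame:
    """Event list as a tidy table (one row per event)."""
    rows = []
    for e in events:
        rows.append({
            "lfp_peak_time_ms": e.lfp_peak_time, "lfp_peak_pa": e.lfp_peak,
            "onset_ms": e.onset, "offset_ms": e.offset,
            "duration_ms": e.duration,
            "first_A_peak_ms": e.peak_times_A[0] if e.peak_times_A else np.nan,
            "first_T_peak_ms": e.peak_times_T[0] if e.peak_times_T else np.nan,
            "peak_rate_A_hz": e.peak_rate_A, "peak_rate_T_hz": e.peak_rate_T,
            "delay_ms": e.delay, "double_A_peak": e.double_A_peak,
            "double_T_peak": e.double_T_peak, "valid_delay": e.valid_delay,
        })
    return pd.DataFrame(rows)
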