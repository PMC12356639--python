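"""Paired-recording connectivity statistics.

Analysis pipeline for multi-patch connectivity screens between thorny (T)
and athorny (A) CA3 pyramidal cells.  In a screen, one cell at a time is
driven with a train of four action potentials at 20 Hz while the membrane
potential of the other patched cells is recorded; averaging 40-50 sweeps
reveals unitary EPSPs.  The pipeline mirrors the standard workflow:

1. quality control (resting potential, series resistance, presynaptic AP
   amplitude, baseline drift);
2. connection detection and EPSP amplitude/latency from the averaged trace;
3. per-sweep failure rates;
4. short-term plasticity via membrane deconvolution d(t) = tau*dV/dt + V
   (tau = 55 ms) which removes temporal summation between pulses;
5. connection-rate and synaptic-strength matrices, the synaptic product
   (rate x strength x presynaptic population fraction), and nonparametric
   group comparisons (Shapiro-Wilk gate, Mann-Whitney-U / Kruskal-Wallis
   with Dunn-Bonferroni post hoc).

Detection thresholds stand in for the visual identification used at the
rig: a connection requires the averaged post-AP1 peak to exceed 3x the
baseline noise of the averaged trace; single-sweep successes (for failure
rates) use 2x the single-sweep baseline noise.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import butter, filtfilt

__all__ = [
    "Cell",
    "PairRecording",
    "PairScreen",
    "ConnectionMeasurement",
    "qc_filter",
    "measure_connection",
    "failure_rate",
    "deconvolve_stp",
    "rate_matrix",
    "strength_matrix",
    "synaptic_product",
    "compare_groups",
    "dunn_posthoc",
    "analyze_screen",
    "write_screen",
    "read_screen",
]

TYPE_ORDER = ("A", "T")  # athorny, thorny


@dataclass(frozen=True)
class Cell:
    id: int
    type: str           # 'A' (athorny) or 'T' (thorny)
    vm: float           # resting membrane potential (mV)
    rs: float           # series resistance (MOhm)

    def __post_init__(self):
        if self.type not in TYPE_ORDER:
            raise ValueError(f"cell type must be one of {TYPE_ORDER}")


@dataclass
class PairRecording:
    """Sweeps of one tested ordered pair (pre stimulated, post recorded)."""

    pre_id: int
    post_id: int
    sweeps: np.ndarray          # (n_sweeps, n_samples) postsynaptic Vm (mV)
    ap_peaks: np.ndarray        # (n_sweeps, 4) presynaptic AP peak voltages (mV)


@dataclass
class PairScreen:
    """A full multi-patch screen: cells, tested pairs, stimulus layout."""

    cells: list[Cell]
    pairs: list[PairRecording]
    ap_times: np.ndarray        # (4,) AP peak times (ms), 20 Hz spacing
    fs_khz: float               # sampling rate (kHz)

    def cell(self, cid: int) -> Cell:
        return self._by_id[cid]

    @property
    def _by_id(self) -> dict:
        return {c.id: c for c in self.cells}


@dataclass
class ConnectionMeasurement:
    pre_id: int
    post_id: int
    n_sweeps: int
    connected: bool
    amplitude: float = np.nan       # mean first-EPSP peak - baseline (mV)
    latency: float = np.nan         # 20%-of-peak rise time - AP time (ms)
    monosynaptic: bool = False      # latency < 3 ms
    failure_pct: float = np.nan
    stp_amplitudes: tuple = (np.nan,) * 4   # normalized to pulse 1
    stp_ratio: float = np.nan       # EPSP4 / EPSP1


# ---------------------------------------------------------------------------
# quality control

def _baseline_windows(ap_times, fs_khz, pre_ms=2.0):
    """Sample slices of the 2 ms baseline just before each AP."""
    out = []
    for t in ap_times:
        i1 = int(round(t * fs_khz))
        i0 = int(round((t - pre_ms) * fs_khz))
        out.append(slice(max(i0, 0), max(i1, 1)))
    return out


def qc_filter(screen: PairScreen, vm_max: float = -50.0, rs_max: float = 30.0,
              ap_min: float = 0.0, drift_max: float = 0.10) -> PairScreen:
    """Drop cells and sweeps failing quality control.

    Cells with resting potential less negative than ``vm_max`` or series
    resistance above ``rs_max`` are removed with every pair they belong to.
    A sweep is removed when any presynaptic AP peak fails to reverse above
    ``ap_min`` or when its baseline deviates by more than ``drift_max``
    (relative) within the sweep or versus the pair's first sweep.  Pairs
    left without sweeps are excluded.
    """
    good = {c.id for c in screen.cells
            if c.vm <= vm_max and c.rs <= rs_max}
    cells = [c for c in screen.cells if c.id in good]
    wins = _baseline_windows(screen.ap_times, screen.fs_khz)
    pairs = []
    for p in screen.pairs:
        if p.pre_id not in good or p.post_id not in good:
            continue
        base = np.stack([p.sweeps[:, w].mean(axis=1) for w in wins], axis=1)
        ref = base[0, 0]
        ok_ap = (p.ap_peaks > ap_min).all(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_within = np.abs(base - base[:, :1]) / np.abs(base[:, :1])
            rel_first = np.abs(base[:, 0] - ref) / abs(ref) if ref != 0 else \
                np.zeros(len(base))
        ok_drift = (rel_within.max(axis=1) <= drift_max) & (rel_first <= drift_max)
        keep = ok_ap & ok_drift
        if keep.any():
            pairs.append(PairRecording(p.pre_id, p.post_id,
                                       p.sweeps[keep], p.ap_peaks[keep]))
    return PairScreen(cells=cells, pairs=pairs,
                      ap_times=screen.ap_times, fs_khz=screen.fs_khz)


# ---------------------------------------------------------------------------
# per-connection measurements

def _detect_window(ap_t, fs_khz, lo_ms=1.0, hi_ms=10.0):
    return slice(int(round((ap_t + lo_ms) * fs_khz)),
                 int(round((ap_t + hi_ms) * fs_khz)))


def measure_connection(sweeps: np.ndarray, ap_times, fs_khz: float,
                       noise_win_ms: float = 20.0, snr: float = 3.0,
                       min_amp_mv: float = 0.15) -> ConnectionMeasurement:
    """Detect and quantify a connection from the averaged trace.

    The pair is connected when the averaged post-AP1 depolarization within
    1-10 ms after the first AP exceeds ``snr`` times the baseline noise of
    the averaged trace and a physiological floor ``min_amp_mv``.  Amplitude
    is peak minus the 2 ms pre-AP1 baseline; latency is where the averaged
    EPSP rises through 20% of its peak, relative to the AP peak time.
    """
    avg = sweeps.mean(axis=0)
    ap1 = ap_times[0]
    i_ap1 = int(round(ap1 * fs_khz))
    base_sl = slice(int(round((ap1 - 2.0) * fs_khz)), i_ap1)
    baseline = float(avg[base_sl].mean())
    noise_sl = slice(max(int(round((ap1 - noise_win_ms) * fs_khz)), 0), i_ap1)
    noise_sd = float(avg[noise_sl].std())
    win = _detect_window(ap1, fs_khz)
    seg = avg[win]
    i_peak = int(np.argmax(seg))
    # average +-0.25 ms around the maximum: suppresses the upward bias of
    # picking the max of a noisy trace
    half = max(int(round(0.25 * fs_khz)), 1)
    peak = float(seg[max(i_peak - half, 0):i_peak + half + 1].mean())
    amp = peak - baseline
    m = ConnectionMeasurement(
        pre_id=-1, post_id=-1, n_sweeps=len(sweeps),
        connected=bool(amp > snr * noise_sd and amp > min_amp_mv))
    if not m.connected:
        return m
    m.amplitude = amp
    # 20%-of-peak rise, searching backwards from the peak
    level = baseline + 0.2 * amp
    j = win.start + i_peak
    while j > i_ap1 and avg[j - 1] > level:
        j -= 1
    m.latency = j / fs_khz - ap1
    m.monosynaptic = m.latency < 3.0
    return m


def failure_rate(sweeps: np.ndarray, ap_times, fs_khz: float,
                 snr: float = 2.0, smooth_ms: float = 1.0) -> float:
    """Percent of AP occasions without a detectable single-sweep EPSP.

    Each of the four APs in each sweep is classified as success when the
    post-AP peak of the boxcar-smoothed sweep exceeds the pre-AP baseline by
    ``snr`` times the raw single-sweep baseline noise; the failure rate
    aggregates all four APs.  Smoothing before peak-picking keeps the
    extreme-value statistics of the noise below the threshold while barely
    attenuating EPSPs, whose rise is slower than ``smooth_ms``.
    """
    ap1 = ap_times[0]
    i_ap1 = int(round(ap1 * fs_khz))
    noise_sl = slice(max(int(round((ap1 - 20.0) * fs_khz)), 0), i_ap1)
    width = max(int(round(smooth_ms * fs_khz)), 1)
    kernel = np.ones(width) / width
    occasions = 0
    successes = 0
    for sweep in sweeps:
        sd = sweep[noise_sl].std()
        sm = np.convolve(sweep, kernel, mode="same")
        for ap_t in ap_times:
            sl = _detect_window(ap_t, fs_khz)
            base = sm[slice(int(round((ap_t - 2.0) * fs_khz)),
                            int(round(ap_t * fs_khz)))].mean()
            occasions += 1
            if sm[sl].max() - base > snr * sd:
                successes += 1
    return 100.0 * (1.0 - successes / occasions)


def deconvolve_stp(avg_trace: np.ndarray, ap_times, fs_khz: float,
                   tau_ms: float = 55.0, lp_hz: float = 300.0):
    """Short-term-plasticity amplitudes via membrane deconvolution.

    Computes d(t) = tau * dV/dt + V on the averaged trace (V relative to the
    pre-AP1 baseline), low-pass filters it, and takes the post-AP peak of d
    for each pulse.  Deconvolution removes the temporal summation of EPSPs
    whose decay is slower than the inter-pulse interval, so the peaks are
    proportional to the underlying per-pulse amplitudes.  Returns
    (normalized amplitudes (4,), EPSP4/EPSP1 ratio).

    Raises ``ValueError`` if the first deconvolved peak is not positive
    (normalization undefined; the pair should be excluded).
    """
    fs = fs_khz * 1000.0
    ap1 = ap_times[0]
    i_ap1 = int(round(ap1 * fs_khz))
    base = avg_trace[slice(int(round((ap1 - 2.0) * fs_khz)), i_ap1)].mean()
    v = avg_trace - base
    dv = np.gradient(v) * fs / 1000.0          # mV/ms
    d = tau_ms * dv + v
    if lp_hz and lp_hz < fs / 2:
        b, a = butter(2, lp_hz / (0.5 * fs), btype="low")
        d = filtfilt(b, a, d)
    amps = []
    for ap_t in ap_times:
        sl = _detect_window(ap_t, fs_khz, lo_ms=0.0, hi_ms=12.0)
        pre = d[slice(int(round((ap_t - 2.0) * fs_khz)),
                      int(round(ap_t * fs_khz)))].mean()
        amps.append(float(d[sl].max() - pre))
    amps = np.array(amps)
    if amps[0] <= 0:
        raise ValueError("first deconvolved peak non-positive; "
                         "normalization undefined")
    norm = amps / amps[0]
    return norm, float(norm[-1])


# ---------------------------------------------------------------------------
# screen-level aggregation

def measure_screen(screen: PairScreen, min_sweeps: int = 10) -> pd.DataFrame:
    """Run all per-pair measurements; one row per tested ordered pair."""
    rows = []
    for p in screen.pairs:
        if len(p.sweeps) < min_sweeps:
            continue
        m = measure_connection(p.sweeps, screen.ap_times, screen.fs_khz)
        m.pre_id, m.post_id = p.pre_id, p.post_id
        row = {"pre_id": p.pre_id, "post_id": p.post_id,
               "pre_type": screen.cell(p.pre_id).type,
               "post_type": screen.cell(p.post_id).type,
               "n_sweeps": len(p.sweeps), "connected": m.connected,
               "amplitude_mv": m.amplitude, "latency_ms": m.latency,
               "monosynaptic": m.monosynaptic,
               "failure_pct": np.nan, "stp_ratio": np.nan,
               "stp1": np.nan, "stp2": np.nan, "stp3": np.nan, "stp4": np.nan}
        if m.connected:
            row["failure_pct"] = failure_rate(p.sweeps, screen.ap_times,
                                              screen.fs_khz)
            try:
                norm, ratio = deconvolve_stp(p.sweeps.mean(axis=0),
                                             screen.ap_times, screen.fs_khz)
                row.update(stp_ratio=ratio, stp1=norm[0], stp2=norm[1],
                           stp3=norm[2], stp4=norm[3])
            except ValueError:
                pass
        rows.append(row)
    return pd.DataFrame(rows)


def rate_matrix(measurements: pd.DataFrame) -> dict:
    """Connection counts and rates per (post, pre) type.

    Returns dict with 'tested', 'connected' (integer DataFrames, rows =
    postsynaptic type, columns = presynaptic type), 'rates' (percent),
    overall counts/rate, and the number of reciprocally connected pairs
    per unordered type combination.
    """
    idx = list(TYPE_ORDER)
    tested = pd.DataFrame(0, index=idx, columns=idx)
    conn = pd.DataFrame(0, index=idx, columns=idx)
    for _, r in measurements.iterrows():
        tested.loc[r.post_type, r.pre_type] += 1
        if r.connected:
            conn.loc[r.post_type, r.pre_type] += 1
    with np.errstate(invalid="ignore"):
        rates = 100.0 * conn / tested.replace(0, np.nan)
    connected_pairs = {(int(r.pre_id), int(r.post_id))
                       for _, r in measurements.iterrows() if r.connected}
    recip = {}
    for _, r in measurements.iterrows():
        if r.connected and (int(r.post_id), int(r.pre_id)) in connected_pairs:
            key = "".join(sorted(r.pre_type + r.post_type))
            recip[key] = recip.get(key, 0) + 1
    total_tested = int(tested.values.sum())
    total_conn = int(conn.values.sum())
    return {"tested": tested, "connected": conn, "rates_pct": rates,
            "overall_tested": total_tested, "overall_connected": total_conn,
            "overall_rate_pct": 100.0 * total_conn / total_tested
            if total_tested else np.nan,
            "reciprocal_connections": recip}


def strength_matrix(measurements: pd.DataFrame, stat: str = "median"
                    ) -> pd.DataFrame:
    """Per (post, pre) type central amplitude (mV) of connected pairs."""
    idx = list(TYPE_ORDER)
    out = pd.DataFrame(np.nan, index=idx, columns=idx)
    conn = measurements[measurements.connected & measurements.amplitude_mv.notna()]
    agg = getattr(conn.groupby(["post_type", "pre_type"]).amplitude_mv, stat)()
    for (post, pre), v in agg.items():
        out.loc[post, pre] = v
    return out


def synaptic_product(rates_pct: pd.DataFrame, strengths_mv: pd.DataFrame,
                     pre_fractions: dict | None = None) -> pd.DataFrame:
    """Per-pathway impact: rate x strength x presynaptic population fraction.

    ``pre_fractions`` maps presynaptic type to its share of the pyramidal
    population (default A: 0.34, T: 0.66).  Rates enter as fractions.
    """
    pre_fractions = pre_fractions or {"A": 0.34, "T": 0.66}
    if (rates_pct.values < 0).any() or np.nanmin(strengths_mv.values) < 0:
        raise ValueError("rates and strengths must be non-negative")
    frac = pd.Series(pre_fractions)[rates_pct.columns]
    return (rates_pct / 100.0) * strengths_mv * frac


# ---------------------------------------------------------------------------
# nonparametric statistics

def dunn_posthoc(groups: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Dunn's post hoc test after Kruskal-Wallis, Bonferroni-corrected.

    Pairwise z statistics on mean ranks of the pooled sample with tie
    correction; two-sided p-values multiplied by the number of comparisons.
    """
    names = list(groups)
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    sizes = {g: len(groups[g]) for g in names}
    ranks = stats.rankdata(values)
    n_total = len(values)
    mean_ranks = {}
    i = 0
    for g in names:
        mean_ranks[g] = ranks[i:i + sizes[g]].mean()
        i += sizes[g]
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        se = math.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = min(2.0 * (1.0 - stats.norm.cdf(abs(z))) * m, 1.0)
        rows.append({"group1": g1, "group2": g2, "z": z,
                     "p_adj": p, "significant": p < alpha})
    return pd.DataFrame(rows)


def compare_groups(groups: dict, alpha: float = 0.05) -> dict:
    """Compare >=2 groups of values nonparametrically.

    Shapiro-Wilk normality check per group (reported), then
    Mann-Whitney-U for two groups or Kruskal-Wallis for more, with
    Dunn-Bonferroni post hoc when the omnibus test is significant.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    clean = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    small = [g for g, v in clean.items() if len(v) < 3]
    if small:
        return {"insufficient_data": small}
    normality = {g: float(stats.shapiro(v).pvalue) for g, v in clean.items()}
    vals = list(clean.values())
    if len(clean) == 2:
        test = "mann-whitney-u"
        res = stats.mannwhitneyu(vals[0], vals[1], alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
        posthoc = None
    else:
        test = "kruskal-wallis"
        res = stats.kruskal(*vals)
        stat, p = float(res.statistic), float(res.pvalue)
        posthoc = dunn_posthoc(clean, alpha) if p < alpha else None
    return {"normality_p": normality, "test": test, "statistic": stat,
            "p_value": p, "significant": p < alpha, "posthoc": posthoc}


# ---------------------------------------------------------------------------
# full pipeline and disk format

def analyze_screen(screen: PairScreen, qc: bool = True,
                   strength_stat: str = "median") -> dict:
    """QC, per-pair measurement and matrix-level aggregation in one call."""
    if qc:
        screen = qc_filter(screen)
    meas = measure_screen(screen)
    rates = rate_matrix(meas)
    strengths = strength_matrix(meas, stat=strength_stat)
    product = synaptic_product(rates["rates_pct"].fillna(0.0),
                               strengths.fillna(0.0))
    amp_groups = {f"{pre}->{post}": g.amplitude_mv.dropna().values
                  for (post, pre), g in
                  meas[meas.connected].groupby(["post_type", "pre_type"])}
    comparison = compare_groups(amp_groups) if len(amp_groups) >= 2 else None
    return {"measurements": meas, "rates": rates, "strengths": strengths,
            "synaptic_product": product, "amplitude_comparison": comparison}


def write_screen(screen: PairScreen, outdir) -> None:
    """Screen to disk: JSON manifest + one npz with all sweep arrays."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "ap_times_ms": list(map(float, screen.ap_times)),
        "fs_khz": screen.fs_khz,
        "cells": [{"id": c.id, "type": c.type, "vm": c.vm, "rs": c.rs}
                  for c in screen.cells],
        "pairs": [{"pre_id": p.pre_id, "post_id": p.post_id,
                   "n_sweeps": int(len(p.sweeps))} for p in screen.pairs],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    arrays = {}
    for k, p in enumerate(screen.pairs):
        arrays[f"sweeps_{k}"] = p.sweeps.astype(np.float32)
        arrays[f"ap_peaks_{k}"] = p.ap_peaks.astype(np.float32)
    np.savez_compressed(outdir / "sweeps.npz", **arrays)


def read_screen(indir) -> PairScreen:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    data = np.load(indir / "sweeps.npz")
    cells = [Cell(**c) for c in manifest["cells"]]
    pairs = [PairRecording(pr["pre_id"], pr["post_id"],
                           data[f"sweeps_{k}"], data[f"ap_peaks_{k}"])
             for k, pr in enumerate(manifest["pairs"])]
    return PairScreen(cells=cells, pairs=pairs,
                      ap_times=np.array(manifest["ap_times_ms"]),
                      fs_khz=manifest["fs_khz"])
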