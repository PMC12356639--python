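"""Synthetic multi-patch screen generator with known ground truth.

Emulates the paired-recording protocol — groups of up to eight
simultaneously patched CA3 pyramidal cells, each stimulated in turn with a
train of four action potentials at 20 Hz while the others are recorded —
so the connectivity pipeline can be exercised end to end without any
experimental data.  For every ordered pair a connection is drawn Bernoulli
with a type-pair-specific probability; connected pairs get a log-normal
amplitude, a Gaussian latency, a per-AP release probability (failures) and
a multiplicative per-pulse depression factor.  EPSPs are double-exponential
kernels (rise 2 ms, decay 20 ms, unit peak) on top of Ornstein-Uhlenbeck
membrane noise around the cell's resting potential.  A configurable
fraction of cells and sweeps deliberately violates the quality-control
thresholds to exercise the QC stage.

Defaults mirror the experimentally reported structure: connection
probabilities A->A 15%, T->A 11%, T->T 8%, A->T 4%; median amplitudes
1.08 / 0.88 / 0.57 / 0.66 mV; a 66:34 thorny:athorny cell-type split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import Cell, PairRecording, PairScreen

__all__ = ["ScreenGroundTruth", "generate_screen", "psp_kernel"]

# keys are (post_type, pre_type); 'A->A' etc. read pre->post biologically
_DEFAULT_P = {("A", "A"): 0.15, ("A", "T"): 0.11,
              ("T", "T"): 0.08, ("T", "A"): 0.04}
_DEFAULT_AMP_MEDIAN = {("A", "A"): 1.08, ("A", "T"): 0.88,
                       ("T", "T"): 0.57, ("T", "A"): 0.66}
# per-pulse multiplicative depression; T->A visibly more depressing
_DEFAULT_DEPRESSION = {("A", "A"): 0.95, ("A", "T"): 0.80,
                       ("T", "T"): 0.88, ("T", "A"): 0.87}


@dataclass(frozen=True)
class ScreenGroundTruth:
    """Generator settings = the statistical structure of the screen."""

    n_cells: int = 64
    group_size: int = 8                 # cells patched simultaneously
    frac_athorny: float = 0.34
    p_connect: dict = field(default_factory=lambda: dict(_DEFAULT_P))
    amp_median_mv: dict = field(default_factory=lambda: dict(_DEFAULT_AMP_MEDIAN))
    amp_sigma: float = 0.4              # log-normal dispersion
    amp_event_cv: float = 0.2           # per-event quantal variability
    latency_mean_ms: float = 1.5
    latency_sd_ms: float = 0.3
    latency_min_ms: float = 0.3
    release_prob: float = 0.8
    depression: dict = field(default_factory=lambda: dict(_DEFAULT_DEPRESSION))
    noise_sd_mv: float = 0.2            # OU membrane noise sd
    noise_tau_ms: float = 2.0
    n_sweeps: int = 40
    fs_khz: float = 20.0
    trace_ms: float = 250.0
    ap1_ms: float = 20.0                # first AP; 50 ms spacing at 20 Hz
    rise_ms: float = 2.0
    decay_ms: float = 20.0
    vm_mean: float = -65.0
    vm_sd: float = 3.0
    frac_bad_cells: float = 0.05        # QC violators (Vm or Rs)
    frac_bad_sweeps: float = 0.03       # QC violators (AP or drift)

    def __post_init__(self):
        for p in self.p_connect.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("connection probabilities must lie in [0,1]")
        if not 0.0 <= self.release_prob <= 1.0:
            raise ValueError("release probability must lie in [0,1]")

    @property
    def ap_times(self) -> np.ndarray:
        return self.ap1_ms + 50.0 * np.arange(4)

    def stp_ratio(self, post_type: str, pre_type: str) -> float:
        """Imposed EPSP4/EPSP1 ratio = depression factor cubed."""
        return self.depression[(post_type, pre_type)] ** 3


def psp_kernel(t_ms: np.ndarray, rise_ms: float = 2.0,
               decay_ms: float = 20.0) -> np.ndarray:
    """Difference-of-exponentials PSP, normalized to unit peak."""
    t = np.maximum(t_ms, 0.0)
    k = np.exp(-t / decay_ms) - np.exp(-t / rise_ms)
    t_peak = rise_ms * decay_ms / (decay_ms - rise_ms) * np.log(decay_ms / rise_ms)
    peak = np.exp(-t_peak / decay_ms) - np.exp(-t_peak / rise_ms)
    out = k / peak
    out[t_ms < 0] = 0.0
    return out


def _ou_noise(rng, n_sweeps, n_samples, sd, tau_ms, fs_khz):
    """Ornstein-Uhlenbeck noise, stationary, sd and correlation time set."""
    if sd == 0:
        return np.zeros((n_sweeps, n_samples))
    alpha = np.exp(-1.0 / (tau_ms * fs_khz))
    drive = rng.normal(0.0, sd * np.sqrt(1 - alpha ** 2),
                       (n_sweeps, n_samples))
    out = np.empty((n_sweeps, n_samples))
    out[:, 0] = rng.normal(0.0, sd, n_sweeps)
    for k in range(1, n_samples):
        out[:, k] = alpha * out[:, k - 1] + drive[:, k]
    return out


def generate_screen(truth: ScreenGroundTruth | None = None, seed: int = 0
                    ) -> tuple[PairScreen, dict]:
    """Generate a synthetic screen plus its ground-truth tables.

    Returns (screen, tables) where tables has 'cells' and 'pairs'
    DataFrames recording every drawn parameter.  Deterministic per seed.
    """
    truth = truth or ScreenGroundTruth()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFA]))
    n_samples = int(round(truth.trace_ms * truth.fs_khz))
    t = np.arange(n_samples) / truth.fs_khz
    ap_times = truth.ap_times

    cells = []
    cell_rows = []
    for cid in range(truth.n_cells):
        ctype = "A" if rng.random() < truth.frac_athorny else "T"
        bad = rng.random() < truth.frac_bad_cells
        if bad and rng.random() < 0.5:
            vm = rng.uniform(-49.0, -44.0)     # too depolarized
            rs = rng.uniform(10.0, 25.0)
        elif bad:
            vm = rng.normal(truth.vm_mean, truth.vm_sd)
            rs = rng.uniform(31.0, 45.0)       # series resistance too high
        else:
            vm = min(rng.normal(truth.vm_mean, truth.vm_sd), -51.0)
            rs = rng.uniform(8.0, 28.0)
        cells.append(Cell(id=cid, type=ctype, vm=float(vm), rs=float(rs)))
        cell_rows.append({"id": cid, "type": ctype, "vm": vm, "rs": rs,
                          "qc_bad": bad})

    pairs = []
    pair_rows = []
    for g0 in range(0, truth.n_cells, truth.group_size):
        group = cells[g0:g0 + truth.group_size]
        for pre in group:
            for post in group:
                if pre.id == post.id:
                    continue
                key = (post.type, pre.type)
                connected = rng.random() < truth.p_connect[key]
                amp = lat = np.nan
                if connected:
                    amp = truth.amp_median_mv[key] * float(
                        rng.lognormal(0.0, truth.amp_sigma))
                    lat = max(rng.normal(truth.latency_mean_ms,
                                         truth.latency_sd_ms),
                              truth.latency_min_ms)
                dep = truth.depression[key]
                sweeps = np.tile(np.float32(post.vm), (truth.n_sweeps,
                                                       n_samples))
                sweeps = sweeps + _ou_noise(rng, truth.n_sweeps, n_samples,
                                            truth.noise_sd_mv,
                                            truth.noise_tau_ms,
                                            truth.fs_khz).astype(np.float32)
                ap_peaks = rng.normal(30.0, 5.0,
                                      (truth.n_sweeps, 4)).astype(np.float32)
                if connected:
                    for s in range(truth.n_sweeps):
                        for k, ap_t in enumerate(ap_times):
                            if rng.random() >= truth.release_prob:
                                continue
                            a = amp * dep ** k
                            if truth.amp_event_cv > 0:
                                a *= max(1.0 + truth.amp_event_cv *
                                         rng.standard_normal(), 0.05)
                            sweeps[s] += (a * psp_kernel(
                                t - ap_t - lat, truth.rise_ms,
                                truth.decay_ms)).astype(np.float32)
                # QC-violating sweeps: failed AP or drifting baseline
                # (never the first sweep, which anchors the drift reference)
                n_bad = min(rng.binomial(truth.n_sweeps, truth.frac_bad_sweeps),
                            truth.n_sweeps - 1)
                for s in rng.choice(np.arange(1, truth.n_sweeps), n_bad,
                                    replace=False):
                    if rng.random() < 0.5:
                        ap_peaks[s, rng.integers(4)] = rng.uniform(-10.0, -1.0)
                    else:
                        sweeps[s] += np.float32(0.15 * abs(post.vm))
                pairs.append(PairRecording(pre.id, post.id, sweeps, ap_peaks))
                pair_rows.append({
                    "pre_id": pre.id, "post_id": post.id,
                    "pre_type": pre.type, "post_type": post.type,
                    "connected": connected, "amplitude_mv": amp,
                    # expected amplitude of the averaged trace: failures
                    # dilute the mean first response
                    "avg_amplitude_mv": amp * truth.release_prob,
                    "latency_ms": lat, "release_prob": truth.release_prob,
                    "depression": dep, "stp_ratio": dep ** 3})

    screen = PairScreen(cells=cells, pairs=pairs, ap_times=ap_times,
                        fs_khz=truth.fs_khz)
    tables = {"cells": pd.DataFrame(cell_rows),
              "pairs": pd.DataFrame(pair_rows)}
    return screen, tables
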