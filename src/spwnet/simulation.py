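"""Time-stepped integration of the full network.

Forward-Euler at dt = 0.05 ms.  Conductance increments are event-based
(spikes scheduled with their synaptic latency), so the only continuous
dynamics are the membrane/adaptation equations and exponential conductance
decay, for which Euler is adequate; the exponential spike upswing is bounded
by the numeric cutoff V_stop.

State per neuron: V, u, refractory countdown, and three conductance
accumulators — one per transmitter class with distinct kinetics/reversal
(glutamatergic from A/T; GABAergic from B, tracked separately from C so
that the basket-cell current onto pyramids is recoverable as the LFP proxy).

The LFP proxy is the mean over pyramidal neurons of the instantaneous
basket-cell synaptic current g_i^B (V_i - E_rev^B), in pA per neuron: the
perisomatic inhibitory current thought to dominate the field potential in
stratum pyramidale.

The inner loop is compiled with numba.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.ndimage import gaussian_filter1d

from .network import Network, POP_ORDER

__all__ = [
    "SimConfig",
    "SimOutput",
    "integrate",
    "population_rate",
    "adaptation_increment",
    "depression_recovery",
    "update_depression",
]

@dataclass(frozen=True)
class SimConfig:
    """Integration settings.  Times in ms."""

    duration: float = 10_000.0   # simulated time after warmup
    dt: float = 0.05
    warmup: float = 500.0        # discarded initial window
    seed: int = 0
    record_raster: bool = True
    record_lfp: bool = True
    record_adaptation: bool = True
    record_bin: float = 1.0      # trace sampling interval

    def __post_init__(self):
        if self.dt <= 0 or self.dt > 0.1:
            raise ValueError("dt must lie in (0, 0.1] ms")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.warmup < 0:
            raise ValueError("warmup must be non-negative")


@dataclass
class SimOutput:
    """Recorded simulation results on a common time base (0 = end of warmup)."""

    net: Network
    cfg: SimConfig
    spike_t: np.ndarray          # ms
    spike_id: np.ndarray         # neuron ids
    time: np.ndarray             # trace sample times (ms)
    lfp: np.ndarray              # B->pyramidal current proxy (pA per neuron)
    u_mean: dict = field(default_factory=dict)   # pop name -> mean adaptation (pA)

    @property
    def duration(self) -> float:
        return self.cfg.duration

    def pop_spikes(self, pop: str) -> np.ndarray:
        sl = self.net.pop_slice(pop)
        m = (self.spike_id >= sl.start) & (self.spike_id < sl.stop)
        return self.spike_t[m]

    def rate(self, pop: str, bin_ms: float = 1.0,
             smooth_ms: float = 5.0) -> np.ndarray:
        """Population rate trace (spikes/s) on the trace time base."""
        sl = self.net.pop_slice(pop)
        return population_rate(self.spike_t, self.spike_id, sl,
                               self.duration, bin_ms=bin_ms,
                               smooth_ms=smooth_ms)


def population_rate(spike_t, spike_id, pop_slice: slice, duration: float,
                    bin_ms: float = 1.0, smooth_ms: float = 5.0) -> np.ndarray:
    """Binned population firing rate in spikes/s per neuron.

    Counts spikes of the population in fixed bins, divides by N*bin, and
    optionally applies Gaussian smoothing (sigma = ``smooth_ms``), which
    preserves the time integral of the rate.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    n_pop = pop_slice.stop - pop_slice.start
    if n_pop <= 0:
        raise ValueError("empty population")
    n_bins = int(round(duration / bin_ms))
    m = (spike_id >= pop_slice.start) & (spike_id < pop_slice.stop)
    counts, _ = np.histogram(spike_t[m], bins=n_bins, range=(0.0, n_bins * bin_ms))
    rate = counts / (n_pop * bin_ms * 1e-3)
    if smooth_ms and smooth_ms > 0:
        rate = gaussian_filter1d(rate, sigma=smooth_ms / bin_ms, mode="nearest")
    return rate


@njit(cache=True, fastmath=True)
def _run_kernel(n_steps, dt, n, n_pyr,
                # per-neuron constants
                inv_C, g_L, E_L, V_T, V_reset, a, b,
                inv_tau_u, refr_steps, Delta_T, I_ext, V_stop, pop_index,
                # synapses
                indptr, post, weight, pre_class,
                dec_E, dec_I, E_rev_I,
                delay_steps, edge_delay_steps, use_edge_delay,
                # depression
                std_on, tau_dep, eta_dep,
                # state (in/out)
                V, u,
                # recorders
                rec_stride, lfp_out, u_sum_out,
                spike_t, spike_id, max_spikes):
    """Integrate the network; returns (n_spikes, status).

    status: 0 ok, 1 spike-buffer overflow, 2 non-finite state.
    """
    gE = np.zeros(n)
    gB = np.zeros(n)
    gC = np.zeros(n)
    refr = np.zeros(n, dtype=np.int32)
    eff = np.ones(n)            # depression efficacy per presynaptic neuron
    e_deliver = np.ones(n)
    last_spike = np.full(n, -1.0e12)

    ring_len = delay_steps + 1
    ring_idx = np.empty((ring_len, n), dtype=np.int32)
    ring_cnt = np.zeros(ring_len, dtype=np.int32)

    acc_len = 1
    if use_edge_delay:
        acc_len = int(edge_delay_steps.max()) + 1
    acc = np.zeros((acc_len, n))

    n_spk = 0
    n_rec = 0
    inv_DT = np.empty(n)
    gLDT = np.empty(n)
    for i in range(n):
        inv_DT[i] = 1.0 / Delta_T[i]
        gLDT[i] = g_L[i] * Delta_T[i]

    for step in range(n_steps):
        # ---- deliver spikes scheduled for this step ----
        slot = step % ring_len
        for s in range(ring_cnt[slot]):
            j = ring_idx[slot, s]
            cls = pre_class[j]
            if cls == 0:
                w_fac = e_deliver[j] if std_on else 1.0
                for k in range(indptr[j], indptr[j + 1]):
                    tgt = post[k]
                    if std_on and tgt < n_pyr:
                        gE[tgt] += weight[k] * w_fac
                    else:
                        gE[tgt] += weight[k]
            elif cls == 1:
                for k in range(indptr[j], indptr[j + 1]):
                    gB[post[k]] += weight[k]
            else:
                for k in range(indptr[j], indptr[j + 1]):
                    gC[post[k]] += weight[k]
        ring_cnt[slot] = 0
        if use_edge_delay:
            aslot = step % acc_len
            for i in range(n):
                gE[i] += acc[aslot, i]
                acc[aslot, i] = 0.0

        # ---- integrate neurons ----
        t_now = step * dt
        for i in range(n):
            gE[i] *= dec_E
            gB[i] *= dec_I
            gC[i] *= dec_I
            if refr[i] > 0:
                refr[i] -= 1
                Vi = V_reset[i]
                V[i] = Vi
                u[i] += dt * inv_tau_u[i] * (a[i] * (Vi - E_L[i]) - u[i])
                continue
            Vi = V[i]
            I_syn = -gE[i] * Vi + (gB[i] + gC[i]) * (E_rev_I - Vi)
            arg = (Vi - V_T[i]) * inv_DT[i]
            if arg > -14.0:
                if arg > 16.0:
                    arg = 16.0
                I_exp = gLDT[i] * math.exp(arg)
            else:
                I_exp = 0.0
            dV = (-g_L[i] * (Vi - E_L[i]) + I_exp - u[i] + I_ext[i] + I_syn) * inv_C[i]
            u[i] += dt * inv_tau_u[i] * (a[i] * (Vi - E_L[i]) - u[i])
            Vi += dt * dV
            if Vi >= V_stop[i]:
                # spike
                if n_spk >= max_spikes:
                    return n_spk, 1
                spike_t[n_spk] = t_now + dt
                spike_id[n_spk] = i
                n_spk += 1
                V[i] = V_reset[i]
                u[i] += b[i]
                refr[i] = refr_steps[i]
                if std_on and pre_class[i] == 0:
                    # closed-form recovery since the previous spike
                    e0 = eff[i]
                    e_rec = 1.0 - (1.0 - e0) * math.exp(-(t_now + dt - last_spike[i]) / tau_dep)
                    e_deliver[i] = e_rec
                    eff[i] = e_rec * (1.0 - eta_dep)
                    last_spike[i] = t_now + dt
                if use_edge_delay and pre_class[i] == 0:
                    w_fac = e_deliver[i] if std_on else 1.0
                    for k in range(indptr[i], indptr[i + 1]):
                        dslot = (step + edge_delay_steps[k]) % acc_len
                        tgt = post[k]
                        if std_on and tgt < n_pyr:
                            acc[dslot, tgt] += weight[k] * w_fac
                        else:
                            acc[dslot, tgt] += weight[k]
                else:
                    dslot = (step + delay_steps) % ring_len
                    ring_idx[dslot, ring_cnt[dslot]] = i
                    ring_cnt[dslot] += 1
            else:
                V[i] = Vi

        # ---- recorders ----
        if (step + 1) % rec_stride == 0:
            lfp = 0.0
            for i in range(n_pyr):
                lfp += gB[i] * (V[i] - E_rev_I)
            lfp /= n_pyr
            if not math.isfinite(lfp):
                return n_spk, 2
            lfp_out[n_rec] = lfp
            for p in range(4):
                u_sum_out[p, n_rec] = 0.0
            for i in range(n):
                u_sum_out[pop_index[i], n_rec] += u[i]
            n_rec += 1

    return n_spk, 0


def integrate(net: Network, cfg: SimConfig) -> SimOutput:
    """Run the network for ``cfg.warmup + cfg.duration`` ms and record.

    Initial conditions: V ~ Uniform(E_L, V_T) per neuron, u = 0, g = 0; the
    warmup window is discarded and the returned time base starts at 0.
    Reproducible for a given (network, cfg.seed).
    """
    dt = cfg.dt
    n_steps = int(round((cfg.warmup + cfg.duration) / dt))
    n = net.n_neurons
    n_pyr = net.n_pyramidal

    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x51A]))
    V = net.E_L + rng.random(n) * (net.V_T - net.E_L)
    u = np.zeros(n)

    pre_class = np.where(net.pop_index <= 1, 0,
                         np.where(net.pop_index == 2, 1, 2)).astype(np.int8)
    tau_d_E = net.syn.tau_d["A"]
    tau_d_I = net.syn.tau_d["B"]
    E_rev_I = net.syn.E_rev["B"]
    dec_E = math.exp(-dt / tau_d_E)
    dec_I = math.exp(-dt / tau_d_I)

    delay_steps = max(1, int(round(net.syn.tau_l / dt)))
    uniform = np.allclose(net.latency, net.syn.tau_l)
    if uniform:
        edge_delay_steps = np.zeros(1, dtype=np.int32)
        use_edge_delay = False
    else:
        edge_delay_steps = np.maximum(1, np.round(net.latency / dt)).astype(np.int32)
        use_edge_delay = True

    rec_stride = max(1, int(round(cfg.record_bin / dt)))
    n_rec = n_steps // rec_stride
    lfp_out = np.zeros(n_rec)
    u_sum_out = np.zeros((4, n_rec))

    # generous raster buffer: sized for sustained 20x the expected mean rate
    max_spikes = int(2e5 * (cfg.warmup + cfg.duration) / 1000.0) + 1_000_000
    spike_t = np.empty(max_spikes)
    spike_id = np.empty(max_spikes, dtype=np.int32)

    refr_steps = np.round(net.tau_ref / dt).astype(np.int32)
    n_spk, status = _run_kernel(
        n_steps, dt, n, n_pyr,
        1.0 / net.C, net.g_L, net.E_L, net.V_T, net.V_reset, net.a, net.b,
        1.0 / net.tau_u, refr_steps, net.Delta_T, net.I_ext, net.V_stop,
        net.pop_index.astype(np.int8),
        net.indptr, net.post, net.weight.astype(np.float64), pre_class,
        dec_E, dec_I, E_rev_I,
        delay_steps, edge_delay_steps, use_edge_delay,
        net.dep.enabled, net.dep.tau_dep, net.dep.eta_dep,
        V, u,
        rec_stride, lfp_out, u_sum_out,
        spike_t, spike_id, max_spikes)

    if status == 1:
        raise RuntimeError("spike buffer overflow: runaway network activity")
    if status == 2:
        raise FloatingPointError("non-finite network state during integration")

    # trim warmup, shift time base to 0
    st = spike_t[:n_spk] - cfg.warmup
    sid = spike_id[:n_spk]
    keep = st >= 0
    st, sid = st[keep], sid[keep]

    t_rec = (np.arange(n_rec) + 1) * (rec_stride * dt) - cfg.warmup
    keep_rec = t_rec > 0
    time = t_rec[keep_rec]
    lfp = lfp_out[keep_rec]
    u_mean = {}
    for p, name in enumerate(POP_ORDER):
        size = int(net.sizes[p])
        u_mean[name] = (u_sum_out[p, keep_rec] / size) if size else np.zeros(keep_rec.sum())

    if not cfg.record_raster:
        st, sid = st[:0], sid[:0]
    return SimOutput(net=net, cfg=cfg, spike_t=st, spike_id=sid,
                     time=time, lfp=lfp if cfg.record_lfp else lfp[:0],
                     u_mean=u_mean if cfg.record_adaptation else {})


# ---------------------------------------------------------------------------
# short-term depression helpers (the engine applies the same rule inline)

def depression_recovery(e0: float, dt: float, tau_dep: float) -> float:
    """Closed-form recovery e(t) = 1 - (1 - e0) exp(-dt/tau_dep)."""
    return 1.0 - (1.0 - e0) * math.exp(-dt / tau_dep)


def update_depression(e, dt: float, spiked, tau_dep: float, eta_dep: float):
    """One update of synaptic efficacies: continuous recovery toward 1 over
    ``dt`` ms, then a multiplicative decrement (1 - eta_dep) where the
    presynaptic neuron spiked.  ``e`` and ``spiked`` may be scalars or arrays.
    """
    e = 1.0 - (1.0 - np.asarray(e, dtype=float)) * math.exp(-dt / tau_dep)
    return np.where(spiked, e * (1.0 - eta_dep), e)


def adaptation_increment(sim: SimOutput, onset: float, offset: float,
                         baseline_ms: float = 200.0, post_ms: float = 100.0):
    """Relative increment of each population's mean adaptation current
    around one event: (u(t) - u0)/u0 with u0 the mean over
    [onset - baseline_ms, onset].

    Returns (t_rel, {pop: trace}) with t_rel = 0 at onset.
    """
    if onset < baseline_ms:
        raise ValueError("need at least the baseline window before onset")
    t = sim.time
    m_base = (t >= onset - baseline_ms) & (t < onset)
    m_win = (t >= onset - baseline_ms) & (t <= offset + post_ms)
    out = {}
    for pop, trace in sim.u_mean.items():
        base = float(trace[m_base].mean())
        if base <= 0:
            raise ValueError(f"non-positive adaptation baseline for {pop}: "
                             "relative increment undefined")
        out[pop] = trace[m_win] / base - 1.0
    return t[m_win] - onset, out
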