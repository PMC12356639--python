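"""Adaptive exponential integrate-and-fire (AdEx) single-neuron dynamics.

Each neuron carries a membrane potential ``V`` and an adaptation current
``u``.  Between spikes::

    C dV/dt = -g_L (V - E_L) + g_L * Delta_T * exp((V - V_T)/Delta_T)
              - u + I_ext + I_syn
    tau_u du/dt = -u + a (V - E_L)

When ``V`` reaches the numeric cutoff ``V_stop`` a spike is emitted: ``V``
is reset to ``V_reset`` and clamped there for a refractory time
``tau_ref``, and ``u`` jumps by ``b``.  The four populations of the sharp
wave model (athorny pyramids A, thorny pyramids T, PV+ basket cells B,
anti-SPW interneurons C) are instances of this model with different
constants; athorny cells are reset *above* threshold, which is how AdEx
produces the bursting seen in that cell type.

This module also provides the single-neuron characterisation used to sanity
check the population parameters: f-I curves and the non-transient rheobase,
both numerically (by simulating) and in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "CELL_PARAMS",
    "derivatives",
    "apply_spike",
    "simulate_isolated",
    "fi_curve",
    "fi_curve_table",
    "rheobase",
]


@dataclass(frozen=True)
class NeuronParams:
    """AdEx constants for one population.

    Units: capacitance pF, conductances nS, potentials mV, currents pA,
    times ms.  With these units conductance*voltage gives pA and pA/pF
    gives mV/ms, so no conversion factors appear in the equations.
    """

    C: float            # membrane capacitance (pF)
    g_L: float          # leak conductance (nS)
    E_L: float          # resting potential (mV)
    V_T: float          # threshold potential (mV)
    V_reset: float      # post-spike reset potential (mV)
    a: float            # adaptation voltage coupling (nS)
    b: float            # spike-triggered adaptation increment (pA)
    tau_u: float        # adaptation time constant (ms)
    tau_ref: float = 3.0    # refractory period (ms)
    Delta_T: float = 2.5    # exponential slope factor (mV)
    I_ext: float = 0.0      # constant background current (pA)
    V_stop: float | None = None  # numeric spike cutoff (mV); default V_T + 10*Delta_T

    def __post_init__(self) -> None:
        if self.V_stop is None:
            object.__setattr__(self, "V_stop", self.V_T + 10.0 * self.Delta_T)
        if self.C <= 0 or self.g_L <= 0 or self.tau_u <= 0 or self.Delta_T <= 0:
            raise ValueError("C, g_L, tau_u and Delta_T must be positive")
        if self.tau_ref < 0 or self.a < 0 or self.b < 0:
            raise ValueError("tau_ref, a and b must be non-negative")
        if self.V_stop <= self.V_T:
            raise ValueError("V_stop must exceed V_T")

    def with_(self, **overrides) -> "NeuronParams":
        return replace(self, **overrides)


@dataclass
class NeuronState:
    """Dynamic variables of one neuron."""

    V: float                    # membrane potential (mV)
    u: float = 0.0              # adaptation current (pA)
    refr_remaining: float = 0.0  # time left clamped at V_reset (ms)


#: Population constants of the sharp-wave network: athorny (A) and thorny (T)
#: pyramids, PV+ basket cells (B) and anti-SPW interneurons (C).  Background
#: currents sit ~10% above each population's non-transient rheobase (~40%
#: for C, which must keep the rest of the network inhibited between events).
CELL_PARAMS: dict[str, NeuronParams] = {
    "A": NeuronParams(C=200, g_L=8, E_L=-60, V_T=-48, V_reset=-42,
                      a=4, b=85, tau_u=200, I_ext=140),
    "T": NeuronParams(C=200, g_L=11, E_L=-70, V_T=-44, V_reset=-46,
                      a=0, b=150, tau_u=200, I_ext=285),
    "B": NeuronParams(C=100, g_L=8, E_L=-55, V_T=-40, V_reset=-57,
                      a=6, b=25, tau_u=50, I_ext=180),
    "C": NeuronParams(C=100, g_L=5, E_L=-57, V_T=-40, V_reset=-52,
                      a=2.5, b=20, tau_u=100, I_ext=160),
}

POP_SIZES: dict[str, int] = {"A": 2700, "T": 5300, "B": 150, "C": 100}


def derivatives(state: NeuronState, params: NeuronParams,
                I_syn: float = 0.0) -> tuple[float, float]:
    """Instantaneous (dV/dt, du/dt) in (mV/ms, pA/ms) for a non-refractory neuron.

    Raises ``FloatingPointError`` on non-finite state, which signals numeric
    blow-up to the caller (the integrator relies on a finite ``V_stop``).
    """
    V, u = state.V, state.u
    if not (math.isfinite(V) and math.isfinite(u)):
        raise FloatingPointError("non-finite neuron state")
    p = params
    I_exp = p.g_L * p.Delta_T * math.exp((V - p.V_T) / p.Delta_T)
    dV = (-p.g_L * (V - p.E_L) + I_exp - u + p.I_ext + I_syn) / p.C
    du = (-u + p.a * (V - p.E_L)) / p.tau_u
    return dV, du


def apply_spike(state: NeuronState, params: NeuronParams) -> NeuronState:
    """Spike/reset rule: V -> V_reset, clamp for tau_ref, u += b."""
    return NeuronState(V=params.V_reset, u=state.u + params.b,
                       refr_remaining=params.tau_ref)


def simulate_isolated(params: NeuronParams, I: float, sim_time: float,
                      dt: float = 0.05, V0: float | None = None) -> np.ndarray:
    """Forward-Euler spike times (ms) of one neuron under constant current ``I``.

    ``I`` replaces I_ext (the drive is the only current applied).  During the
    refractory period V is clamped at V_reset while u keeps evolving.
    """
    p = params
    V = p.E_L if V0 is None else V0
    u = 0.0
    refr = 0.0
    n = int(round(sim_time / dt))
    spikes = []
    for k in range(n):
        if refr > 0.0:
            refr -= dt
            V = p.V_reset
            u += dt * (-u + p.a * (V - p.E_L)) / p.tau_u
            continue
        arg = min((V - p.V_T) / p.Delta_T, 16.0)
        I_exp = p.g_L * p.Delta_T * math.exp(arg)
        dV = (-p.g_L * (V - p.E_L) + I_exp - u + I) / p.C
        du = (-u + p.a * (V - p.E_L)) / p.tau_u
        V += dt * dV
        u += dt * du
        if V >= p.V_stop:
            spikes.append((k + 1) * dt)
            V = p.V_reset
            u += p.b
            refr = p.tau_ref
    return np.asarray(spikes)


def fi_curve(params: NeuronParams, currents, sim_time: float = 5000.0,
             discard: float = 1000.0, dt: float = 0.05) -> np.ndarray:
    """Steady-state firing rate (spikes/s) for each constant current (pA).

    An initial ``discard`` window (default 1 s) removes onset transients so
    class-2 cells that spike only transiently report 0.
    """
    rates = np.empty(len(currents))
    for i, I in enumerate(currents):
        t = simulate_isolated(params, float(I), sim_time, dt=dt)
        t = t[t >= discard]
        rates[i] = len(t) / ((sim_time - discard) / 1000.0)
    return rates


def fi_curve_table(params: NeuronParams, currents, **kwargs):
    """f-I curve as a table with columns (current_pA, rate_hz), ready for
    ``.to_csv(path, index=False)``."""
    import pandas as pd
    return pd.DataFrame({"current_pA": np.asarray(currents, dtype=float),
                         "rate_hz": fi_curve(params, currents, **kwargs)})


def _fires_sustained(params: NeuronParams, I: float, sim_time: float,
                     dt: float) -> bool:
    """Non-transient firing criterion: spikes persist into the last 20%."""
    t = simulate_isolated(params, I, sim_time, dt=dt)
    return len(t) > 0 and t[-1] >= 0.8 * sim_time


def rheobase(params: NeuronParams, mode: str = "closed_form",
             tol: float = 0.5, sim_time: float = 5000.0,
             dt: float = 0.05) -> float:
    """Minimal constant current (pA) giving sustained (non-transient) firing.

    ``closed_form`` evaluates the saddle-node threshold current

        (g_L + a) * [V_T - E_L - Delta_T + Delta_T * ln(1 + a/g_L)]

    which for a=0 reduces to the exponential-IF rheobase
    g_L (V_T - E_L - Delta_T).  ``numeric`` bisects on the sustained-firing
    criterion (spiking persists through the last 20% of a ``sim_time``
    simulation) to within ``tol`` pA.
    """
    p = params
    if mode == "closed_form":
        return (p.g_L + p.a) * (p.V_T - p.E_L - p.Delta_T
                                + p.Delta_T * math.log1p(p.a / p.g_L))
    if mode != "numeric":
        raise ValueError(f"unknown mode {mode!r}")
    lo = 0.0
    hi = max(2.0 * rheobase(p, "closed_form"), 50.0)
    for _ in range(20):  # expand bracket if needed
        if _fires_sustained(p, hi, sim_time, dt):
            break
        hi *= 2.0
    else:
        raise RuntimeError("no sustained firing found: non-spiking parameter set")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _fires_sustained(p, mid, sim_time, dt):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
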