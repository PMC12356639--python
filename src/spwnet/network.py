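"""Four-population network construction.

Populations are laid out in the fixed order A (athorny), T (thorny),
B (PV+ basket), C (anti-SPW interneuron).  Every ordered pair of distinct
neurons (pre j in population J, post i in population I) is connected
independently with probability ``p[I, J]``; a connection delivers a
conductance increment ``w[I, J]`` (nS) after a latency ``tau_l`` (ms), onto
the transmitter class of the presynaptic population (glutamatergic for A/T:
E_rev = 0 mV, tau_d = 2 ms; GABAergic for B/C: E_rev = -70 mV, tau_d = 4 ms).

Connectivity among the pyramidal populations follows the paired-recording
measurements (A->A 15%, T->A 11%, A->T 4%, T->T 8%); all connections
involving interneurons use a common 20%.  Optional model variants add
short-term depression on excitatory-to-excitatory synapses and quenched
heterogeneity of E->E weights/latencies and excitatory E_L / g_L.

The network is stored in compressed sparse row form keyed by the
*presynaptic* neuron, which is the natural layout for spike propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .neuron import CELL_PARAMS, POP_SIZES, NeuronParams

__all__ = [
    "POP_ORDER",
    "PopulationSpec",
    "ConnectivitySpec",
    "SynapseSpec",
    "DepressionSpec",
    "HeterogeneitySpec",
    "Network",
    "default_populations",
    "build_network",
    "default_network",
    "scale_ee_weights",
    "scale_eb_weights",
]

POP_ORDER = ("A", "T", "B", "C")
_EXC = ("A", "T")  # glutamatergic populations


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    size: int
    params: NeuronParams

    def __post_init__(self):
        if self.name not in POP_ORDER:
            raise ValueError(f"unknown population {self.name!r}")
        if self.size < 0:
            raise ValueError("population size must be non-negative")


def default_populations() -> tuple[PopulationSpec, ...]:
    """A/T split 2700/5300 (34:66 of 8000 pyramids) plus 150 B and 100 C."""
    return tuple(PopulationSpec(n, POP_SIZES[n], CELL_PARAMS[n]) for n in POP_ORDER)


def _as_matrix(m, name: str) -> np.ndarray:
    arr = np.asarray(m, dtype=float)
    if arr.shape != (4, 4):
        raise ValueError(f"{name} must be 4x4 (post x pre, order A,T,B,C)")
    return arr


@dataclass(frozen=True)
class ConnectivitySpec:
    """Connection probabilities, row = postsynaptic population, col = presynaptic."""

    p: np.ndarray = field(default_factory=lambda: np.array([
        # from:  A     T     B     C
        [0.15, 0.11, 0.20, 0.20],   # onto A
        [0.04, 0.08, 0.20, 0.20],   # onto T
        [0.20, 0.20, 0.20, 0.20],   # onto B
        [0.20, 0.20, 0.20, 0.20],   # onto C
    ]))

    def __post_init__(self):
        p = _as_matrix(self.p, "p")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("connection probabilities must lie in [0, 1]")
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class SynapseSpec:
    """Weights (nS) and per-presynaptic-class transmitter constants."""

    w: np.ndarray = field(default_factory=lambda: np.array([
        # from:  A     T     B     C
        [0.20, 0.20, 2.15, 15.0],   # onto A
        [0.20, 0.20, 0.80, 15.0],   # onto T
        [0.70, 0.50, 6.00,  9.0],   # onto B
        [0.10, 0.05, 5.00,  3.0],   # onto C
    ]))
    tau_d: dict = field(default_factory=lambda: {"A": 2.0, "T": 2.0, "B": 4.0, "C": 4.0})
    E_rev: dict = field(default_factory=lambda: {"A": 0.0, "T": 0.0, "B": -70.0, "C": -70.0})
    tau_l: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "w", _as_matrix(self.w, "w"))
        if self.tau_l <= 0:
            raise ValueError("synaptic latency must be positive")


@dataclass(frozen=True)
class DepressionSpec:
    """Short-term depression of E->E synapses (per-presynaptic-spike decrement
    eta_dep with exponential recovery tau_dep)."""

    enabled: bool = False
    tau_dep: float = 250.0  # ms
    eta_dep: float = 0.2

    def __post_init__(self):
        if not 0.0 <= self.eta_dep < 1.0:
            raise ValueError("eta_dep must lie in [0, 1)")
        if self.tau_dep <= 0:
            raise ValueError("tau_dep must be positive")


@dataclass(frozen=True)
class HeterogeneitySpec:
    """Quenched variability: E->E weights and latencies get relative sd 1/4;
    excitatory E_L gets sd |E_L|/20 and g_L relative sd 1/4.  Samples are
    truncated-normal (resampled) to keep weights, latencies and g_L positive.
    """

    enabled: bool = False
    cv_weight: float = 0.25
    cv_latency: float = 0.25
    sd_EL_rel: float = 0.05
    cv_gL: float = 0.25

    def __post_init__(self):
        for f in (self.cv_weight, self.cv_latency, self.sd_EL_rel, self.cv_gL):
            if f < 0:
                raise ValueError("heterogeneity sds must be non-negative")


def _trunc_normal(rng, mean, sd, size, low=0.0) -> np.ndarray:
    """Normal samples resampled until strictly above ``low``."""
    x = rng.normal(mean, sd, size)
    bad = x <= low
    while bad.any():
        x[bad] = rng.normal(np.broadcast_to(mean, x.shape)[bad] if np.ndim(mean) else mean,
                            sd, bad.sum())
        bad = x <= low
    return x


@dataclass
class Network:
    """Built network: per-neuron parameter arrays plus a presynaptic-CSR
    synapse table (edges sorted by presynaptic neuron)."""

    pops: tuple[PopulationSpec, ...]
    conn: ConnectivitySpec
    syn: SynapseSpec
    dep: DepressionSpec
    het: HeterogeneitySpec
    seed: int
    # layout
    sizes: np.ndarray          # (4,) neuron counts in POP_ORDER
    offsets: np.ndarray        # (5,) population start indices
    pop_index: np.ndarray      # (N,) population id per neuron
    # per-neuron parameters (heterogeneity already applied)
    C: np.ndarray
    g_L: np.ndarray
    E_L: np.ndarray
    V_T: np.ndarray
    V_reset: np.ndarray
    a: np.ndarray
    b: np.ndarray
    tau_u: np.ndarray
    tau_ref: np.ndarray
    Delta_T: np.ndarray
    I_ext: np.ndarray
    V_stop: np.ndarray
    # synapse table (CSR by presynaptic neuron)
    indptr: np.ndarray         # (N+1,)
    post: np.ndarray           # (n_edges,) int32
    weight: np.ndarray         # (n_edges,) float32, nS
    latency: np.ndarray        # (n_edges,) float32, ms

    @property
    def n_neurons(self) -> int:
        return int(self.offsets[-1])

    @property
    def n_pyramidal(self) -> int:
        return int(self.offsets[2])  # A then T

    @property
    def n_edges(self) -> int:
        return len(self.post)

    def pop_slice(self, name: str) -> slice:
        i = POP_ORDER.index(name)
        return slice(int(self.offsets[i]), int(self.offsets[i + 1]))

    def block_edge_mask(self, post_pop: str, pre_pop: str) -> np.ndarray:
        """Boolean mask over edges belonging to one (post, pre) block."""
        j = POP_ORDER.index(pre_pop)
        pre_ids = np.repeat(np.arange(self.n_neurons), np.diff(self.indptr))
        pre_ok = (pre_ids >= self.offsets[j]) & (pre_ids < self.offsets[j + 1])
        i = POP_ORDER.index(post_pop)
        post_ok = (self.post >= self.offsets[i]) & (self.post < self.offsets[i + 1])
        return pre_ok & post_ok

    def to_edgelist(self) -> pd.DataFrame:
        pre_ids = np.repeat(np.arange(self.n_neurons), np.diff(self.indptr))
        return pd.DataFrame({"pre": pre_ids, "post": self.post,
                             "weight_nS": self.weight, "latency_ms": self.latency})

    def save_edgelist(self, path) -> None:
        """Edge list to CSV; a ``.gz`` suffix compresses transparently."""
        self.to_edgelist().to_csv(path, index=False)

    def with_edgelist(self, edges: pd.DataFrame) -> "Network":
        """Copy of this network with the synapse table replaced by ``edges``
        (columns pre, post, weight_nS, latency_ms; used to re-import a saved
        edge list into a network with the same population layout)."""
        n = self.n_neurons
        if edges.pre.max() >= n or edges.post.max() >= n:
            raise ValueError("edge list references neurons outside the network")
        order = np.argsort(edges.pre.to_numpy(), kind="stable")
        pre = edges.pre.to_numpy()[order].astype(np.int32)
        indptr = np.zeros(n + 1, dtype=np.int64)
        np.add.at(indptr, pre + 1, 1)
        return replace(self, indptr=np.cumsum(indptr),
                       post=edges.post.to_numpy()[order].astype(np.int32),
                       weight=edges.weight_nS.to_numpy()[order].astype(np.float32),
                       latency=edges.latency_ms.to_numpy()[order].astype(np.float32))


def build_network(pops=None, conn=None, syn=None, dep=None, het=None,
                  seed: int = 0) -> Network:
    """Sample the Bernoulli connectivity and assemble all engine arrays.

    Reproducible: the same ``seed`` yields an identical synapse table.
    Autapses are excluded; reciprocal connections are sampled independently.
    """
    pops = tuple(pops) if pops is not None else default_populations()
    if tuple(p.name for p in pops) != POP_ORDER:
        raise ValueError(f"populations must be given in order {POP_ORDER}")
    conn = conn or ConnectivitySpec()
    syn = syn or SynapseSpec()
    dep = dep or DepressionSpec()
    het = het or HeterogeneitySpec()

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E7]))
    sizes = np.array([p.size for p in pops], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    n = int(offsets[-1])
    pop_index = np.repeat(np.arange(4), sizes).astype(np.int8)

    # per-neuron parameters
    cols = {}
    for fname in ("C", "g_L", "E_L", "V_T", "V_reset", "a", "b",
                  "tau_u", "tau_ref", "Delta_T", "I_ext", "V_stop"):
        cols[fname] = np.concatenate([
            np.full(p.size, getattr(p.params, fname), dtype=np.float64)
            for p in pops])
    if het.enabled:
        for name in _EXC:
            sl = slice(int(offsets[POP_ORDER.index(name)]),
                       int(offsets[POP_ORDER.index(name) + 1]))
            p = pops[POP_ORDER.index(name)].params
            if het.sd_EL_rel > 0:
                cols["E_L"][sl] = rng.normal(p.E_L, het.sd_EL_rel * abs(p.E_L),
                                             sl.stop - sl.start)
            if het.cv_gL > 0:
                cols["g_L"][sl] = _trunc_normal(rng, p.g_L, het.cv_gL * p.g_L,
                                                sl.stop - sl.start)

    # Bernoulli edges, block by block (post population I, pre population J)
    pre_list, post_list, w_list, lat_list = [], [], [], []
    for i, post_pop in enumerate(pops):
        for j, pre_pop in enumerate(pops):
            p_ij = conn.p[i, j]
            if p_ij == 0.0 or post_pop.size == 0 or pre_pop.size == 0:
                continue
            n_pre, n_post = pre_pop.size, post_pop.size
            chunk = max(1, int(4e6 // max(n_post, 1)))
            for start in range(0, n_pre, chunk):
                stop = min(start + chunk, n_pre)
                mask = rng.random((stop - start, n_post)) < p_ij
                if i == j:  # no autapses
                    rows = np.arange(start, stop)
                    mask[np.arange(stop - start), rows] = False
                pre_loc, post_loc = np.nonzero(mask)
                m = len(pre_loc)
                if m == 0:
                    continue
                pre_list.append((pre_loc + start + offsets[j]).astype(np.int32))
                post_list.append((post_loc + offsets[i]).astype(np.int32))
                is_ee = post_pop.name in _EXC and pre_pop.name in _EXC
                w0 = syn.w[i, j]
                if het.enabled and is_ee and het.cv_weight > 0:
                    w = _trunc_normal(rng, w0, het.cv_weight * w0, m)
                else:
                    w = np.full(m, w0)
                if het.enabled and is_ee and het.cv_latency > 0:
                    lat = _trunc_normal(rng, syn.tau_l, het.cv_latency * syn.tau_l, m)
                else:
                    lat = np.full(m, syn.tau_l)
                w_list.append(w.astype(np.float32))
                lat_list.append(lat.astype(np.float32))

    if pre_list:
        pre = np.concatenate(pre_list)
        post = np.concatenate(post_list)
        weight = np.concatenate(w_list)
        latency = np.concatenate(lat_list)
        order = np.argsort(pre, kind="stable")
        pre, post = pre[order], post[order]
        weight, latency = weight[order], latency[order]
        indptr = np.zeros(n + 1, dtype=np.int64)
        np.add.at(indptr, pre + 1, 1)
        indptr = np.cumsum(indptr)
    else:
        post = np.empty(0, dtype=np.int32)
        weight = latency = np.empty(0, dtype=np.float32)
        indptr = np.zeros(n + 1, dtype=np.int64)

    return Network(pops=pops, conn=conn, syn=syn, dep=dep, het=het,
                   seed=int(seed), sizes=sizes, offsets=offsets,
                   pop_index=pop_index, indptr=indptr, post=post,
                   weight=weight, latency=latency, **cols)


def default_network(seed: int = 0, **kwargs) -> Network:
    """Network with all default parameters."""
    return build_network(seed=seed, **kwargs)


def _scale_blocks(net: Network, blocks, factor: float) -> Network:
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    mask = np.zeros(net.n_edges, dtype=bool)
    for post_pop, pre_pop in blocks:
        mask |= net.block_edge_mask(post_pop, pre_pop)
    weight = net.weight.copy()
    weight[mask] = weight[mask] * np.float32(factor)
    w = net.syn.w.copy()
    for post_pop, pre_pop in blocks:
        w[POP_ORDER.index(post_pop), POP_ORDER.index(pre_pop)] *= factor
    return replace(net, weight=weight, syn=replace(net.syn, w=w))


def scale_ee_weights(net: Network, factor: float) -> Network:
    """Multiply all four excitatory-to-excitatory weight blocks by ``factor``.

    This is the common-factor rescaling used in the connectivity sweeps to
    keep sharp-wave events at a comparable LFP size.
    """
    return _scale_blocks(net, [(i, j) for i in _EXC for j in _EXC], factor)


def scale_eb_weights(net: Network, factor: float) -> Network:
    """Multiply the pyramidal->basket (A->B and T->B) weights by ``factor``."""
    return _scale_blocks(net, [("B", "A"), ("B", "T")], factor)
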