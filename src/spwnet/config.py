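"""Run configuration: a validated, YAML-backed schema whose defaults
reproduce the published parameter tables exactly.

A configuration file only needs the values that differ from the defaults;
an empty file yields the default model.  Unknown keys are rejected with a
field-level error.  The single global seed is expanded into named
per-stage streams (network construction, simulation, screen generation)
so that toggling one stage does not perturb the randomness of another.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .neuron import NeuronParams, CELL_PARAMS, POP_SIZES
from .network import (ConnectivitySpec, SynapseSpec, DepressionSpec,
                      HeterogeneitySpec, PopulationSpec, Network,
                      build_network, POP_ORDER)
from .simulation import SimConfig
from .synthetic import ScreenGroundTruth

__all__ = ["RunConfig", "load_config", "stage_seed", "network_from_config",
           "simconfig_from_config"]

_STAGES = {"network": 11, "simulation": 12, "screen": 13, "sweep": 14}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    ss = np.random.SeedSequence([int(seed), _STAGES[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NeuronBlock(_Block):
    C: float
    g_L: float
    E_L: float
    V_thr: float            # Table column name; maps to NeuronParams.V_T
    V_reset: float
    a: float
    b: float
    tau_u: float
    tau_ref: float = 3.0
    Delta_T: float = 2.5
    I_ext: float
    V_stop: float | None = None

    def to_params(self) -> NeuronParams:
        d = self.model_dump()
        d["V_T"] = d.pop("V_thr")
        return NeuronParams(**d)


def _neuron_default(pop: str) -> NeuronBlock:
    p = CELL_PARAMS[pop]
    return NeuronBlock(C=p.C, g_L=p.g_L, E_L=p.E_L, V_thr=p.V_T,
                       V_reset=p.V_reset, a=p.a, b=p.b, tau_u=p.tau_u,
                       tau_ref=p.tau_ref, Delta_T=p.Delta_T, I_ext=p.I_ext)


class PopulationsBlock(_Block):
    sizes: dict[str, int] = Field(default_factory=lambda: dict(POP_SIZES))
    A: NeuronBlock = Field(default_factory=lambda: _neuron_default("A"))
    T: NeuronBlock = Field(default_factory=lambda: _neuron_default("T"))
    B: NeuronBlock = Field(default_factory=lambda: _neuron_default("B"))
    C: NeuronBlock = Field(default_factory=lambda: _neuron_default("C"))

    @field_validator("sizes")
    @classmethod
    def _check_sizes(cls, v):
        unknown = set(v) - set(POP_ORDER)
        if unknown:
            raise ValueError(f"unknown population(s) {sorted(unknown)}")
        if any(n < 0 for n in v.values()):
            raise ValueError("population sizes must be non-negative")
        return {**dict(POP_SIZES), **v}


class ConnectivityBlock(_Block):
    """Overrides of single entries, e.g. ``p_TA: 0.0`` (post T, pre A)."""
    model_config = ConfigDict(extra="allow")

    def to_spec(self) -> ConnectivitySpec:
        p = ConnectivitySpec().p.copy()
        for key, val in (self.model_extra or {}).items():
            if not (key.startswith("p_") and len(key) == 4
                    and key[2] in POP_ORDER and key[3] in POP_ORDER):
                raise ValueError(f"unknown connectivity key {key!r}")
            if not isinstance(val, (int, float)) or not 0 <= val <= 1:
                raise ValueError(f"{key} must be a probability in [0, 1]")
            p[POP_ORDER.index(key[2]), POP_ORDER.index(key[3])] = float(val)
        return ConnectivitySpec(p=p)


class WeightsBlock(_Block):
    """Overrides of single entries, e.g. ``w_AB: 2.0`` (onto A, from B)."""
    model_config = ConfigDict(extra="allow")
    tau_l: float = 1.0

    def to_spec(self) -> SynapseSpec:
        w = SynapseSpec().w.copy()
        for key, val in (self.model_extra or {}).items():
            if not (key.startswith("w_") and len(key) == 4
                    and key[2] in POP_ORDER and key[3] in POP_ORDER):
                raise ValueError(f"unknown weight key {key!r}")
            if not isinstance(val, (int, float)) or val < 0:
                raise ValueError(f"{key} must be a non-negative weight (nS)")
            w[POP_ORDER.index(key[2]), POP_ORDER.index(key[3])] = float(val)
        return SynapseSpec(w=w, tau_l=self.tau_l)


class DepressionBlock(_Block):
    enabled: bool = False
    tau_dep: float = 250.0
    eta_dep: float = 0.2


class HeterogeneityBlock(_Block):
    enabled: bool = False
    cv_weight: float = 0.25
    cv_latency: float = 0.25
    sd_EL_rel: float = 0.05
    cv_gL: float = 0.25


class SimulationBlock(_Block):
    dt: float = 0.05
    duration_s: float = 10.0
    warmup_ms: float = 500.0
    record_raster: bool = True
    record_lfp: bool = True
    record_adaptation: bool = True


class AnalysisBlock(_Block):
    threshold_pa: float = 50.0
    cutoff_hz: float = 5.0
    min_gap_ms: float = 50.0
    min_rate_hz: float = 2.0


class SweepBlock(_Block):
    mode: str = "ee"
    tol_pa: float = 10.0
    sim_s: float = 60.0
    calib_s: float = 30.0
    max_sim_s: float = 120.0
    min_events: int = 30
    target_lfp_pa: float | None = None


class ScreenBlock(_Block):
    n_cells: int = 64
    group_size: int = 8
    frac_athorny: float = 0.34
    amp_sigma: float = 0.4
    release_prob: float = 0.8
    noise_sd_mv: float = 0.2
    n_sweeps: int = 40
    frac_bad_cells: float = 0.05
    frac_bad_sweeps: float = 0.03

    def to_truth(self) -> ScreenGroundTruth:
        return ScreenGroundTruth(**self.model_dump())


class RunConfig(_Block):
    seed: int = 0
    outdir: str = "out"
    populations: PopulationsBlock = Field(default_factory=PopulationsBlock)
    connectivity: ConnectivityBlock = Field(default_factory=ConnectivityBlock)
    weights: WeightsBlock = Field(default_factory=WeightsBlock)
    depression: DepressionBlock = Field(default_factory=DepressionBlock)
    heterogeneity: HeterogeneityBlock = Field(default_factory=HeterogeneityBlock)
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)
    analysis: AnalysisBlock = Field(default_factory=AnalysisBlock)
    sweep: SweepBlock = Field(default_factory=SweepBlock)
    screen: ScreenBlock = Field(default_factory=ScreenBlock)

    def overrides(self) -> dict:
        """Non-default fields, for the run manifest."""
        default = RunConfig()
        mine, base = self.model_dump(), default.model_dump()
        return {k: v for k, v in mine.items() if v != base[k]}


def load_config(path=None) -> RunConfig:
    """Read a YAML config; an empty or missing body yields full defaults.

    Raises ``pydantic.ValidationError`` with field-level messages on schema
    violations and ``ValueError`` on malformed block entries.
    """
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text())
    return RunConfig(**(data or {}))


def network_from_config(cfg: RunConfig) -> Network:
    pops = tuple(
        PopulationSpec(name, cfg.populations.sizes[name],
                       getattr(cfg.populations, name).to_params())
        for name in POP_ORDER)
    dep = DepressionSpec(**cfg.depression.model_dump())
    het = HeterogeneitySpec(**cfg.heterogeneity.model_dump())
    return build_network(pops=pops, conn=cfg.connectivity.to_spec(),
                         syn=cfg.weights.to_spec(), dep=dep, het=het,
                         seed=stage_seed(cfg.seed, "network"))


def simconfig_from_config(cfg: RunConfig) -> SimConfig:
    s = cfg.simulation
    return SimConfig(duration=s.duration_s * 1000.0, dt=s.dt,
                     warmup=s.warmup_ms, seed=stage_seed(cfg.seed, "simulation"),
                     record_raster=s.record_raster, record_lfp=s.record_lfp,
                     record_adaptation=s.record_adaptation)
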