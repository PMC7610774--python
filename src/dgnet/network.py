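"""The GC-BC dentate gyrus network: synapses, heterogeneities, simulation.

The default microcircuit has 100 granule cells and 15 basket cells (a
large variant uses 500/75, preserving the ratio), with Bernoulli
connectivity: P(BC -> GC) = 0.1 (GABA_A), P(GC -> BC) = 0.05 (AMPA).
Receptor currents use the GHK equation -- AMPA as equal-permeability
Na + K components (reversal ~0 mV), GABA_A as a chloride current
(reversal ~ -79 mV) -- gated by a normalized double exponential

    s(t) = a (exp(-t/tau_d) - exp(-t/tau_r)),  tau_r = 2 ms, tau_d = 10 ms,

with linear superposition over presynaptic spikes, clipped at 1.
Synaptic permeabilities are densities over the postsynaptic membrane:
a synapse onto a structurally immature (small) granule cell delivers a
proportionally smaller absolute current, consistent with the low
synaptic connectivity of adult-born neurons.  The afferent drive is
scaled by the floor-clipped membrane-area ratio, so the smallest cells
are relatively over-driven -- the high excitability of immature neurons
survives the drive reduction.

Four heterogeneity axes (all independently switchable): intrinsic
(distinct valid models vs clones of one), synaptic (per-synapse
permeability factors U[0.5, 1.5] vs fixed), structural (GC diameters:
mature 63 um, fully immature U[2, 9] um, heterogeneous age U[2, 63] um;
BCs stay mature), and afferent (identical vs per-neuron entorhinal
inputs).
"""

from __future__ import annotations

import copy as _copy
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import integrator as _integ
from .afferents import (AfferentBank, Trajectory, afferent_current_matrix,
                        scale_drive_by_geometry)
from .constants import DEFAULT_CONSTANTS, DEFAULT_IONS
from .ghk import ghk_current
from .membrane import SPIKE_REFRACTORY_MS, SPIKE_THRESHOLD_MV
from .mpmoss import ValidPopulation
from .neuron import NeuronModel, pack_model, scale_geometry

__all__ = [
    "SynapseSpec", "NetworkConfig", "HeterogeneityConfig", "SpikeRaster",
    "Network", "build_network", "network_knockout", "simulate",
    "synapse_gate", "ampa_current", "gabaa_current",
    "GC_NETWORK_CHANNELS", "BC_NETWORK_CHANNELS",
]

# channels eligible for network knockouts (spike-generating NaF/KDR excluded)
GC_NETWORK_CHANNELS = ("KA", "HCN", "SK", "BK", "CaT", "CaN", "CaL")
BC_NETWORK_CHANNELS = ("KA", "HCN")

# calibrated defaults: receptor permeability densities (cm/s) and the
# afferent gain (pA at unit drive) that put baseline peak rates in the
# experimental bands (GC 4-10 Hz, BC 30-50 Hz)
DEFAULT_P_AMPA = 1.5e-8
DEFAULT_P_GABAA = 3.0e-8
DEFAULT_GAIN_PA = 210.0
DEFAULT_BC_GAIN_FACTOR = 1.2


@dataclass
class SynapseSpec:
    """Double-exponential GHK synapse parameters."""

    permeability: float          # cm/s, maximal (P_AMPA or P_GABAA)
    tau_rise_ms: float = 2.0
    tau_decay_ms: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise_ms < self.tau_decay_ms:
            raise ValueError("need tau_d > tau_r > 0")
        if self.permeability < 0:
            raise ValueError("permeability must be >= 0")

    @property
    def peak_time_ms(self) -> float:
        tr, td = self.tau_rise_ms, self.tau_decay_ms
        return tr * td / (td - tr) * math.log(td / tr)

    @property
    def norm(self) -> float:
        """a such that max_t s(t) = 1 for a single presynaptic spike."""
        tp = self.peak_time_ms
        return 1.0 / (math.exp(-tp / self.tau_decay_ms)
                      - math.exp(-tp / self.tau_rise_ms))


def synapse_gate(t_since_spike_ms, spec: SynapseSpec):
    """Normalized gate s(t) in [0, 1] for a single presynaptic spike."""
    t = np.asarray(t_since_spike_ms, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    s = spec.norm * (np.exp(-t / spec.tau_decay_ms)
                     - np.exp(-t / spec.tau_rise_ms))
    s = np.clip(s, 0.0, 1.0)
    return s if s.ndim else float(s)


def ampa_current(v_mV: float, s: float, spec: SynapseSpec,
                 area_cm2: float, ions=DEFAULT_IONS,
                 constants=DEFAULT_CONSTANTS) -> float:
    """AMPA receptor current (pA, outward positive) at gate value ``s``.

    Sum of GHK Na and K components with P_Na = P_K; depolarizing below
    the ~0 mV composite reversal.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("gate must be in [0, 1]")
    p = spec.permeability * s
    i = (ghk_current(v_mV, p, 1, ions.na_in, ions.na_out, constants)
         + ghk_current(v_mV, p, 1, ions.k_in, ions.k_out, constants))
    return i * area_cm2 * 1e9


def gabaa_current(v_mV: float, s: float, spec: SynapseSpec,
                  area_cm2: float, ions=DEFAULT_IONS,
                  constants=DEFAULT_CONSTANTS) -> float:
    """GABA_A chloride current (pA, outward positive) at gate ``s``."""
    if not 0.0 <= s <= 1.0:
        raise ValueError("gate must be in [0, 1]")
    p = spec.permeability * s
    i = ghk_current(v_mV, p, -1, ions.cl_in, ions.cl_out, constants)
    return i * area_cm2 * 1e9


@dataclass
class HeterogeneityConfig:
    """Which of the four heterogeneity axes are expressed."""

    intrinsic: bool = True
    synaptic: bool = True
    structural: str = "mature"      # mature | immature | heterogeneous
    afferent: str = "identical"     # identical | heterogeneous

    def __post_init__(self) -> None:
        if self.structural not in ("mature", "immature", "heterogeneous"):
            raise ValueError(f"unknown structural mode {self.structural!r}")
        if self.afferent not in ("identical", "heterogeneous"):
            raise ValueError(f"unknown afferent mode {self.afferent!r}")

    def gc_diameter(self, rng: np.random.Generator) -> float:
        if self.structural == "mature":
            return 63.0
        if self.structural == "immature":
            return float(rng.uniform(2.0, 9.0))
        return float(rng.uniform(2.0, 63.0))


@dataclass
class NetworkConfig:
    """Population sizes, connectivity, synapses and seeds."""

    n_gc: int = 100
    n_bc: int = 15
    p_bc_gc: float = 0.1
    p_gc_bc: float = 0.05
    p_ampa: float = DEFAULT_P_AMPA
    p_gabaa: float = DEFAULT_P_GABAA
    tau_rise_ms: float = 2.0
    tau_decay_ms: float = 10.0
    gain_pA: float = DEFAULT_GAIN_PA
    bc_gain_factor: float = DEFAULT_BC_GAIN_FACTOR
    heterogeneity: HeterogeneityConfig = field(default_factory=HeterogeneityConfig)
    seed_network: int = 0
    seed_synapse: int = 1
    seed_afferent: int = 2

    def __post_init__(self) -> None:
        for p in (self.p_bc_gc, self.p_gc_bc):
            if not 0.0 <= p <= 1.0:
                raise ValueError("connection probabilities must be in [0, 1]")

    @classmethod
    def large(cls, **kw) -> "NetworkConfig":
        """The 500 GC / 75 BC variant (GC:BC ratio preserved)."""
        kw.setdefault("n_gc", 500)
        kw.setdefault("n_bc", 75)
        return cls(**kw)


@dataclass
class SpikeRaster:
    """Per-neuron sorted spike times (ms) over the traversal."""

    n_neurons: int
    neuron_ids: np.ndarray
    times_ms: np.ndarray
    duration_ms: float

    def spikes_of(self, neuron: int) -> np.ndarray:
        return np.sort(self.times_ms[self.neuron_ids == neuron])

    def per_neuron(self) -> List[np.ndarray]:
        return [self.spikes_of(n) for n in range(self.n_neurons)]

    def counts(self) -> np.ndarray:
        return np.bincount(self.neuron_ids, minlength=self.n_neurons)


@dataclass
class Network:
    """An instantiated GC-BC network ready for simulation."""

    config: NetworkConfig
    gc_models: List[NeuronModel]
    bc_models: List[NeuronModel]
    syn_pre: np.ndarray       # presynaptic neuron index (global)
    syn_post: np.ndarray      # postsynaptic neuron index (global)
    syn_perm: np.ndarray      # per-synapse permeability (cm/s)
    syn_gaba: np.ndarray      # 1 for BC->GC GABA_A, 0 for GC->BC AMPA
    bank: AfferentBank

    @property
    def n_gc(self) -> int:
        return len(self.gc_models)

    @property
    def n_bc(self) -> int:
        return len(self.bc_models)

    @property
    def n_neurons(self) -> int:
        return self.n_gc + self.n_bc

    @property
    def models(self) -> List[NeuronModel]:
        return list(self.gc_models) + list(self.bc_models)

    def packed_params(self) -> np.ndarray:
        return np.stack([pack_model(m) for m in self.models])

    def copy(self) -> "Network":
        return _copy.deepcopy(self)


def _pick_models(pop: ValidPopulation, n: int, intrinsic: bool,
                 rng: np.random.Generator) -> List[NeuronModel]:
    if len(pop) == 0:
        raise ValueError("empty valid population")
    if not intrinsic:
        # intrinsic heterogeneity off: every neuron is a clone of one model
        idx = int(rng.integers(len(pop)))
        return [pop.models[idx].copy() for _ in range(n)]
    if n <= len(pop):
        chosen = rng.choice(len(pop), size=n, replace=False)
    else:
        chosen = rng.choice(len(pop), size=n, replace=True)
    return [pop.models[int(i)].copy() for i in chosen]


def build_network(config: NetworkConfig, gc_pop: ValidPopulation,
                  bc_pop: ValidPopulation) -> Network:
    """Instantiate a network from valid populations, per the config seeds.

    Models are drawn without replacement when the pool allows (with
    replacement otherwise); Bernoulli connectivity with the configured
    probabilities; synaptic heterogeneity multiplies each synapse's
    permeability by U[0.5, 1.5]; structural heterogeneity rescales GC
    geometry and the per-neuron afferent drive by the area ratio.
    """
    het = config.heterogeneity
    rng = np.random.default_rng(config.seed_network)
    gcs = _pick_models(gc_pop, config.n_gc, het.intrinsic, rng)
    bcs = _pick_models(bc_pop, config.n_bc, het.intrinsic, rng)

    diameters = np.array([het.gc_diameter(rng) for _ in gcs])
    gcs = [scale_geometry(m, d) if d != m.geometry.diameter_um else m
           for m, d in zip(gcs, diameters)]

    # Bernoulli connectivity
    pre, post, gaba = [], [], []
    n_gc, n_bc = config.n_gc, config.n_bc
    bc_gc = rng.random((n_bc, n_gc)) < config.p_bc_gc
    gc_bc = rng.random((n_gc, n_bc)) < config.p_gc_bc
    for b, g in zip(*np.nonzero(bc_gc)):
        pre.append(n_gc + int(b)); post.append(int(g)); gaba.append(1)
    for g, b in zip(*np.nonzero(gc_bc)):
        pre.append(int(g)); post.append(n_gc + int(b)); gaba.append(0)

    syn_rng = np.random.default_rng(config.seed_synapse)
    base = np.where(np.array(gaba) == 1, config.p_gabaa, config.p_ampa)
    if het.synaptic:
        factors = syn_rng.uniform(0.5, 1.5, size=len(pre))
    else:
        factors = np.ones(len(pre))
    perm = base * factors

    # afferent bank: GC drives scaled by area ratio; BC gain factor
    # compensates the basket cells' much lower input resistance
    scale = np.concatenate([
        np.array([scale_drive_by_geometry(d) for d in diameters]),
        np.full(n_bc, config.bc_gain_factor),
    ])
    bank = AfferentBank.build(
        n_neurons=n_gc + n_bc, gain_pA=config.gain_pA,
        identical=(het.afferent == "identical"), seed=config.seed_afferent,
        scale=scale)

    return Network(config, gcs, bcs, np.array(pre, dtype=np.int64),
                   np.array(post, dtype=np.int64), perm,
                   np.array(gaba, dtype=np.int64), bank)


def network_knockout(network: Network, channel: str,
                     population: str) -> Network:
    """Zero ``channel`` across the stated population ('GC' or 'BC').

    Connectivity, synapses, seeds and the afferent bank are untouched.
    The spike-generating conductances NaF and KDR are refused: without
    spiking (or repolarization), firing-rate and response-correlation
    measures cannot be computed.
    """
    if channel in ("NaF", "KDR"):
        raise ValueError(
            f"{channel} knockout is not assessed at network scale: "
            "eliminating a spike-generating conductance abolishes the "
            "spiking response that rate and correlation measures require")
    if population not in ("GC", "BC"):
        raise ValueError("population must be 'GC' or 'BC'")
    allowed = (GC_NETWORK_CHANNELS if population == "GC"
               else BC_NETWORK_CHANNELS)
    if channel not in allowed:
        raise ValueError(f"unknown {population} channel {channel!r}")
    out = network.copy()
    targets = out.gc_models if population == "GC" else out.bc_models
    for m in targets:
        m.conductances[channel] = 0.0
    return out


def simulate(network: Network, trajectory: Trajectory,
             bank: Optional[AfferentBank] = None, dt: float = 0.025,
             settle_ms: float = 200.0) -> SpikeRaster:
    """Co-integrate the network during the traversal; return the raster.

    All neurons, synapse gates and afferent currents advance together at
    ``dt`` (ms); afferent currents are piecewise constant per 1 ms
    trajectory sample.  Spike detection: upward 0 mV crossing with a
    2 ms refractory hold.  Deterministic for fixed network and inputs.
    """
    bank = bank if bank is not None else network.bank
    params = network.packed_params()
    n = network.n_neurons
    states = np.stack([
        _integ._init_state(params[i], network.models[i].passive.v_rest_mV)
        for i in range(n)])
    # settle at rest without afferents
    for i in range(n):
        _integ._settle(params[i], states[i], int(round(settle_ms / dt)), dt)

    aff = afferent_current_matrix(bank, trajectory)
    steps_per_ms = int(round(1.0 / dt))
    if abs(steps_per_ms * dt - 1.0) > 1e-9:
        raise ValueError("dt must divide the 1 ms afferent update interval")
    n_steps = aff.shape[1] * steps_per_ms

    spec = SynapseSpec(1.0, network.config.tau_rise_ms,
                       network.config.tau_decay_ms)
    order = np.argsort(network.syn_pre, kind="stable")
    synidx = np.ascontiguousarray(order.astype(np.int64))
    indptr = np.searchsorted(network.syn_pre[order], np.arange(n + 1)).astype(np.int64)

    max_spikes = int(n * (n_steps * dt / 1e3) * 200 + 10000)
    spike_n = np.empty(max_spikes, dtype=np.int64)
    spike_t = np.empty(max_spikes, dtype=np.float64)
    ions = DEFAULT_IONS
    ret = _integ._run_network(
        params, states, dt, n_steps, steps_per_ms, aff,
        network.syn_post, network.syn_perm,
        network.syn_gaba, indptr, synidx,
        spec.tau_rise_ms, spec.tau_decay_ms, spec.norm,
        ions.na_in, ions.na_out, ions.k_in, ions.k_out,
        ions.cl_in, ions.cl_out,
        spike_n, spike_t, SPIKE_THRESHOLD_MV, SPIKE_REFRACTORY_MS)
    if ret < 0:
        bad = -(ret + 1)
        raise FloatingPointError(
            f"network integration lost finiteness (neuron {bad})")
    return SpikeRaster(n, spike_n[:ret].copy(), spike_t[:ret].copy(),
                       n_steps * dt)


def calibrate_gain(config: NetworkConfig, gc_pop: ValidPopulation,
                   bc_pop: ValidPopulation, trajectory: Trajectory,
                   target_gc_hz: float = 7.0, iters: int = 4,
                   dt: float = 0.05) -> float:
    """Adjust the global afferent gain so the median GC peak rate hits
    the centre of the 4-10 Hz experimental band on a short traversal."""
    from .analysis import peak_rate
    gain = config.gain_pA
    for _ in range(iters):
        cfg = replace(config, gain_pA=gain)
        net = build_network(cfg, gc_pop, bc_pop)
        raster = simulate(net, trajectory, dt=dt)
        spikes = raster.per_neuron()[:net.n_gc]
        peaks = [peak_rate(s, trajectory.duration_s) for s in spikes]
        med = float(np.median(peaks))
        if med <= 0:
            gain *= 2.0
            continue
        gain *= (target_gc_hz / med) ** 0.7
    return gain
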