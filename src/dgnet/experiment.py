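"""The knockout x heterogeneity experiment grid.

The full design crosses the knockout factor (base network + 7 GC-channel
knockouts + 2 BC-channel knockouts) with four named heterogeneity
presets -- 40 network configurations in total, every one driven by the
same frozen trajectory so that base and knockout runs consume
bit-identical afferent current streams.

Presets (intrinsic + synaptic heterogeneity always on):

* ``mature-identical``      -- mature GCs, identical afferents
* ``mature-heterogeneous``  -- mature GCs, per-neuron afferents
* ``heterogeneous-age``     -- GC diameters U[2, 63] um, identical afferents
* ``fully-immature``        -- GC diameters U[2, 9] um, identical afferents
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .afferents import Trajectory, afferent_current_matrix, generate_trajectory
from .analysis import (CorrelationBundle, input_correlation_matrix,
                       instantaneous_rate, output_correlation_matrix,
                       overall_rate)
from .mpmoss import ValidPopulation
from .network import (BC_NETWORK_CHANNELS, GC_NETWORK_CHANNELS, Network,
                      NetworkConfig, SpikeRaster, build_network,
                      network_knockout, simulate)

__all__ = [
    "HETEROGENEITY_PRESETS", "KNOCKOUT_FACTORS", "ExperimentConfig",
    "ExperimentResult", "enumerate_configurations", "run_experiment",
]

HETEROGENEITY_PRESETS: Dict[str, Dict[str, object]] = {
    "mature-identical": dict(intrinsic=True, synaptic=True,
                             structural="mature", afferent="identical"),
    "mature-heterogeneous": dict(intrinsic=True, synaptic=True,
                                 structural="mature",
                                 afferent="heterogeneous"),
    "heterogeneous-age": dict(intrinsic=True, synaptic=True,
                              structural="heterogeneous",
                              afferent="identical"),
    "fully-immature": dict(intrinsic=True, synaptic=True,
                           structural="immature", afferent="identical"),
}

# (channel, population); None = base network with all channels intact
KNOCKOUT_FACTORS: List[Optional[Tuple[str, str]]] = (
    [None]
    + [(ch, "GC") for ch in GC_NETWORK_CHANNELS]
    + [(ch, "BC") for ch in BC_NETWORK_CHANNELS]
)


@dataclass(frozen=True)
class ExperimentConfig:
    """One fully reproducible cell of the experiment grid."""

    preset: str
    knockout: Optional[Tuple[str, str]]  # (channel, population) or None
    n_gc: int = 100
    n_bc: int = 15
    duration_s: float = 1000.0
    dt_ms: float = 0.025
    seed_network: int = 0
    seed_synapse: int = 1
    seed_afferent: int = 2
    seed_trajectory: int = 3

    @property
    def config_id(self) -> str:
        ko = "base" if self.knockout is None else "-".join(self.knockout[::-1])
        return f"{self.preset}_{ko}"


def enumerate_configurations(
        presets: Sequence[str] = tuple(HETEROGENEITY_PRESETS),
        knockouts: Sequence[Optional[Tuple[str, str]]] = tuple(KNOCKOUT_FACTORS),
        **overrides) -> List[ExperimentConfig]:
    """Cartesian product of heterogeneity presets and knockout factors.

    Stable ordering (knockouts vary fastest), unique ids; with the
    default factor sets this enumerates 40 configurations.
    """
    if not presets or not knockouts:
        raise ValueError("factor sets must be non-empty")
    out = []
    for preset in presets:
        if preset not in HETEROGENEITY_PRESETS:
            raise ValueError(f"unknown preset {preset!r}")
        for ko in knockouts:
            out.append(ExperimentConfig(preset=preset, knockout=ko,
                                        **overrides))
    return out


@dataclass
class ExperimentResult:
    """Outputs of one grid cell, with provenance."""

    config: ExperimentConfig
    raster: SpikeRaster
    gc_rates_hz: np.ndarray
    bundle: CorrelationBundle

    @property
    def config_id(self) -> str:
        return self.config.config_id


def _network_for(config: ExperimentConfig, gc_pop: ValidPopulation,
                 bc_pop: ValidPopulation) -> Network:
    from .network import HeterogeneityConfig
    het = HeterogeneityConfig(**HETEROGENEITY_PRESETS[config.preset])
    net_cfg = NetworkConfig(
        n_gc=config.n_gc, n_bc=config.n_bc, heterogeneity=het,
        seed_network=config.seed_network, seed_synapse=config.seed_synapse,
        seed_afferent=config.seed_afferent)
    net = build_network(net_cfg, gc_pop, bc_pop)
    if config.knockout is not None:
        channel, population = config.knockout
        net = network_knockout(net, channel, population)
    return net


def run_experiment(config: ExperimentConfig, gc_pop: ValidPopulation,
                   bc_pop: ValidPopulation,
                   trajectory: Optional[Trajectory] = None,
                   sigma_ms: float = 50.0) -> ExperimentResult:
    """Run one grid cell end to end.

    Builds the network (applying the knockout if any), simulates the
    traversal, and computes per-GC overall rates plus the input/output
    correlation bundle.  Configurations differing only in knockout share
    the trajectory, connectivity, synapse and afferent seeds, so their
    input streams are bit-identical.
    """
    if trajectory is None:
        trajectory = generate_trajectory(config.duration_s,
                                         seed=config.seed_trajectory)
    net = _network_for(config, gc_pop, bc_pop)
    raster = simulate(net, trajectory, dt=config.dt_ms)
    gc_spikes = raster.per_neuron()[:net.n_gc]
    rates = np.array([overall_rate(s, trajectory.duration_s)
                      for s in gc_spikes])
    series = [instantaneous_rate(s, trajectory.duration_s, sigma_ms=sigma_ms)
              for s in gc_spikes]
    out_corr = output_correlation_matrix(series)
    aff = afferent_current_matrix(net.bank, trajectory)[:net.n_gc]
    in_corr = input_correlation_matrix(aff)
    return ExperimentResult(config, raster, rates,
                            CorrelationBundle(out_corr, in_corr))
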