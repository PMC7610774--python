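"""Network assembly, GHK synapses and co-integration."""

import math

import numpy as np
import pytest

from dgnet.ephys import measure_all
from dgnet.network import (BC_NETWORK_CHANNELS, GC_NETWORK_CHANNELS,
                           HeterogeneityConfig, NetworkConfig, SynapseSpec,
                           ampa_current, build_network, gabaa_current,
                           network_knockout, simulate, synapse_gate)
from dgnet.neuron import gc_base_model
from dgnet.vkm import knockout

AREA = gc_base_model().geometry.area_cm2


def test_synapse_gate_rise_peak_and_decay():
    spec = SynapseSpec(1e-9)
    assert synapse_gate(0.0, spec) == 0.0
    t_peak = 2.0 * 10.0 / 8.0 * math.log(5.0)  # 2.5 ln 5 ~ 4.02 ms
    assert spec.peak_time_ms == pytest.approx(t_peak, rel=1e-12)
    assert synapse_gate(t_peak, spec) == pytest.approx(1.0, abs=1e-12)
    t = np.linspace(0.0, 200.0, 2001)
    s = synapse_gate(t, spec)
    assert np.all((0.0 <= s) & (s <= 1.0))
    assert s[-1] < 1e-8


def test_synapse_spec_requires_ordered_time_constants():
    with pytest.raises(ValueError):
        SynapseSpec(1e-9, tau_rise_ms=10.0, tau_decay_ms=2.0)


def test_ampa_reversal_and_sign():
    spec = SynapseSpec(1e-8)
    assert ampa_current(-70.0, 0.0, spec, AREA) == 0.0
    assert ampa_current(-70.0, 1.0, spec, AREA) < 0.0   # depolarizing
    assert ampa_current(20.0, 1.0, spec, AREA) > 0.0
    # zero crossing sits at the composite Na/K reversal (~ -2.3 mV)
    lo, hi = -5.0, 0.0
    assert ampa_current(lo, 1.0, spec, AREA) < 0 < ampa_current(hi, 1.0, spec, AREA)
    with pytest.raises(ValueError):
        ampa_current(0.0, 1.5, spec, AREA)


def test_gabaa_reversal_and_sign():
    spec = SynapseSpec(1e-8)
    assert gabaa_current(-60.0, 0.0, spec, AREA) == 0.0
    assert gabaa_current(-60.0, 1.0, spec, AREA) > 0.0  # opposes depolarization
    assert gabaa_current(-90.0, 1.0, spec, AREA) < 0.0  # below E_Cl ~ -79


def test_default_network_composition_and_edge_statistics(gc_pop, bc_pop):
    cfg = NetworkConfig(seed_network=8)
    net = build_network(cfg, gc_pop, bc_pop)
    assert net.n_gc == 100 and net.n_bc == 15
    n_inh = int(np.sum(net.syn_gaba == 1))
    n_exc = int(np.sum(net.syn_gaba == 0))
    # Binomial(1500, 0.1) and Binomial(1500, 0.05), three-sigma bands
    assert abs(n_inh - 150) <= 3 * math.sqrt(1500 * 0.1 * 0.9)
    assert abs(n_exc - 75) <= 3 * math.sqrt(1500 * 0.05 * 0.95)
    # reproducible for fixed seeds
    again = build_network(cfg, gc_pop, bc_pop)
    np.testing.assert_array_equal(net.syn_pre, again.syn_pre)
    np.testing.assert_array_equal(net.syn_perm, again.syn_perm)


def test_zero_probability_network_is_decoupled(gc_pop, bc_pop):
    cfg = NetworkConfig(n_gc=10, n_bc=2, p_bc_gc=0.0, p_gc_bc=0.0)
    net = build_network(cfg, gc_pop, bc_pop)
    assert net.syn_pre.size == 0


def test_network_knockout_scope_and_exclusions(gc_pop, bc_pop):
    cfg = NetworkConfig(n_gc=5, n_bc=2)
    net = build_network(cfg, gc_pop, bc_pop)
    ko = network_knockout(net, "BK", "GC")
    assert all(m.conductances["BK"] == 0.0 for m in ko.gc_models)
    assert all(m.conductances["BK"] > 0.0 for m in net.gc_models)  # untouched
    assert all(b.conductances == nb.conductances
               for b, nb in zip(net.bc_models, ko.bc_models))
    assert len(GC_NETWORK_CHANNELS) == 7
    assert len(BC_NETWORK_CHANNELS) == 2
    for ch in ("NaF", "KDR"):
        with pytest.raises(ValueError, match="spike-generating"):
            network_knockout(net, ch, "GC")


def test_network_knockout_matches_single_cell_knockout(gc_pop, bc_pop):
    cfg = NetworkConfig(n_gc=3, n_bc=1, seed_network=2)
    net = build_network(cfg, gc_pop, bc_pop)
    ko_net = network_knockout(net, "HCN", "GC")
    isolated = measure_all(ko_net.gc_models[0]).as_dict()
    direct = measure_all(knockout(net.gc_models[0], "HCN")).as_dict()
    for k, v in direct.items():
        assert (np.isnan(v) and np.isnan(isolated[k])) \
            or isolated[k] == pytest.approx(v)


@pytest.fixture(scope="module")
def short_trajectory():
    from dgnet.afferents import generate_trajectory
    return generate_trajectory(10.0, seed=21)


def test_symmetric_network_produces_identical_rasters(gc_pop, bc_pop,
                                                      short_trajectory):
    """With intrinsic heterogeneity off, no local synapses and identical
    afferents, every granule cell is the same dynamical system driven by
    the same input."""
    het = HeterogeneityConfig(intrinsic=False, synaptic=False,
                              structural="mature", afferent="identical")
    cfg = NetworkConfig(n_gc=5, n_bc=1, p_bc_gc=0.0, p_gc_bc=0.0,
                        heterogeneity=het)
    raster = simulate(build_network(cfg, gc_pop, bc_pop), short_trajectory)
    trains = raster.per_neuron()[:5]
    assert trains[0].size > 0
    for t in trains[1:]:
        np.testing.assert_array_equal(t, trains[0])


def test_inhibition_does_not_raise_population_rate(gc_pop, bc_pop,
                                                   short_trajectory):
    base = NetworkConfig(n_gc=15, n_bc=3, p_bc_gc=0.0, seed_network=5)
    inh = NetworkConfig(n_gc=15, n_bc=3, p_bc_gc=0.5, seed_network=5)
    r0 = simulate(build_network(base, gc_pop, bc_pop), short_trajectory)
    r1 = simulate(build_network(inh, gc_pop, bc_pop), short_trajectory)
    m0 = np.median(r0.counts()[:15])
    m1 = np.median(r1.counts()[:15])
    assert m1 <= m0


def test_zero_afferent_gain_gives_empty_raster(gc_pop, bc_pop,
                                               short_trajectory):
    cfg = NetworkConfig(n_gc=4, n_bc=1, gain_pA=0.0)
    raster = simulate(build_network(cfg, gc_pop, bc_pop), short_trajectory)
    assert raster.times_ms.size == 0


def test_large_variant_runs_through_the_same_code_path(gc_pop, bc_pop):
    from dgnet.afferents import generate_trajectory
    cfg = NetworkConfig.large()
    assert cfg.n_gc == 500 and cfg.n_bc == 75
    net = build_network(cfg, gc_pop, bc_pop)
    raster = simulate(net, generate_trajectory(2.0, seed=13))
    assert raster.n_neurons == 575
    assert raster.times_ms.size > 0
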