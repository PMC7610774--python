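"""Membrane integration: passive analytics, calcium ODE, stability."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from dgnet.membrane import (calcium_step, init_state, membrane_step,
                            run_current_clamp, settled_state)
from dgnet.neuron import (CalciumHandling, NeuronGeometry, gc_base_model,
                          pack_model)


@pytest.fixture(scope="module")
def passive_gc():
    m = gc_base_model()
    for ch in m.conductances:
        m.conductances[ch] = 0.0
    m.e_leak_mV = None
    m.__post_init__()
    return m


def _exp_fit(t, y):
    """(tau, asymptote) of a mono-exponential fit y = a exp(-t/tau) + c."""
    def f(t, a, tau, c):
        return a * np.exp(-t / tau) + c
    p, _ = curve_fit(f, t, y, p0=(y[0] - y[-1], 30.0, y[-1]))
    return p[1], p[2]


def _exp_fit_tau(t, y):
    return _exp_fit(t, y)[0]


def test_passive_input_resistance_matches_rm_over_area(passive_gc):
    r_analytic = passive_gc.passive.r_m_kohm_cm2 * 1e3 \
        / passive_gc.geometry.area_cm2 / 1e6  # MOhm
    tr = run_current_clamp(passive_gc, [(-50.0, 1000.0)])
    w = slice(int(1000 / tr.dt_ms), int(1100 / tr.dt_ms))
    deflection = np.mean(tr.v_mV[w]) - tr.baseline_mV
    r_sim = deflection / -50.0 * 1e3  # MOhm
    assert r_sim == pytest.approx(r_analytic, rel=0.01)
    assert r_sim == pytest.approx(304.7, rel=0.01)
    # steady deflection for -50 pA is about -15.2 mV
    assert deflection == pytest.approx(-50e-12 * r_analytic * 1e6 * 1e3,
                                       rel=0.01)


def test_passive_membrane_time_constant_is_rm_cm(passive_gc):
    tr = run_current_clamp(passive_gc, [(-50.0, 1000.0)])
    i0 = int(tr.stim_start_ms / tr.dt_ms)
    seg = tr.v_mV[i0:i0 + int(300 / tr.dt_ms)]
    t = np.arange(seg.size) * tr.dt_ms
    tau = _exp_fit_tau(t, seg)
    assert tau == pytest.approx(38.0, rel=0.01)


def test_calcium_fixed_point_and_relaxation():
    ca = CalciumHandling()
    stepped = calcium_step(ca, 0.0, 0.025)
    assert stepped.ca_mM == pytest.approx(ca.ca_inf_mM, rel=1e-12)

    # relaxation from 1 uM recovers tau_Ca = 160 ms
    state = CalciumHandling(ca_mM=1e-3)
    dt = 0.025
    n = int(1000 / dt)
    trace = np.empty(n)
    for i in range(n):
        state = calcium_step(state, 0.0, dt)
        trace[i] = state.ca_mM
    t = np.arange(1, n + 1) * dt
    tau, asymptote = _exp_fit(t, trace)
    assert tau == pytest.approx(160.0, rel=0.01)
    assert asymptote == pytest.approx(50e-6, rel=1e-3)


def test_calcium_constant_influx_steady_state_matches_closed_form():
    ca = CalciumHandling()
    i_ca = -2e-3  # inward calcium current density, mA/cm^2
    influx = -10000.0 * i_ca / (ca.influx_denominator * ca.depth_um * 96485.332)
    expected = ca.ca_inf_mM + ca.tau_ms * influx
    state = ca
    for _ in range(int(2000 / 0.05)):  # ~12 time constants
        state = calcium_step(state, i_ca, 0.05)
    assert state.ca_mM == pytest.approx(expected, rel=1e-3)


def test_calcium_step_rejects_nonpositive_dt():
    with pytest.raises(ValueError):
        calcium_step(CalciumHandling(), 0.0, 0.0)


def test_membrane_step_flags_offending_state():
    m = gc_base_model()
    s = init_state(m)
    s[0] = float("nan")
    with pytest.raises(FloatingPointError, match="v"):
        membrane_step(m, s, 0.0)


def test_resting_stability_drift_below_half_millivolt():
    m = gc_base_model()
    s0 = settled_state(m, settle_ms=500.0)
    s1 = settled_state(m, settle_ms=1500.0)  # one extra second at rest
    assert abs(s1[0] - s0[0]) < 0.5


def test_hcn_sag_peak_exceeds_steady_state(gc_base):
    tr = run_current_clamp(gc_base, [(-50.0, 1000.0)])
    w = slice(int(tr.stim_start_ms / tr.dt_ms), int(tr.stim_end_ms / tr.dt_ms))
    deflection = tr.v_mV[w] - tr.baseline_mV
    steady = np.mean(deflection[-int(100 / tr.dt_ms):])
    assert np.min(deflection) < steady < 0


def test_base_gc_spikes_in_table_band(gc_base_measurements):
    assert 10.0 <= gc_base_measurements.f150 <= 15.0


def test_measurements_converge_when_dt_halved(gc_base):
    from dgnet.ephys import measure_all
    a = measure_all(gc_base, dt=0.025).as_dict()
    b = measure_all(gc_base, dt=0.0125).as_dict()
    # spike counts are integers: allow one spike; continuous measures 2%
    assert abs(a["f150"] - b["f150"]) <= 1.0
    for key in ("R_in", "sag", "V_AP", "V_th", "T_APHW"):
        assert b[key] == pytest.approx(a[key], rel=0.02)


def test_run_current_clamp_requires_protocol(gc_base):
    with pytest.raises(ValueError):
        run_current_clamp(gc_base, [])


def test_geometry_area_formula():
    g = NeuronGeometry(63.0, 63.0)
    assert g.area_cm2 == pytest.approx(np.pi * 63e-4 * 63e-4, rel=1e-12)
    with pytest.raises(ValueError):
        NeuronGeometry(0.0, 63.0)
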