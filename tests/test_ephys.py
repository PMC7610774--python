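"""Measurement operations on constructed and simulated traces."""

import numpy as np
import pytest

from dgnet.ephys import (RIN_AMPLITUDES_PA, MeasurementVector, NoSpikeError,
                         measure_all, measure_ap_features,
                         measure_input_resistance, measure_rate_and_sfa,
                         measure_sag_ratio)
from dgnet.neuron import VoltageTrace, gc_base_model

DT = 0.1
PRE, PULSE, POST = 100.0, 1000.0, 100.0


def _trace(v, baseline=-75.0, stim_amp=0.0):
    n = v.size
    i = np.zeros(n)
    i[int(PRE / DT):int((PRE + PULSE) / DT)] = stim_amp
    return VoltageTrace(dt_ms=DT, v_mV=v, i_pA=i, baseline_mV=baseline,
                        stim_start_ms=PRE, stim_end_ms=PRE + PULSE)


def _ohmic_traces(r_mohm):
    traces = []
    for amp in RIN_AMPLITUDES_PA:
        v = np.full(int((PRE + PULSE + POST) / DT), -75.0)
        v[int(PRE / DT):int((PRE + PULSE) / DT)] += amp * r_mohm * 1e-3
        traces.append(_trace(v, stim_amp=float(amp)))
    return traces


def test_input_resistance_exact_on_constructed_ohmic_traces():
    assert measure_input_resistance(_ohmic_traces(200.0)) == pytest.approx(
        200.0, abs=1e-9)


def test_input_resistance_requires_full_protocol():
    with pytest.raises(ValueError):
        measure_input_resistance(_ohmic_traces(200.0)[:10])
    bad = _ohmic_traces(200.0)
    bad[0], bad[1] = bad[1], bad[0]  # out of order
    with pytest.raises(ValueError):
        measure_input_resistance(bad)


def test_sag_ratio_on_constructed_trace():
    n = int((PRE + PULSE + POST) / DT)
    v = np.full(n, -75.0)
    stim = slice(int(PRE / DT), int((PRE + PULSE) / DT))
    v[stim] = -75.0 - 10.8           # steady deflection -10.8 mV
    v[stim.start:stim.start + 100] = -75.0 - 12.0  # early peak -12 mV
    assert measure_sag_ratio(_trace(v, stim_amp=-50.0)) == pytest.approx(
        0.90, abs=1e-9)


def test_sag_requires_hyperpolarization():
    v = np.full(int((PRE + PULSE + POST) / DT), -75.0)
    with pytest.raises(ValueError):
        measure_sag_ratio(_trace(v, stim_amp=-50.0))


def _triangular_spike_trace():
    """One AP with hand-computable geometry.

    Pre-threshold plateau at -60 mV, rise at 100 mV/ms to +40 mV, fall at
    -100 mV/ms to -70 mV (the fast AHP), then return to baseline.
    """
    n = int((PRE + PULSE + POST) / DT)
    v = np.full(n, -75.0)
    i0 = int((PRE + 50) / DT)
    v[int(PRE / DT):i0] = -60.0
    rise = np.arange(0.0, 100.0, 100.0 * DT)         # -60 -> +40 in 1 ms
    fall = np.arange(0.0, 110.0, 100.0 * DT)         # +40 -> -70 in 1.1 ms
    seg = np.concatenate([-60.0 + rise, 40.0 - fall])
    v[i0:i0 + seg.size] = seg
    v[i0 + seg.size:int((PRE + PULSE) / DT)] = -70.0
    return _trace(v, stim_amp=150.0)


def test_ap_features_on_triangular_spike():
    v_ap, v_th, t_aphw, v_fahp = measure_ap_features(_triangular_spike_trace())
    assert v_th == pytest.approx(-60.0, abs=0.5)
    assert v_ap == pytest.approx(115.0, abs=0.5)      # +40 peak vs -75 rest
    assert t_aphw == pytest.approx(1.0, abs=0.05)     # 100 mV/ms symmetric
    assert v_fahp == pytest.approx(-10.0, abs=0.5)    # -70 trough vs -60


def test_no_spike_raises():
    v = np.full(int((PRE + PULSE + POST) / DT), -75.0)
    with pytest.raises(NoSpikeError):
        measure_ap_features(_trace(v, stim_amp=150.0))


def _raster_trace(spike_times_ms):
    n = int((PRE + PULSE + POST) / DT)
    v = np.full(n, -75.0)
    for t in spike_times_ms:
        i = int(t / DT)
        v[i:i + 5] = 30.0  # brief suprathreshold pulse
    return _trace(v, stim_amp=150.0)


def test_rate_and_adaptation_on_constructed_raster():
    # ISIs 50, 60, ..., 100 ms -> SFA = 50/100 = 0.5
    times = PRE + np.concatenate([[10.0], 10.0 + np.cumsum(np.arange(50.0, 101.0, 10.0))])
    f, sfa = measure_rate_and_sfa(_raster_trace(times), 150.0)
    assert f == pytest.approx(len(times), abs=1e-9)
    assert sfa == pytest.approx(0.5, abs=1e-6)


def test_adaptation_undefined_below_three_spikes():
    f, sfa = measure_rate_and_sfa(_raster_trace([PRE + 100.0, PRE + 300.0]),
                                  150.0)
    assert f == 2.0
    assert np.isnan(sfa)


def test_passive_base_measurement_vector():
    m = gc_base_model()
    for ch in m.conductances:
        m.conductances[ch] = 0.0
    m.e_leak_mV = None
    m.__post_init__()
    mv = measure_all(m)
    assert mv.R_in == pytest.approx(304.7, rel=0.01)
    assert mv.sag == pytest.approx(1.0, abs=1e-3)
    assert mv.f150 == 0.0 and mv.f50 == 0.0
    assert not mv.spiking and np.isnan(mv.V_AP)


def test_measure_all_deterministic(gc_base, gc_base_measurements):
    again = measure_all(gc_base)
    assert again.as_dict() == gc_base_measurements.as_dict()
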