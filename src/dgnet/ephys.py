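"""The nine electrophysiological measurements used to validate models.

All measurements are computed from current-clamp voltage traces:

* R_in -- slope of the V-I fit over steady-state responses to eleven
  1000 ms pulses from -50 to +50 pA in 10 pA steps;
* sag ratio -- steady-state over peak deflection at -50 pA;
* V_AP, V_th, T_APHW, V_fAHP -- first action potential of the +150 pA
  trace: amplitude relative to resting potential, the voltage where
  dV/dt crosses 20 V/s, width at half-maximum relative to threshold,
  and maximal repolarizing deflection from threshold;
* f50 / f150 -- spike counts during a 1 s pulse of 50 / 150 pA;
* SFA -- first over last interspike interval (needs >= 3 spikes, else
  flagged undefined as NaN).

Steady-state deflections are averaged over the final 100 ms of a pulse;
half-width crossings are linearly interpolated between samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Dict, Sequence, Tuple

import numpy as np

from .membrane import (DEFAULT_DT_MS, SPIKE_REFRACTORY_MS,
                       SPIKE_THRESHOLD_MV, run_current_clamp)
from .neuron import NeuronModel, VoltageTrace

__all__ = [
    "MeasurementVector", "NoSpikeError", "detect_spikes",
    "measure_input_resistance", "measure_sag_ratio", "measure_ap_features",
    "measure_rate_and_sfa", "measure_all",
    "RIN_AMPLITUDES_PA", "DVDT_THRESHOLD_MV_MS",
]

RIN_AMPLITUDES_PA = tuple(range(-50, 51, 10))
DVDT_THRESHOLD_MV_MS = 20.0  # 20 V/s
STEADY_WINDOW_MS = 100.0
PULSE_MS = 1000.0


class NoSpikeError(ValueError):
    """Raised when an AP measurement is requested on a spikeless trace."""


@dataclass
class MeasurementVector:
    """The nine measurements, named by their conventional symbols."""

    V_AP: float      # AP amplitude relative to V_RMP (mV)
    V_th: float      # AP threshold (mV)
    T_APHW: float    # AP half-width (ms)
    V_fAHP: float    # fast AHP relative to threshold (mV, negative)
    SFA: float       # first ISI / last ISI (NaN when < 3 spikes)
    sag: float       # steady-state / peak deflection at -50 pA
    R_in: float      # input resistance (MOhm)
    f50: float       # firing rate at 50 pA (Hz)
    f150: float      # firing rate at 150 pA (Hz)

    def as_dict(self) -> Dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def spiking(self) -> bool:
        return np.isfinite(self.V_AP)


def detect_spikes(trace: VoltageTrace,
                  threshold: float = SPIKE_THRESHOLD_MV,
                  refractory_ms: float = SPIKE_REFRACTORY_MS) -> np.ndarray:
    """Spike times (ms) as upward threshold crossings with refractory hold."""
    from .integrator import _count_spikes
    return _count_spikes(trace.v_mV, trace.dt_ms, threshold, refractory_ms)


def _window(trace: VoltageTrace, t0: float, t1: float) -> slice:
    return slice(int(round(t0 / trace.dt_ms)), int(round(t1 / trace.dt_ms)))


def _steady_deflection(trace: VoltageTrace) -> float:
    w = _window(trace, trace.stim_end_ms - STEADY_WINDOW_MS, trace.stim_end_ms)
    return float(np.mean(trace.v_mV[w]) - trace.baseline_mV)


def measure_input_resistance(traces: Sequence[VoltageTrace]) -> float:
    """R_in (MOhm) as the slope of the V-I fit over the 11-pulse protocol."""
    if len(traces) != len(RIN_AMPLITUDES_PA):
        raise ValueError(
            f"expected {len(RIN_AMPLITUDES_PA)} traces, got {len(traces)}")
    amps = []
    defl = []
    for trace, expected in zip(traces, RIN_AMPLITUDES_PA):
        stim = trace.i_pA[_window(trace, trace.stim_start_ms,
                                  trace.stim_end_ms)]
        amp = float(stim[0]) if stim.size else 0.0
        if abs(amp - expected) > 1e-9:
            raise ValueError(f"missing or out-of-order pulse: {expected} pA")
        amps.append(amp)
        defl.append(_steady_deflection(trace))
    slope_mV_per_pA = float(np.polyfit(amps, defl, 1)[0])
    return slope_mV_per_pA * 1e3  # mV/pA = GOhm -> MOhm


def measure_sag_ratio(trace: VoltageTrace) -> float:
    """Steady-state over peak deflection for a hyperpolarizing pulse."""
    w = _window(trace, trace.stim_start_ms, trace.stim_end_ms)
    deflection = trace.v_mV[w] - trace.baseline_mV
    peak = float(np.min(deflection))
    steady = _steady_deflection(trace)
    if peak >= -1e-6:
        raise ValueError("no hyperpolarizing deflection in trace")
    return steady / peak


def measure_ap_features(trace: VoltageTrace) -> Tuple[float, float, float, float]:
    """(V_AP, V_th, T_APHW, V_fAHP) from the first action potential."""
    dt = trace.dt_ms
    w = _window(trace, trace.stim_start_ms, trace.stim_end_ms)
    v = trace.v_mV[w]
    dvdt = np.diff(v) / dt
    above = np.flatnonzero(dvdt >= DVDT_THRESHOLD_MV_MS)
    if above.size == 0:
        raise NoSpikeError("no dV/dt crossing of 20 V/s in stimulus window")
    i_th = int(above[0])
    v_th = float(v[i_th])
    # peak: maximum before the voltage first falls back below threshold
    after = v[i_th:]
    below = np.flatnonzero(after < v_th)
    below = below[below > 0]
    i_end = int(below[0]) if below.size else after.size
    i_peak = i_th + int(np.argmax(after[:i_end]))
    v_peak = float(v[i_peak])
    v_ap = v_peak - trace.baseline_mV
    # half-width at half-maximal amplitude relative to threshold
    half = v_th + 0.5 * (v_peak - v_th)
    t_up = _interp_crossing(v, i_th, i_peak, half, dt, rising=True)
    t_dn = _interp_crossing(v, i_peak, min(i_th + i_end, v.size - 1), half,
                            dt, rising=False)
    t_aphw = t_dn - t_up
    # fAHP: most repolarized voltage between this AP and the next threshold
    # crossing (or stimulus end)
    nxt = above[above > i_peak]
    i_stop = int(nxt[0]) if nxt.size else v.size
    v_fahp = float(np.min(v[i_peak:i_stop])) - v_th
    return v_ap, v_th, t_aphw, v_fahp


def _interp_crossing(v: np.ndarray, i0: int, i1: int, level: float,
                     dt: float, rising: bool) -> float:
    seg = v[i0:i1 + 1]
    if rising:
        idx = np.flatnonzero((seg[:-1] < level) & (seg[1:] >= level))
    else:
        idx = np.flatnonzero((seg[:-1] >= level) & (seg[1:] < level))
    if idx.size == 0:
        return (i0 if rising else i1) * dt
    i = int(idx[0]) + i0
    frac = (level - v[i]) / (v[i + 1] - v[i])
    return (i + frac) * dt


def measure_rate_and_sfa(trace: VoltageTrace,
                         amplitude_pA: float) -> Tuple[float, float]:
    """Firing rate (Hz over the 1 s window) and adaptation ratio.

    SFA is the first interspike interval divided by the last; it is
    returned as NaN (undefined) when the trace has fewer than 3 spikes.
    """
    spikes = detect_spikes(trace)
    spikes = spikes[(spikes >= trace.stim_start_ms)
                    & (spikes < trace.stim_end_ms)]
    window_s = (trace.stim_end_ms - trace.stim_start_ms) / 1e3
    rate = spikes.size / window_s
    if spikes.size >= 3:
        isi = np.diff(spikes)
        sfa = float(isi[0] / isi[-1])
    else:
        sfa = float("nan")
    return float(rate), sfa


def measure_all(model: NeuronModel, dt: float = DEFAULT_DT_MS,
                pulse_ms: float = PULSE_MS) -> MeasurementVector:
    """Run the full protocol battery and compute all nine measurements.

    Deterministic for a fixed model and dt.  A non-spiking model yields
    f150 = 0 with the AP features flagged undefined (NaN).
    """
    traces = [run_current_clamp(model, [(float(a), pulse_ms)], dt=dt)
              for a in RIN_AMPLITUDES_PA]
    r_in = measure_input_resistance(traces)
    sag = measure_sag_ratio(traces[0])  # the -50 pA trace
    t50 = run_current_clamp(model, [(50.0, pulse_ms)], dt=dt)
    t150 = run_current_clamp(model, [(150.0, pulse_ms)], dt=dt)
    f50, _ = measure_rate_and_sfa(t50, 50.0)
    f150, sfa = measure_rate_and_sfa(t150, 150.0)
    try:
        v_ap, v_th, t_aphw, v_fahp = measure_ap_features(t150)
    except NoSpikeError:
        v_ap = v_th = t_aphw = v_fahp = float("nan")
    return MeasurementVector(V_AP=v_ap, V_th=v_th, T_APHW=t_aphw,
                             V_fAHP=v_fahp, SFA=sfa, sag=sag, R_in=r_in,
                             f50=f50, f150=f150)
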