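"""Public stepping and current-clamp interface over the compiled kernels.

Spike detection for rasters uses an upward crossing of 0 mV with a 2 ms
refractory hold.  This is distinct from the action-potential *threshold
measurement*, which uses the dV/dt = 20 V/s rule (see
:mod:`dgnet.ephys`).
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence, Tuple

import numpy as np

from . import integrator as _integ
from .integrator import NS, _init_state, _run, _settle, _step
from .kinetics import GATES
from .neuron import CalciumHandling, NeuronModel, VoltageTrace, pack_model

__all__ = [
    "SPIKE_THRESHOLD_MV", "SPIKE_REFRACTORY_MS", "DEFAULT_DT_MS",
    "init_state", "membrane_step", "calcium_step", "run_current_clamp",
    "settled_state",
]

SPIKE_THRESHOLD_MV = 0.0
SPIKE_REFRACTORY_MS = 2.0
DEFAULT_DT_MS = 0.025  # 25 us
DEFAULT_SETTLE_MS = 500.0

_STATE_NAMES = ("v", "Ca") + GATES + ("SK_z", "BK_z")


def init_state(model: NeuronModel) -> np.ndarray:
    """State vector with every gate at steady state for V_RMP."""
    return _init_state(pack_model(model), model.passive.v_rest_mV)


def _check_state(state: np.ndarray) -> None:
    if np.all(np.isfinite(state)):
        return
    bad = [name for name, val in zip(_STATE_NAMES, state) if not np.isfinite(val)]
    raise FloatingPointError(
        f"non-finite membrane state in: {', '.join(bad)}")


def membrane_step(model: NeuronModel, state: np.ndarray, i_inject_pA: float,
                  i_syn_pA: float = 0.0, i_aff_pA: float = 0.0,
                  dt: float = DEFAULT_DT_MS) -> np.ndarray:
    """Advance the membrane state by one time step of ``dt`` ms.

    All currents are absolute (pA), positive depolarizing.  Returns a new
    state vector; the input state is untouched.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    _check_state(np.asarray(state))
    out = np.array(state, dtype=float)
    _step(pack_model(model), out, i_inject_pA + i_syn_pA + i_aff_pA, 0.0, dt)
    _check_state(out)
    return out


def calcium_step(ca: CalciumHandling, i_ca_mA_cm2: float, dt: float,
                 faraday: float = _integ.FARADAY) -> CalciumHandling:
    """Advance cytosolic calcium one step of the first-order decay ODE."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    dca = (-10000.0 * i_ca_mA_cm2 / (ca.influx_denominator * ca.depth_um * faraday)
           + (ca.ca_inf_mM - ca.ca_mM) / ca.tau_ms)
    new = max(ca.ca_mM + dt * dca, _integ._CA_FLOOR)
    return replace(ca, ca_mM=new)


def settled_state(model: NeuronModel, dt: float = DEFAULT_DT_MS,
                  settle_ms: float = DEFAULT_SETTLE_MS) -> np.ndarray:
    """Steady-state initialisation followed by a zero-input settling run."""
    p = pack_model(model)
    s = _init_state(p, model.passive.v_rest_mV)
    _settle(p, s, int(round(settle_ms / dt)), dt)
    _check_state(s)
    return s


def run_current_clamp(model: NeuronModel,
                      protocol: Sequence[Tuple[float, float]],
                      dt: float = DEFAULT_DT_MS,
                      settle_ms: float = DEFAULT_SETTLE_MS,
                      pre_ms: float = 100.0,
                      post_ms: float = 100.0) -> VoltageTrace:
    """Run a current-clamp protocol and return the full voltage trace.

    ``protocol`` is a list of (amplitude pA, duration ms) segments applied
    back to back after a ``pre_ms`` baseline period; the model is first
    settled at rest for ``settle_ms`` (not recorded).  Deterministic for
    fixed inputs.
    """
    if not protocol:
        raise ValueError("protocol must be non-empty")
    p = pack_model(model)
    s = _init_state(p, model.passive.v_rest_mV)
    _settle(p, s, int(round(settle_ms / dt)), dt)
    baseline = s[0]
    segments = [(0.0, pre_ms)] + list(protocol) + [(0.0, post_ms)]
    i_ext = np.concatenate([
        np.full(int(round(dur / dt)), amp) for amp, dur in segments])
    v = _run(p, s, i_ext, dt, True)
    _check_state(s)
    stim_start = pre_ms
    stim_end = pre_ms + sum(dur for _, dur in protocol)
    return VoltageTrace(dt_ms=dt, v_mV=v, i_pA=i_ext, baseline_mV=baseline,
                        stim_start_ms=stim_start, stim_end_ms=stim_end)
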