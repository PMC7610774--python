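"""Single-compartment neuron model definitions.

A :class:`NeuronModel` is a cylinder with passive membrane properties,
per-channel maximal conductance densities (S/cm^2) or GHK permeabilities
(cm/s), a gating-kinetics registry, first-order cytosolic calcium
handling and fixed ionic conditions.  ``gc_base_model`` /
``bc_base_model`` return the calibrated granule- and basket-cell base
models: GC -- 63 um x 63 um cylinder, V_RMP = -75 mV, R_m = 38 kOhm cm^2,
C_m = 1 uF/cm^2 (passive R_in = 305 MOhm, tau = 38 ms); BC -- 66 um x
66 um, V_RMP = -65 mV, R_m = 7.1 kOhm cm^2.

The leak reversal potential is chosen at construction so that the model
rests exactly at V_RMP with every channel at its steady state ("balanced
leak").  A knockout copy keeps the base model's leak reversal, so removing
a resting-active channel (e.g. HCN) shifts the resting potential and input
resistance, as it should.
"""

from __future__ import annotations

import copy as _copy
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np

from . import integrator as _integ
from .constants import (DEFAULT_CONSTANTS, DEFAULT_IONS, IonConcentrations,
                        PhysicalConstants)
from .kinetics import (CHANNELS_BC, CHANNELS_GC, GATES, KineticsRegistry,
                       bc_kinetics, gc_kinetics)

__all__ = [
    "NeuronGeometry", "PassiveProperties", "CalciumHandling", "NeuronModel",
    "VoltageTrace", "gc_base_model", "bc_base_model", "pack_model",
    "scale_geometry",
]


@dataclass
class NeuronGeometry:
    """Cylindrical geometry; the lateral surface is the membrane area."""

    diameter_um: float
    length_um: float

    def __post_init__(self) -> None:
        if self.diameter_um <= 0 or self.length_um <= 0:
            raise ValueError("diameter and length must be > 0")

    @property
    def area_cm2(self) -> float:
        return math.pi * self.diameter_um * 1e-4 * self.length_um * 1e-4


@dataclass
class PassiveProperties:
    v_rest_mV: float
    r_m_kohm_cm2: float
    c_m_uF_cm2: float = 1.0

    def __post_init__(self) -> None:
        if self.r_m_kohm_cm2 <= 0 or self.c_m_uF_cm2 <= 0:
            raise ValueError("R_m and C_m must be > 0")

    @property
    def g_leak_S_cm2(self) -> float:
        return 1e-3 / self.r_m_kohm_cm2

    @property
    def tau_ms(self) -> float:
        """Passive charging time constant R_m C_m (ms)."""
        return self.r_m_kohm_cm2 * self.c_m_uF_cm2


@dataclass
class CalciumHandling:
    """First-order cytosolic calcium dynamics.

    d[Ca]_c/dt = -10000 I_Ca / (denom * dpt * F) + ([Ca]_inf - [Ca]_c)/tau_Ca

    with I_Ca in mA/cm^2, dpt in um and concentrations in mM (rate mM/ms).
    ``influx_denominator`` defaults to 3.6 (the shell-influx reading of the
    printed constant); the literal 36 is available as a configuration
    switch and only rescales the influx gain.
    """

    tau_ms: float = 160.0
    depth_um: float = 0.1
    ca_inf_mM: float = 50e-6
    ca_mM: float = 50e-6
    influx_denominator: float = 3.6

    def __post_init__(self) -> None:
        if self.tau_ms <= 0 or self.depth_um <= 0:
            raise ValueError("tau_Ca and shell depth must be > 0")
        if self.ca_mM <= 0 or self.ca_inf_mM <= 0:
            raise ValueError("calcium concentrations must be > 0")


@dataclass
class VoltageTrace:
    """Uniformly sampled voltage with the aligned stimulus current."""

    dt_ms: float
    v_mV: np.ndarray
    i_pA: np.ndarray
    baseline_mV: float = float("nan")  # settled resting potential
    stim_start_ms: float = 0.0
    stim_end_ms: float = 0.0

    def __post_init__(self) -> None:
        self.v_mV = np.asarray(self.v_mV, dtype=float)
        self.i_pA = np.asarray(self.i_pA, dtype=float)
        if self.v_mV.shape != self.i_pA.shape:
            raise ValueError("voltage and current arrays must align")
        if not np.all(np.isfinite(self.v_mV)):
            raise FloatingPointError("non-finite voltage trace")

    @property
    def t_ms(self) -> np.ndarray:
        return np.arange(1, self.v_mV.size + 1) * self.dt_ms


@dataclass
class NeuronModel:
    """A conductance-based single-compartment GC or BC model."""

    cell_class: str
    geometry: NeuronGeometry
    passive: PassiveProperties
    conductances: Dict[str, float]
    kinetics: KineticsRegistry
    calcium: CalciumHandling = field(default_factory=CalciumHandling)
    ions: IonConcentrations = DEFAULT_IONS
    constants: PhysicalConstants = DEFAULT_CONSTANTS
    e_leak_mV: Optional[float] = None  # computed (balanced) when None

    def __post_init__(self) -> None:
        if self.cell_class not in ("GC", "BC"):
            raise ValueError("cell_class must be 'GC' or 'BC'")
        for name, g in self.conductances.items():
            if g < 0:
                raise ValueError(f"negative conductance for {name}")
        if self.e_leak_mV is None:
            self.e_leak_mV = _balanced_leak_reversal(self)

    @property
    def channel_names(self) -> tuple:
        return CHANNELS_GC if self.cell_class == "GC" else CHANNELS_BC

    def copy(self) -> "NeuronModel":
        return _copy.deepcopy(self)


def _pack_without_leak(model: NeuronModel) -> np.ndarray:
    p = np.zeros(_integ.NP)
    p[_integ.IDX_AREA] = model.geometry.area_cm2
    p[_integ.IDX_CM] = model.passive.c_m_uF_cm2
    p[_integ.IDX_GL] = model.passive.g_leak_S_cm2
    p[_integ.IDX_EL] = model.e_leak_mV if model.e_leak_mV is not None else 0.0
    for i, name in enumerate(CHANNELS_GC):
        p[_integ.IDX_G0 + i] = model.conductances.get(name, 0.0)
    ions, const = model.ions, model.constants
    p[_integ.IDX_ENA] = ions.nernst("na", const)
    p[_integ.IDX_EK] = ions.nernst("k", const)
    p[_integ.IDX_EH] = model.kinetics.e_h
    for g, gate in enumerate(GATES):
        k = model.kinetics.gates[gate]
        b = _integ.IDX_GATE0 + 6 * g
        p[b:b + 6] = (k.v_half, k.slope, k.tau_min, k.tau_amp,
                      k.tau_vhalf, k.tau_slope)
    sk = model.kinetics.sk
    bk = model.kinetics.bk
    if sk is not None:
        p[_integ.IDX_SK:_integ.IDX_SK + 3] = (sk.kd_mM, sk.hill, sk.tau_ms)
    else:
        p[_integ.IDX_SK:_integ.IDX_SK + 3] = (1.0, 1.0, 1.0)
    if bk is not None:
        p[_integ.IDX_BK:_integ.IDX_BK + 5] = (bk.kd_mM, bk.hill, bk.v_half,
                                              bk.slope, bk.tau_ms)
    else:
        p[_integ.IDX_BK:_integ.IDX_BK + 5] = (1.0, 1.0, 0.0, 10.0, 1.0)
    ca = model.calcium
    p[_integ.IDX_TAUCA] = ca.tau_ms
    p[_integ.IDX_DPT] = ca.depth_um
    p[_integ.IDX_CAINF] = ca.ca_inf_mM
    p[_integ.IDX_CADEN] = ca.influx_denominator
    p[_integ.IDX_CAOUT] = ions.ca_out
    p[_integ.IDX_VT] = const.vt_mV
    return p


def _balanced_leak_reversal(model: NeuronModel) -> float:
    """Leak reversal that makes V_RMP a steady state of the full model."""
    p = _pack_without_leak(model)
    v0 = model.passive.v_rest_mV
    p[_integ.IDX_EL] = v0  # leak contributes zero at v0 during this probe
    s = _integ._init_state(p, v0)
    i_active, _ = _integ._membrane_currents(p, s)
    return v0 + i_active / model.passive.g_leak_S_cm2


def pack_model(model: NeuronModel) -> np.ndarray:
    """Pack a model into the integrator's parameter vector."""
    p = _pack_without_leak(model)
    if model.e_leak_mV is None:  # pragma: no cover - set in __post_init__
        p[_integ.IDX_EL] = _balanced_leak_reversal(model)
    return p


def scale_geometry(model: NeuronModel, diameter_um: float) -> NeuronModel:
    """Return a copy with the cylinder scaled to ``diameter_um``.

    Length scales proportionally with diameter, emulating the reduced
    surface area of structurally immature adult-born granule cells.  All
    membrane densities are unchanged, so input resistance scales inversely
    with area.
    """
    if diameter_um <= 0:
        raise ValueError("diameter must be > 0")
    out = model.copy()
    ratio = diameter_um / model.geometry.diameter_um
    out.geometry = NeuronGeometry(diameter_um, model.geometry.length_um * ratio)
    return out


# ---------------------------------------------------------------------------
# calibrated base models

GC_BASE_CONDUCTANCES: Dict[str, float] = {
    # S/cm^2 for NaF..BK, cm/s (GHK permeability) for CaT/CaN/CaL
    "NaF": 0.07,
    "KDR": 0.012,
    "KA": 0.002,
    "HCN": 8e-6,
    "SK": 1e-4,
    "BK": 1.5e-3,
    "CaT": 5e-6,
    "CaN": 1e-5,
    "CaL": 1e-5,
}

BC_BASE_CONDUCTANCES: Dict[str, float] = {
    "NaF": 0.5,
    "KDR": 0.022,
    "KA": 0.002,
    "HCN": 3e-5,
}


def gc_base_model(**overrides) -> NeuronModel:
    """The granule-cell base model (63 x 63 um, R_m 38 kOhm cm^2)."""
    kwargs = dict(
        cell_class="GC",
        geometry=NeuronGeometry(63.0, 63.0),
        passive=PassiveProperties(-75.0, 38.0, 1.0),
        conductances=dict(GC_BASE_CONDUCTANCES),
        kinetics=gc_kinetics(),
        calcium=CalciumHandling(),
    )
    kwargs.update(overrides)
    return NeuronModel(**kwargs)


def bc_base_model(**overrides) -> NeuronModel:
    """The basket-cell base model (66 x 66 um, R_m 7.1 kOhm cm^2)."""
    kwargs = dict(
        cell_class="BC",
        geometry=NeuronGeometry(66.0, 66.0),
        passive=PassiveProperties(-65.0, 7.1, 1.0),
        conductances=dict(BC_BASE_CONDUCTANCES),
        kinetics=bc_kinetics(),
        calcium=CalciumHandling(),
    )
    kwargs.update(overrides)
    return NeuronModel(**kwargs)
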