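"""Multi-parametric multi-objective stochastic search (MPMOSS).

Heterogeneous, physiologically valid GC/BC populations are produced by
unbiased rejection sampling: parameter vectors are drawn uniformly and
independently within configured ranges, each candidate model is measured
with the full current-clamp battery, and a model is retained only when
every one of the nine measurements lies inside its experimentally derived
closed interval (Table-1 bounds below).

The granule-cell search spans exactly 40 parameters (nine maximal
conductances/permeabilities, passive properties, calcium handling,
per-gate half-voltage shifts and time-constant scale factors); the
basket-cell search spans exactly 18.  The shipped ranges bracket the
calibrated base models by roughly 0.5x-2x in the conductance densities
(+/- a few mV in half-voltages); they are configuration, documented as
provisional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .ephys import (MeasurementVector, RIN_AMPLITUDES_PA, NoSpikeError,
                    measure_all, measure_ap_features,
                    measure_input_resistance, measure_rate_and_sfa,
                    measure_sag_ratio)
from .kinetics import GATES
from .membrane import DEFAULT_DT_MS, run_current_clamp
from .neuron import NeuronModel, bc_base_model, gc_base_model

__all__ = [
    "ParameterTable", "ValidationBounds", "ValidPopulation",
    "gc_parameter_table", "bc_parameter_table", "TABLE1_BOUNDS",
    "sample_parameters", "build_model", "validate_measurements",
    "run_search",
]


@dataclass(frozen=True)
class ParameterEntry:
    name: str
    unit: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower bound must be < upper")


@dataclass
class ParameterTable:
    """Ordered search-space definition for one cell class."""

    cell_class: str
    entries: List[ParameterEntry]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> List[str]:
        return [e.name for e in self.entries]

    @property
    def lower(self) -> np.ndarray:
        return np.array([e.lower for e in self.entries])

    @property
    def upper(self) -> np.ndarray:
        return np.array([e.upper for e in self.entries])


def _conductance_entries(base: Dict[str, float],
                         lo: float = 0.5, hi: float = 2.0) -> List[ParameterEntry]:
    out = []
    for name, g in base.items():
        unit = "cm/s" if name.startswith("Ca") else "S/cm^2"
        prefix = "p" if name.startswith("Ca") else "g"
        out.append(ParameterEntry(f"{prefix}_{name}", unit, lo * g, hi * g))
    return out


def gc_parameter_table() -> ParameterTable:
    """The 40-parameter granule-cell search space."""
    from .neuron import GC_BASE_CONDUCTANCES
    e = _conductance_entries(GC_BASE_CONDUCTANCES)           # 9
    e += [
        ParameterEntry("R_m", "kOhm cm^2", 28.0, 48.0),
        ParameterEntry("C_m", "uF/cm^2", 0.8, 1.2),
        ParameterEntry("V_RMP", "mV", -80.0, -70.0),
        ParameterEntry("tau_Ca", "ms", 80.0, 320.0),
        ParameterEntry("dpt", "um", 0.05, 0.2),
    ]                                                         # 5 -> 14
    e += [ParameterEntry(f"{g}_shift", "mV", -3.0, 3.0) for g in GATES]   # 11 -> 25
    e += [ParameterEntry(f"{g}_tau", "x", 0.8, 1.3) for g in GATES]       # 11 -> 36
    e += [
        ParameterEntry("SK_kd", "mM", 2.5e-3, 1e-2),
        ParameterEntry("SK_tau", "ms", 8.0, 30.0),
        ParameterEntry("BK_kd", "mM", 1e-3, 4e-3),
        ParameterEntry("BK_tau", "ms", 0.6, 2.4),
    ]                                                         # 4 -> 40
    return ParameterTable("GC", e)


_BC_GATES = ("NaF_m", "NaF_h", "KDR_n", "KA_a", "KA_b", "HCN_h")


def bc_parameter_table() -> ParameterTable:
    """The 18-parameter basket-cell search space."""
    from .neuron import BC_BASE_CONDUCTANCES
    e = _conductance_entries(BC_BASE_CONDUCTANCES)            # 4
    e += [
        ParameterEntry("R_m", "kOhm cm^2", 5.5, 9.0),
        ParameterEntry("V_RMP", "mV", -70.0, -60.0),
    ]                                                         # 2 -> 6
    e += [ParameterEntry(f"{g}_shift", "mV", -3.0, 3.0) for g in _BC_GATES]  # 6 -> 12
    e += [ParameterEntry(f"{g}_tau", "x", 0.8, 1.3) for g in _BC_GATES]      # 6 -> 18
    return ParameterTable("BC", e)


# ---------------------------------------------------------------------------
# Table-1 validation bounds (closed intervals), per cell class

TABLE1_BOUNDS: Dict[str, Dict[str, Tuple[float, float]]] = {
    "GC": {
        "V_AP": (95.0, 115.0),
        "V_th": (-55.0, -40.0),
        "T_APHW": (0.53, 1.6),
        "V_fAHP": (-25.0, -3.4),
        "sag": (0.9, 1.0),
        "SFA": (0.1, 0.8),
        "R_in": (107.0, 228.0),
        "f50": (0.0, 0.0),
        "f150": (10.0, 15.0),
    },
    "BC": {
        "V_AP": (110.0, 120.0),
        "V_th": (-51.0, -41.0),
        "T_APHW": (0.53, 1.5),
        "V_fAHP": (-27.0, -14.0),
        "sag": (0.9, 1.0),
        "SFA": (0.9, 1.04),
        "R_in": (45.0, 65.0),
        "f50": (0.0, 0.0),
        "f150": (30.0, 50.0),
    },
}


@dataclass
class ValidationBounds:
    """Per-measurement closed intervals used to accept candidate models."""

    bounds: Dict[str, Tuple[float, float]]

    @classmethod
    def table1(cls, cell_class: str) -> "ValidationBounds":
        if cell_class not in TABLE1_BOUNDS:
            raise ValueError(f"unknown cell class: {cell_class}")
        return cls(dict(TABLE1_BOUNDS[cell_class]))


def validate_measurements(m: MeasurementVector, bounds: ValidationBounds,
                          cell_class: Optional[str] = None
                          ) -> Tuple[bool, Dict[str, bool]]:
    """Check a measurement vector against closed validation intervals.

    Returns (passed, per-measurement flags).  Undefined measurements
    (NaN, e.g. AP features of a non-spiking model) fail automatically.
    """
    if isinstance(bounds, str):  # tolerate (bounds, cell_class) swapped use
        raise TypeError("bounds must be a ValidationBounds")
    flags: Dict[str, bool] = {}
    md = m.as_dict()
    for name, (lo, hi) in bounds.bounds.items():
        val = md[name]
        flags[name] = bool(np.isfinite(val) and lo <= val <= hi)
    return all(flags.values()), flags


def sample_parameters(table: ParameterTable, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` uniform parameter vectors (shape n x len(table))."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(table.lower, table.upper, size=(n, len(table)))


def build_model(cell_class: str, params: Dict[str, float]) -> NeuronModel:
    """Instantiate a model from a named parameter dictionary.

    Unrecognised names raise; omitted parameters keep base-model values.
    """
    model = gc_base_model() if cell_class == "GC" else bc_base_model()
    gates = model.kinetics.gates
    for name, val in params.items():
        if name.startswith(("g_", "p_")):
            channel = name[2:]
            if channel not in model.conductances:
                raise KeyError(f"unknown channel parameter {name}")
            model.conductances[channel] = float(val)
        elif name == "R_m":
            model.passive.r_m_kohm_cm2 = float(val)
        elif name == "C_m":
            model.passive.c_m_uF_cm2 = float(val)
        elif name == "V_RMP":
            model.passive.v_rest_mV = float(val)
        elif name == "tau_Ca":
            model.calcium.tau_ms = float(val)
        elif name == "dpt":
            model.calcium.depth_um = float(val)
        elif name == "SK_kd":
            model.kinetics.sk.kd_mM = float(val)
        elif name == "SK_tau":
            model.kinetics.sk.tau_ms = float(val)
        elif name == "BK_kd":
            model.kinetics.bk.kd_mM = float(val)
        elif name == "BK_tau":
            model.kinetics.bk.tau_ms = float(val)
        elif name.endswith("_shift"):
            gate = name[:-len("_shift")]
            gates[gate].v_half += float(val)
            gates[gate].tau_vhalf += float(val)
        elif name.endswith("_tau"):
            gate = name[:-len("_tau")]
            gates[gate].tau_min *= float(val)
            gates[gate].tau_amp *= float(val)
        else:
            raise KeyError(f"unknown parameter {name}")
    # re-balance the leak reversal for the new parameter set
    model.e_leak_mV = None
    model.__post_init__()
    return model


@dataclass
class ValidPopulation:
    """Search result: retained models with their measurements."""

    cell_class: str
    models: List[NeuronModel]
    measurements: List[MeasurementVector]
    parameters: List[Dict[str, float]]
    n_sampled: int
    seed: int

    @property
    def yield_fraction(self) -> float:
        return len(self.models) / self.n_sampled if self.n_sampled else 0.0

    def __len__(self) -> int:
        return len(self.models)


def _fast_reject(model: NeuronModel, bounds: ValidationBounds,
                 dt: float) -> bool:
    """Cheap staged screen before the full battery (search-internal).

    Runs the 150 pA and -50 pA protocols first; candidates failing the
    suprathreshold or sag bounds are rejected without the 11-pulse R_in
    battery.  Retained models are always re-measured in full, so this
    never changes which models are valid, only how fast invalid ones are
    discarded.
    """
    b = bounds.bounds
    t150 = run_current_clamp(model, [(150.0, 1000.0)], dt=dt)
    f150, sfa = measure_rate_and_sfa(t150, 150.0)
    if not (b["f150"][0] <= f150 <= b["f150"][1]):
        return True
    if not (np.isfinite(sfa) and b["SFA"][0] <= sfa <= b["SFA"][1]):
        return True
    try:
        v_ap, v_th, t_aphw, v_fahp = measure_ap_features(t150)
    except NoSpikeError:
        return True
    for name, val in (("V_AP", v_ap), ("V_th", v_th),
                      ("T_APHW", t_aphw), ("V_fAHP", v_fahp)):
        lo, hi = b[name]
        if not lo <= val <= hi:
            return True
    tm50 = run_current_clamp(model, [(-50.0, 1000.0)], dt=dt)
    sag = measure_sag_ratio(tm50)
    if not (b["sag"][0] <= sag <= b["sag"][1]):
        return True
    return False


def run_search(table: ParameterTable, bounds: ValidationBounds, n: int,
               seed: int, dt: float = DEFAULT_DT_MS,
               progress: Optional[Callable[[int, int], None]] = None
               ) -> ValidPopulation:
    """Sample ``n`` models, validate each, and return the valid population.

    Every retained model passes :func:`validate_measurements` on a full
    :func:`~dgnet.ephys.measure_all` battery; an integration failure in a
    candidate counts as a rejection.  Reproducible for a fixed seed.
    """
    samples = sample_parameters(table, n, seed)
    names = table.names
    models: List[NeuronModel] = []
    vectors: List[MeasurementVector] = []
    dicts: List[Dict[str, float]] = []
    for i in range(n):
        pdict = {name: float(v) for name, v in zip(names, samples[i])}
        try:
            model = build_model(table.cell_class, pdict)
            if _fast_reject(model, bounds, dt):
                continue
            mv = measure_all(model, dt=dt)
        except (FloatingPointError, ValueError, ZeroDivisionError,
                OverflowError):
            continue
        ok, _ = validate_measurements(mv, bounds)
        if ok:
            models.append(model)
            vectors.append(mv)
            dicts.append(pdict)
        if progress is not None:
            progress(i + 1, len(models))
    if not models:
        import warnings
        warnings.warn("stochastic search returned zero valid models")
    return ValidPopulation(table.cell_class, models, vectors, dicts, n, seed)
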