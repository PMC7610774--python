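"""Physical constants and ionic conditions shared by all models.

All simulations run at a fixed temperature of 34 degrees C (307.15 K).
Voltages are millivolts, time is milliseconds, membrane current densities
are mA/cm^2 and concentrations are millimolar unless a field says otherwise.

Sign conventions (used consistently across the package):

* transmembrane channel/receptor currents are positive when outward;
* injected, synaptic and afferent currents (pA) are positive when
  depolarizing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

FARADAY = 96485.332  # C/mol
GAS_CONSTANT = 8.314462  # J/(mol K)
CELSIUS = 34.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Faraday constant, gas constant and absolute temperature.

    The temperature is fixed per simulation; the default corresponds to
    the 34 degrees C used throughout.
    """

    F: float = FARADAY
    R: float = GAS_CONSTANT
    T: float = 273.15 + CELSIUS

    def __post_init__(self) -> None:
        if not (self.F > 0 and self.R > 0 and self.T > 0):
            raise ValueError("F, R and T must be strictly positive")

    @property
    def vt_mV(self) -> float:
        """Thermal voltage RT/F in millivolts (~26.47 mV at 34 C)."""
        return 1000.0 * self.R * self.T / self.F


@dataclass(frozen=True)
class IonConcentrations:
    """Intracellular/extracellular concentrations (mM).

    Defaults: Na 18/140, K 140/5, Cl 5/98, Ca 50 nM / 2 mM.  Cytosolic
    calcium is dynamic during simulation; ``ca_in`` is its resting value.
    """

    na_in: float = 18.0
    na_out: float = 140.0
    k_in: float = 140.0
    k_out: float = 5.0
    cl_in: float = 5.0
    cl_out: float = 98.0
    ca_in: float = 50e-6
    ca_out: float = 2.0

    def __post_init__(self) -> None:
        for name in ("na_in", "na_out", "k_in", "k_out",
                     "cl_in", "cl_out", "ca_in", "ca_out"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def nernst(self, species: str, constants: PhysicalConstants | None = None) -> float:
        """Nernst equilibrium potential (mV) for ``species`` in {na, k, cl, ca}."""
        c = constants or PhysicalConstants()
        z = {"na": 1, "k": 1, "cl": -1, "ca": 2}[species]
        c_in = getattr(self, f"{species}_in")
        c_out = getattr(self, f"{species}_out")
        return c.vt_mV / z * math.log(c_out / c_in)


DEFAULT_CONSTANTS = PhysicalConstants()
DEFAULT_IONS = IonConcentrations()
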