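"""Goldman-Hodgkin-Katz constant-field current equation.

Calcium channel currents and the AMPA/GABA_A receptor currents are
computed with the GHK current equation rather than an ohmic driving
force.  The current density for an ion of valence ``z`` with membrane
permeability ``P`` (cm/s) is

    I = P z^2 (vF^2 / RT) * (c_in - c_out exp(-zvF/RT)) / (1 - exp(-zvF/RT))

with concentrations in mol/cm^3; here concentrations are passed in mM and
the result is returned in mA/cm^2 (positive = outward).  The removable
singularity at v = 0 is handled with the analytic limit
I(0) = 1e-3 P z F (c_in - c_out).
"""

from __future__ import annotations

import math

import numpy as np

from .constants import PhysicalConstants, DEFAULT_CONSTANTS

__all__ = ["ghk_current", "ghk_reversal_numeric"]

# below this |zv/vt| the series expansion replaces the exact expression
_U_SMALL = 1e-4


def ghk_current(v, permeability, valence, c_in, c_out,
                constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """GHK current density (mA/cm^2) at membrane potential ``v`` (mV).

    Parameters
    ----------
    v : float or ndarray
        Membrane potential in mV.  Must be finite.
    permeability : float
        Membrane permeability in cm/s, >= 0.
    valence : int
        Ionic valence (e.g. +1 Na/K, -1 Cl, +2 Ca).
    c_in, c_out : float
        Intracellular / extracellular concentrations in mM, > 0.

    Returns
    -------
    float or ndarray
        Current density in mA/cm^2, positive outward.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    if permeability < 0:
        raise ValueError("permeability must be >= 0")
    if c_in <= 0 or c_out <= 0:
        raise ValueError("concentrations must be > 0")

    z = float(valence)
    vt = constants.vt_mV
    w = v / vt
    u = z * w
    small = np.abs(u) < _U_SMALL
    u_safe = np.where(small, 1.0, u)
    exact = z * z * w * (c_in - c_out * np.exp(-u_safe)) / (1.0 - np.exp(-u_safe))
    series = z * (c_in - c_out) + z * z * w * 0.5 * (c_in + c_out)
    bracket = np.where(small, series, exact)
    out = 1e-3 * permeability * constants.F * bracket
    return out if out.ndim else float(out)


def ghk_reversal_numeric(permeability_terms, lo=-150.0, hi=150.0,
                         constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Zero-crossing voltage (mV) of a sum of GHK components.

    ``permeability_terms`` is an iterable of ``(P, z, c_in, c_out)``
    tuples; the composite current is the sum of the individual GHK
    currents (e.g. the Na + K components of the AMPA receptor).  Uses
    bisection on the (monotone) composite current.
    """
    from scipy.optimize import brentq

    def total(v: float) -> float:
        return sum(ghk_current(v, p, z, ci, co, constants)
                   for p, z, ci, co in permeability_terms)

    return float(brentq(total, lo, hi, xtol=1e-9))
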