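"""Hodgkin-Huxley style gating kinetics for granule- and basket-cell channels.

The granule cell (GC) expresses nine active channels -- NaF, KDR, KA, HCN,
SK, BK, CaT, CaN, CaL -- and the basket cell (BC) four -- NaF, KDR, KA,
HCN.  Sodium, potassium and HCN channels use an ohmic (Nernstian) driving
force; the three calcium channels use the GHK current equation with the
dynamic cytosolic calcium concentration.  SK is gated purely by cytosolic
calcium; BK requires both depolarization and calcium.

Voltage-gated gates use Boltzmann steady states

    x_inf(v) = 1 / (1 + exp(-(v - v_half)/slope))

(negative ``slope`` for inactivation gates) and sigmoidal voltage-dependent
time constants

    tau(v) = tau_min + tau_amp / (1 + exp((v - tau_vhalf)/tau_slope)).

The numeric values below are a calibrated registry in the canonical style
of published dentate gyrus models (fast transient Na, delayed-rectifier K,
inactivating A-type K, slow hyperpolarization-activated HCN, high- and
low-voltage-activated Ca); they are configuration, not hard-coded physics,
and every entry can be overridden per model.  Gate exponents: NaF m^3 h,
KDR n^2, KA a b, HCN single gate, CaT m^2 h, CaN m^2 h, CaL m^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

# canonical channel ordering used throughout the package
CHANNELS_GC = ("NaF", "KDR", "KA", "HCN", "SK", "BK", "CaT", "CaN", "CaL")
CHANNELS_BC = ("NaF", "KDR", "KA", "HCN")

# gate ordering matching the packed state layout of the integrator
GATES = ("NaF_m", "NaF_h", "KDR_n", "KA_a", "KA_b", "HCN_h",
         "CaT_m", "CaT_h", "CaN_m", "CaN_h", "CaL_m")


@dataclass
class GateKinetics:
    """One voltage-gated activation/inactivation gate."""

    v_half: float  # mV
    slope: float   # mV; > 0 activation, < 0 inactivation
    tau_min: float  # ms
    tau_amp: float = 0.0  # ms; 0 -> voltage-independent time constant
    tau_vhalf: float = 0.0  # mV
    tau_slope: float = 10.0  # mV

    def steady_state(self, v: float) -> float:
        import math
        return 1.0 / (1.0 + math.exp(-(v - self.v_half) / self.slope))

    def time_constant(self, v: float) -> float:
        import math
        return self.tau_min + self.tau_amp / (
            1.0 + math.exp((v - self.tau_vhalf) / self.tau_slope))


@dataclass
class SKKinetics:
    """Purely calcium-gated SK channel: z_inf = ca^h / (ca^h + kd^h)."""

    kd_mM: float = 0.5e-3
    hill: float = 4.0
    tau_ms: float = 15.0


@dataclass
class BKKinetics:
    """Calcium- and voltage-gated BK channel.

    z_inf = Boltzmann(v) * ca^h / (ca^h + kd^h), relaxing with ``tau_ms``.
    """

    kd_mM: float = 1.0e-3
    hill: float = 2.0
    v_half: float = -10.0
    slope: float = 12.0
    tau_ms: float = 1.0


@dataclass
class KineticsRegistry:
    """Complete gating registry for one cell class."""

    gates: Dict[str, GateKinetics]
    sk: Optional[SKKinetics] = None
    bk: Optional[BKKinetics] = None
    e_h: float = -30.0  # HCN mixed-cation reversal (mV)

    def copy(self) -> "KineticsRegistry":
        return KineticsRegistry(
            gates={k: replace(v) for k, v in self.gates.items()},
            sk=replace(self.sk) if self.sk else None,
            bk=replace(self.bk) if self.bk else None,
            e_h=self.e_h,
        )

    def validate(self, v_range=(-120.0, 60.0)) -> None:
        for name, g in self.gates.items():
            for v in (v_range[0], 0.5 * sum(v_range), v_range[1]):
                x = g.steady_state(v)
                if not 0.0 <= x <= 1.0:
                    raise ValueError(f"{name}: steady state outside [0,1]")
                if g.time_constant(v) <= 0:
                    raise ValueError(f"{name}: non-positive time constant")


def gc_kinetics() -> KineticsRegistry:
    """Granule-cell gating registry (regular spiking, adapting)."""
    return KineticsRegistry(
        gates={
            "NaF_m": GateKinetics(-42.0, 6.0, 0.18),
            "NaF_h": GateKinetics(-52.0, -6.0, 0.4, 6.0, -55.0, 8.0),
            "KDR_n": GateKinetics(-30.0, 10.0, 0.5, 0.22, -30.0, 10.0),
            "KA_a": GateKinetics(-10.0, 10.0, 1.0),
            "KA_b": GateKinetics(-70.0, -7.0, 5.0, 20.0, -60.0, 10.0),
            "HCN_h": GateKinetics(-82.0, -9.0, 50.0),
            "CaT_m": GateKinetics(-52.0, 5.0, 2.0),
            "CaT_h": GateKinetics(-72.0, -5.0, 25.0),
            "CaN_m": GateKinetics(-20.0, 7.0, 1.5),
            "CaN_h": GateKinetics(-60.0, -10.0, 80.0),
            "CaL_m": GateKinetics(-12.0, 7.0, 1.5),
        },
        sk=SKKinetics(kd_mM=5e-3, hill=4.0, tau_ms=15.0),
        bk=BKKinetics(kd_mM=2e-3, hill=2.0, v_half=-5.0, slope=12.0,
                      tau_ms=1.2),
    )


def bc_kinetics() -> KineticsRegistry:
    """Basket-cell gating registry (fast spiking, non-adapting).

    Only the four voltage-gated channels are present; the calcium entries
    are retained in the gate table (with zero conductance in the model) so
    both classes share one state layout.
    """
    return KineticsRegistry(
        gates={
            "NaF_m": GateKinetics(-36.0, 6.0, 0.12),
            "NaF_h": GateKinetics(-56.0, -4.0, 0.3, 3.0, -55.0, 8.0),
            "KDR_n": GateKinetics(-30.0, 6.0, 0.25, 0.5, -40.0, -10.0),
            "KA_a": GateKinetics(-10.0, 12.0, 0.6),
            "KA_b": GateKinetics(-68.0, -7.0, 4.0, 15.0, -60.0, 10.0),
            "HCN_h": GateKinetics(-84.0, -8.0, 40.0),
            "CaT_m": GateKinetics(-52.0, 5.0, 2.0),
            "CaT_h": GateKinetics(-72.0, -5.0, 25.0),
            "CaN_m": GateKinetics(-20.0, 7.0, 1.5),
            "CaN_h": GateKinetics(-60.0, -10.0, 80.0),
            "CaL_m": GateKinetics(-12.0, 7.0, 1.5),
        },
        sk=None,
        bk=None,
    )
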