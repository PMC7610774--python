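"""Single-neuron virtual knockout models (VKMs).

A virtual knockout sets one channel's maximal conductance (or GHK
permeability) to exactly zero in a copy of a valid model, re-runs the
full measurement battery, and quantifies the impact as a percentage
change of each measurement from its base value:

    dM = 100 * (M_knockout - M_base) / M_base.

Population sweeps summarise these percentage changes as quartiles
(median and 25th/75th percentiles, linear interpolation).  NaF and KDR
are excluded from measurement sweeps -- removing either abolishes
action-potential firing or repolarization, leaving the suprathreshold
measurements undefined -- and f50 is excluded because it is pinned at
zero by validation.  Measurements that are undefined after a knockout
(e.g. no spikes) are reported as missing, not zero, and excluded
pairwise from the summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .ephys import MeasurementVector, measure_all
from .membrane import DEFAULT_DT_MS
from .mpmoss import ValidPopulation
from .neuron import NeuronModel

__all__ = [
    "knockout", "percent_change", "KnockoutResult", "vkm_sweep",
    "SWEEP_MEASUREMENTS", "GC_SWEEP_CHANNELS", "BC_SWEEP_CHANNELS",
]

# the eight measurements analysed in knockout sweeps (f50 excluded)
SWEEP_MEASUREMENTS = ("V_AP", "V_th", "T_APHW", "V_fAHP", "SFA", "sag",
                      "R_in", "f150")
# spike-generating conductances are excluded from sweeps
GC_SWEEP_CHANNELS = ("KA", "HCN", "SK", "BK", "CaT", "CaN", "CaL")
BC_SWEEP_CHANNELS = ("KA", "HCN")


def knockout(model: NeuronModel, channel: str) -> NeuronModel:
    """Non-destructive copy of ``model`` with ``channel`` zeroed.

    Everything else -- including the balanced leak reversal of the base
    model -- is untouched, so the knockout's resting state may shift, as
    it does when a resting-active channel is removed.  Idempotent.
    """
    if channel not in model.conductances:
        raise KeyError(f"unknown channel {channel!r} for {model.cell_class}")
    out = model.copy()
    out.conductances[channel] = 0.0
    return out


def percent_change(m_base: float, m_vkm: float) -> float:
    """Percentage change of a measurement after knockout.

    Returns NaN (flagged undefined) when the base value is zero or
    either value is undefined; such entries are excluded from summaries.
    """
    if not (np.isfinite(m_base) and np.isfinite(m_vkm)) or m_base == 0:
        return float("nan")
    return 100.0 * (m_vkm - m_base) / m_base


@dataclass
class KnockoutResult:
    """Knockout outcome for one model/channel pair."""

    model_index: int
    channel: str
    base: MeasurementVector
    vkm: MeasurementVector

    @property
    def delta_percent(self) -> Dict[str, float]:
        b, k = self.base.as_dict(), self.vkm.as_dict()
        return {name: percent_change(b[name], k[name]) for name in b}


def vkm_sweep(population: ValidPopulation,
              channels: Optional[Sequence[str]] = None,
              measurements: Sequence[str] = SWEEP_MEASUREMENTS,
              dt: float = DEFAULT_DT_MS) -> pd.DataFrame:
    """Knock out each channel from each model and tabulate dM (%).

    Returns a tidy DataFrame with one row per (model, channel) and one
    column per measurement, holding Eq.-style percentage changes; the
    base population is never modified.  ``channels`` defaults to the
    non-spike-generating channels of the population's cell class.
    """
    if len(population) == 0:
        raise ValueError("population is empty")
    if channels is None:
        channels = (GC_SWEEP_CHANNELS if population.cell_class == "GC"
                    else BC_SWEEP_CHANNELS)
    rows = []
    for idx, (model, base_mv) in enumerate(
            zip(population.models, population.measurements)):
        base = base_mv.as_dict()
        for ch in channels:
            ko = knockout(model, ch)
            try:
                mv = measure_all(ko, dt=dt).as_dict()
            except FloatingPointError:
                mv = {name: float("nan") for name in base}
            row = {"model": idx, "channel": ch}
            row.update({name: percent_change(base[name], mv[name])
                        for name in measurements})
            rows.append(row)
    cols = ["model", "channel", *measurements]
    return pd.DataFrame(rows, columns=cols)


def sweep_quartiles(sweep: pd.DataFrame,
                    measurements: Sequence[str] = SWEEP_MEASUREMENTS
                    ) -> pd.DataFrame:
    """Per-channel quartile summary (25/50/75, linear interpolation)."""
    present = [m for m in measurements if m in sweep.columns]
    out = sweep.groupby("channel")[list(present)].quantile([0.25, 0.5, 0.75])
    out.index.names = ["channel", "quartile"]
    return out
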