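"""Entorhinal afferent synthesis: arena, trajectory and input currents.

A virtual animal traverses a 1 m x 1 m arena with direction and step
length redrawn every millisecond (speed band 2.5-3.5 m/s, i.e.
2.5-3.5 mm per 1 ms step; steps that would leave the arena are redrawn).
Every dentate neuron receives active input from 5 medial entorhinal
(MEC) grid cells and 5 lateral entorhinal (LEC) tile cells, with the
two streams weighted equally.

A grid cell's normalized drive at position (x, y) is the hexagonal
sum-of-three-cosines field

    psi(x, y) = (2/3) * ((cos g1 + cos g2 + cos g3)/3 + 1/2),
    g_i = k [ (cos a_i + sin a_i)(x - x0) + (cos a_i - sin a_i)(y - y0) ],

with wave angles a_i = theta + {pi/12, 5 pi/12, 3 pi/4} and spatial
prefactor k = 4 pi lambda / sqrt(6); lambda (the grid frequency, sampled
uniformly in [2, 6] per metre) and theta (orientation, [0, 360) degrees)
are per-cell.  psi is 1 at the offset (x0, y0) and bounded in [0, 1].
An LEC cell is a random binary 5 x 5 tiling of the arena (each tile
active with probability 0.5); its drive is the value of the tile
containing the position (half-open tiles resolve edges).

Afferent drive onto structurally immature cells is scaled by the
membrane-area ratio (diameter and length scale together), emulating the
reduced synaptic connectivity of adult-born neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .integrator import _random_walk

__all__ = [
    "Arena", "Trajectory", "GridCellSpec", "LECCellSpec", "AfferentBank",
    "generate_trajectory", "grid_current", "lec_current",
    "total_afferent_current", "afferent_current_matrix",
    "scale_drive_by_geometry", "sample_grid_spec", "sample_lec_spec",
]

_WAVE_ANGLES = (np.pi / 12.0, 5.0 * np.pi / 12.0, 3.0 * np.pi / 4.0)
REFERENCE_DIAMETER_UM = 63.0
# Floor for the area-ratio drive scaling.  Below ~6.3 um the reduction
# stops tracking the membrane area, leaving the smallest (immature) cells
# relatively over-driven: the drive reduction deliberately undercompensates
# their high excitability, keeping every cell active and rate variability
# low across mixed-age populations.
MIN_DRIVE_SCALE = 0.005


@dataclass(frozen=True)
class Arena:
    """Square arena; origin at the lower-left corner, coordinates in m."""

    width_m: float = 1.0
    height_m: float = 1.0

    def contains(self, x, y) -> bool:
        return bool(np.all((x >= 0) & (x <= self.width_m)
                           & (y >= 0) & (y <= self.height_m)))


@dataclass
class Trajectory:
    """1 ms-resolution virtual-animal path starting at the arena center."""

    x_m: np.ndarray
    y_m: np.ndarray
    dt_ms: float = 1.0
    arena: Arena = field(default_factory=Arena)

    def __post_init__(self) -> None:
        self.x_m = np.asarray(self.x_m, dtype=float)
        self.y_m = np.asarray(self.y_m, dtype=float)
        if self.x_m.shape != self.y_m.shape:
            raise ValueError("x and y must align")
        if not self.arena.contains(self.x_m, self.y_m):
            raise ValueError("trajectory leaves the arena")

    @property
    def n_samples(self) -> int:
        return self.x_m.size

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.dt_ms / 1e3


def generate_trajectory(duration_s: float, arena: Optional[Arena] = None,
                        speed_band_m_s=(2.5, 3.5), seed: int = 0
                        ) -> Trajectory:
    """Random arena traversal; direction/step redrawn each millisecond.

    The printed speed band (m/s) maps to mm per 1 ms step; proposals that
    would cross the boundary are redrawn.  Bit-reproducible per seed.
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    arena = arena or Arena()
    n_ms = int(round(duration_s * 1e3))
    step_min = speed_band_m_s[0] * 1e-3  # m per ms
    step_max = speed_band_m_s[1] * 1e-3
    xs, ys = _random_walk(n_ms, arena.width_m / 2.0, arena.height_m / 2.0,
                          step_min, step_max, seed)
    return Trajectory(xs, ys, 1.0, arena)


@dataclass(frozen=True)
class GridCellSpec:
    """One MEC grid cell: spatial frequency, orientation and offsets."""

    grid_frequency: float      # lambda, per metre, sampled U[2, 6]
    orientation_deg: float     # theta, [0, 360)
    x0_m: float
    y0_m: float

    def __post_init__(self) -> None:
        if self.grid_frequency <= 0:
            raise ValueError("grid frequency must be > 0")


@dataclass(frozen=True)
class LECCellSpec:
    """One LEC cell: binary 5 x 5 active-tile matrix."""

    tiles: tuple  # 5 rows x 5 cols of 0/1, row-major

    def __post_init__(self) -> None:
        arr = np.asarray(self.tiles)
        if arr.shape != (5, 5):
            raise ValueError("LEC spec needs a 5 x 5 tile matrix")

    @property
    def tile_array(self) -> np.ndarray:
        return np.asarray(self.tiles, dtype=float)


def sample_grid_spec(rng: np.random.Generator) -> GridCellSpec:
    return GridCellSpec(
        grid_frequency=float(rng.uniform(2.0, 6.0)),
        orientation_deg=float(rng.uniform(0.0, 360.0)),
        x0_m=float(rng.uniform(0.0, 1.0)),
        y0_m=float(rng.uniform(0.0, 1.0)),
    )


def sample_lec_spec(rng: np.random.Generator,
                    p_active: float = 0.5) -> LECCellSpec:
    tiles = (rng.random((5, 5)) < p_active).astype(int)
    return LECCellSpec(tuple(map(tuple, tiles)))


def grid_current(x, y, spec: GridCellSpec):
    """Normalized hexagonal grid drive psi(x, y) in [0, 1]."""
    theta = np.deg2rad(spec.orientation_deg)
    k = 4.0 * np.pi * spec.grid_frequency / np.sqrt(6.0)
    dx = np.asarray(x) - spec.x0_m
    dy = np.asarray(y) - spec.y0_m
    acc = 0.0
    for off in _WAVE_ANGLES:
        a = theta + off
        g = k * ((np.cos(a) + np.sin(a)) * dx + (np.cos(a) - np.sin(a)) * dy)
        acc = acc + np.cos(g)
    psi = (2.0 / 3.0) * (acc / 3.0 + 0.5)
    return psi if np.ndim(psi) else float(psi)


def lec_current(x, y, spec: LECCellSpec):
    """Binary LEC tile drive at (x, y); tiles are half-open in x and y."""
    tiles = spec.tile_array
    col = np.minimum((np.asarray(x) * 5).astype(int), 4)
    row = np.minimum((np.asarray(y) * 5).astype(int), 4)
    out = tiles[row, col]
    return out if np.ndim(out) else float(out)


def scale_drive_by_geometry(diameter_um: float,
                            reference_um: float = REFERENCE_DIAMETER_UM
                            ) -> float:
    """Afferent-drive scale for a cell of ``diameter_um``.

    Membrane-area ratio with length scaling proportionally to diameter,
    i.e. (d / d_ref)^2; equals 1 at the mature reference diameter and is
    floor-clipped at ``MIN_DRIVE_SCALE`` (non-decreasing in diameter).
    """
    if diameter_um <= 0:
        raise ValueError("diameter must be > 0")
    return max((diameter_um / reference_um) ** 2, MIN_DRIVE_SCALE)


@dataclass
class AfferentBank:
    """Per-neuron assignment of 5 grid + 5 LEC inputs with gains.

    In identical mode every neuron shares one spec set (pairwise input
    correlation is then exactly 1); in heterogeneous mode each neuron
    draws independent specs.  ``gain_pA`` converts the normalized mean
    drive to current; ``scale`` holds the per-neuron geometry factor.
    """

    grid_specs: List[List[GridCellSpec]]
    lec_specs: List[List[LECCellSpec]]
    gain_pA: float
    scale: np.ndarray
    identical: bool

    def __post_init__(self) -> None:
        n = len(self.grid_specs)
        if len(self.lec_specs) != n or len(self.scale) != n:
            raise ValueError("bank components must align")
        self.scale = np.asarray(self.scale, dtype=float)

    @property
    def n_neurons(self) -> int:
        return len(self.grid_specs)

    @classmethod
    def build(cls, n_neurons: int, gain_pA: float, identical: bool,
              seed: int, scale: Optional[Sequence[float]] = None,
              n_grid: int = 5, n_lec: int = 5) -> "AfferentBank":
        rng = np.random.default_rng(seed)
        if identical:
            shared_grid = [sample_grid_spec(rng) for _ in range(n_grid)]
            shared_lec = [sample_lec_spec(rng) for _ in range(n_lec)]
            grids = [list(shared_grid) for _ in range(n_neurons)]
            lecs = [list(shared_lec) for _ in range(n_neurons)]
        else:
            grids = [[sample_grid_spec(rng) for _ in range(n_grid)]
                     for _ in range(n_neurons)]
            lecs = [[sample_lec_spec(rng) for _ in range(n_lec)]
                    for _ in range(n_neurons)]
        if scale is None:
            scale = np.ones(n_neurons)
        return cls(grids, lecs, gain_pA, np.asarray(scale, float), identical)


def total_afferent_current(neuron: int, x, y, bank: AfferentBank):
    """Total afferent current (pA) onto ``neuron`` at position (x, y).

    gain * scale * (mean grid drive + mean LEC drive) / 2.
    """
    if not 0 <= neuron < bank.n_neurons:
        raise IndexError(f"unknown neuron {neuron}")
    g = np.mean([grid_current(x, y, s) for s in bank.grid_specs[neuron]],
                axis=0)
    l = np.mean([lec_current(x, y, s) for s in bank.lec_specs[neuron]],
                axis=0)
    return bank.gain_pA * bank.scale[neuron] * 0.5 * (g + l)


def afferent_current_matrix(bank: AfferentBank, trajectory: Trajectory,
                            dtype=np.float32) -> np.ndarray:
    """Per-neuron afferent current time series (n_neurons x n_ms, pA).

    In identical mode the normalized drive is computed once and shared;
    per-neuron gains/scales still apply.
    """
    x, y = trajectory.x_m, trajectory.y_m
    if bank.identical:
        g = np.mean([grid_current(x, y, s) for s in bank.grid_specs[0]],
                    axis=0)
        l = np.mean([lec_current(x, y, s) for s in bank.lec_specs[0]],
                    axis=0)
        drive = 0.5 * (g + l)
        out = (bank.gain_pA * bank.scale[:, None] * drive[None, :])
    else:
        out = np.empty((bank.n_neurons, x.size))
        for n in range(bank.n_neurons):
            out[n] = total_afferent_current(n, x, y, bank)
    return np.ascontiguousarray(out, dtype=dtype)
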