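"""Firing-rate estimation, spatial maps and channel-decorrelation metrics.

Channel decorrelation is quantified from one arena traversal: the
instantaneous firing rate of every granule cell (binarized spike trains
convolved with a Gaussian kernel, default sigma 50 ms for correlations,
2 s for display maps), pairwise Pearson correlations between the rate
arrays of all cell pairs (the output-correlation matrix), and matching
correlations between the total afferent currents (the input-correlation
matrix).  Knockout impact is the per-cell rate difference

    dF = F_knockout - F_base            (Hz)

and the per-pair percentage change in output correlation

    dR = 100 (R_knockout - R_base) / R_base,

with pairs whose base correlation is within ``EPS_BASE_CORRELATION`` of
zero flagged undefined and excluded (their count is always reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "RateSeries", "RateMap", "CorrelationBundle",
    "overall_rate", "instantaneous_rate", "peak_rate",
    "output_correlation_matrix", "input_correlation_matrix",
    "lower_triangle", "delta_firing", "delta_correlation",
    "delta_correlation_matrix", "bin_by_input_correlation",
    "spatial_rate_map", "EPS_BASE_CORRELATION",
]

EPS_BASE_CORRELATION = 0.01
SIGMA_CORRELATION_MS = 50.0
SIGMA_DISPLAY_MS = 2000.0


@dataclass
class RateSeries:
    """Instantaneous firing rate (Hz) on a uniform time base."""

    dt_ms: float
    rate_hz: np.ndarray
    sigma_ms: float

    def __post_init__(self) -> None:
        self.rate_hz = np.asarray(self.rate_hz, dtype=float)

    @property
    def spike_count(self) -> float:
        """Time integral of the rate (kernel is normalized)."""
        return float(np.sum(self.rate_hz) * self.dt_ms * 1e-3)


def overall_rate(spike_times_ms: np.ndarray, duration_s: float) -> float:
    """Mean rate: spike count over the traversal period (Hz)."""
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    return np.asarray(spike_times_ms).size / duration_s


def instantaneous_rate(spike_times_ms: np.ndarray, duration_s: float,
                       sigma_ms: float = SIGMA_CORRELATION_MS,
                       dt_ms: float = 1.0) -> RateSeries:
    """Gaussian-smoothed rate from a binarized spike sequence.

    The kernel is normalized so the time integral of the returned series
    equals the spike count (reflected boundaries preserve total mass).
    """
    if sigma_ms <= 0 or dt_ms <= 0:
        raise ValueError("sigma and dt must be > 0")
    n = int(round(duration_s * 1e3 / dt_ms))
    counts = np.zeros(n)
    idx = np.asarray(spike_times_ms / dt_ms, dtype=int)
    idx = idx[(idx >= 0) & (idx < n)]
    np.add.at(counts, idx, 1.0)
    smoothed = gaussian_filter1d(counts, sigma_ms / dt_ms, mode="reflect")
    return RateSeries(dt_ms, smoothed / (dt_ms * 1e-3), sigma_ms)


def peak_rate(spike_times_ms: np.ndarray, duration_s: float,
              sigma_ms: float = SIGMA_DISPLAY_MS) -> float:
    """Peak of the (smoothed) instantaneous rate over the traversal."""
    rs = instantaneous_rate(spike_times_ms, duration_s, sigma_ms=sigma_ms)
    return float(np.max(rs.rate_hz))


def _corrcoef_flagged(arrays: np.ndarray) -> np.ndarray:
    """Pearson matrix with zero-variance rows flagged as NaN."""
    arrays = np.asarray(arrays, dtype=float)
    sd = arrays.std(axis=1)
    ok = sd > 0
    n = arrays.shape[0]
    out = np.full((n, n), np.nan)
    if ok.sum() >= 2:
        # enforce exact symmetry (BLAS products are symmetric only to the
        # last ulp) and clip the tiny excursions beyond +/-1 that corrcoef
        # produces on poorly conditioned (low-variance) rows
        sub = np.corrcoef(arrays[ok])
        sub = np.clip(0.5 * (sub + sub.T), -1.0, 1.0)
        out[np.ix_(ok, ok)] = sub
    np.fill_diagonal(out, 1.0)
    return out


def output_correlation_matrix(rates: Sequence[RateSeries]) -> np.ndarray:
    """Pairwise Pearson correlations between instantaneous-rate arrays.

    Symmetric with unit diagonal; pairs involving a zero-variance
    (silent or constant) series are NaN and excluded downstream.
    """
    lengths = {r.rate_hz.size for r in rates}
    dts = {r.dt_ms for r in rates}
    if len(lengths) != 1 or len(dts) != 1:
        raise ValueError("rate series must share length and sampling")
    return _corrcoef_flagged(np.stack([r.rate_hz for r in rates]))


def input_correlation_matrix(currents: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations between afferent-current arrays."""
    return _corrcoef_flagged(np.asarray(currents, dtype=float))


def lower_triangle(matrix: np.ndarray, drop_nan: bool = True) -> np.ndarray:
    """Lower-triangle entries (i > j) as a vector."""
    m = np.asarray(matrix)
    vals = m[np.tril_indices_from(m, k=-1)]
    return vals[np.isfinite(vals)] if drop_nan else vals


def delta_firing(f_base_hz: float, f_vkm_hz: float) -> float:
    """Knockout impact on the overall rate: plain difference (Hz)."""
    return f_vkm_hz - f_base_hz


def delta_correlation(r_base: float, r_vkm: float,
                      eps: float = EPS_BASE_CORRELATION) -> float:
    """Percentage change of one pairwise correlation after knockout.

    NaN (undefined) when |r_base| < eps -- the percentage explodes for
    near-zero bases -- or when either value is undefined.
    """
    if not (np.isfinite(r_base) and np.isfinite(r_vkm)) or abs(r_base) < eps:
        return float("nan")
    return 100.0 * (r_vkm - r_base) / r_base


def delta_correlation_matrix(r_base: np.ndarray, r_vkm: np.ndarray,
                             eps: float = EPS_BASE_CORRELATION
                             ) -> Tuple[np.ndarray, int]:
    """Elementwise dR (%) with the count of excluded near-zero pairs."""
    r_base = np.asarray(r_base, float)
    r_vkm = np.asarray(r_vkm, float)
    if r_base.shape != r_vkm.shape:
        raise ValueError("matrices must align")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (r_vkm - r_base) / r_base
    bad = (~np.isfinite(r_base)) | (~np.isfinite(r_vkm)) | (np.abs(r_base) < eps)
    out[bad] = np.nan
    tri = np.tril_indices_from(r_base, k=-1)
    n_excluded = int(np.sum(bad[tri]))
    return out, n_excluded


@dataclass
class CorrelationBundle:
    """Input/output correlation matrices for one network condition."""

    output: np.ndarray
    input: np.ndarray

    def __post_init__(self) -> None:
        for m in (self.output, self.input):
            if m.shape[0] != m.shape[1]:
                raise ValueError("correlation matrices must be square")
        if self.output.shape != self.input.shape:
            raise ValueError("input/output matrices must align")

    @property
    def output_pairs(self) -> np.ndarray:
        return lower_triangle(self.output)

    @property
    def input_pairs(self) -> np.ndarray:
        return lower_triangle(self.input)


def bin_by_input_correlation(bundle: CorrelationBundle,
                             bin_width: float = 0.1,
                             values: Optional[np.ndarray] = None
                             ) -> List[Dict[str, float]]:
    """Mean +/- SEM of output correlation (or dR) per input-correlation bin.

    Bins tile [-1, 1] with ``bin_width``; empty bins are omitted.  With
    identical afferents every pair collapses into the single bin at 1.
    ``values`` overrides the binned quantity (e.g. a dR matrix).
    """
    tri = np.tril_indices_from(bundle.input, k=-1)
    x = bundle.input[tri]
    y = bundle.output[tri] if values is None else np.asarray(values)[tri]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    edges = np.arange(-1.0, 1.0 + bin_width, bin_width)
    # values exactly at the top edge (input correlation 1) stay in the last bin
    which = np.clip(np.digitize(x, edges) - 1, 0, edges.size - 2)
    out = []
    for b in range(edges.size - 1):
        sel = which == b
        n = int(sel.sum())
        if n == 0:
            continue
        vals = y[sel]
        out.append({
            "bin_center": float(0.5 * (edges[b] + edges[b + 1])),
            "mean": float(vals.mean()),
            "sem": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
            "n": n,
        })
    return out


@dataclass
class RateMap:
    """Occupancy-weighted mean rate per spatial bin; unvisited bins NaN."""

    rate_hz: np.ndarray
    occupancy_s: np.ndarray

    @property
    def visited(self) -> np.ndarray:
        return self.occupancy_s > 0


def spatial_rate_map(rate: RateSeries, trajectory, n_bins: int = 50
                     ) -> RateMap:
    """Overlay a (smooth) rate series on the temporally aligned positions."""
    x, y = trajectory.x_m, trajectory.y_m
    if rate.rate_hz.size != x.size:
        raise ValueError("rate series and trajectory must align")
    col = np.minimum((x * n_bins).astype(int), n_bins - 1)
    row = np.minimum((y * n_bins).astype(int), n_bins - 1)
    flat = row * n_bins + col
    occupancy = np.bincount(flat, minlength=n_bins * n_bins)
    total = np.bincount(flat, weights=rate.rate_hz, minlength=n_bins * n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = total / occupancy
    dt_s = rate.dt_ms * 1e-3
    return RateMap(mean.reshape(n_bins, n_bins),
                   occupancy.reshape(n_bins, n_bins) * dt_s)
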