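"""Rate estimation, correlation matrices and knockout deltas."""

import numpy as np
import pytest

from dgnet.afferents import generate_trajectory, grid_current, sample_grid_spec
from dgnet.analysis import (CorrelationBundle, RateSeries,
                            bin_by_input_correlation, delta_correlation,
                            delta_correlation_matrix, delta_firing,
                            input_correlation_matrix, instantaneous_rate,
                            lower_triangle, output_correlation_matrix,
                            overall_rate, spatial_rate_map)


def test_overall_rate_is_count_over_duration():
    assert overall_rate(np.arange(4000.0), 1000.0) == 4.0
    assert overall_rate(np.array([]), 1000.0) == 0.0
    with pytest.raises(ValueError):
        overall_rate(np.array([]), 0.0)


def test_instantaneous_rate_conserves_spike_count():
    rng = np.random.default_rng(0)
    spikes = np.sort(rng.uniform(1000.0, 59000.0, size=300))
    for sigma in (50.0, 2000.0):
        rs = instantaneous_rate(spikes, 60.0, sigma_ms=sigma)
        assert np.all(rs.rate_hz >= 0.0)
        assert rs.spike_count == pytest.approx(300.0, rel=1e-3)


def test_single_spike_gives_unimodal_bump():
    rs = instantaneous_rate(np.array([5000.0]), 10.0, sigma_ms=50.0)
    peak = int(np.argmax(rs.rate_hz))
    assert abs(peak - 5000) <= 1
    assert np.all(np.diff(rs.rate_hz[:peak]) >= -1e-12)
    assert np.all(np.diff(rs.rate_hz[peak:]) <= 1e-12)


def test_kernel_width_changes_pairwise_correlation():
    """The smoothing scale matters: two trains that interleave on a fast
    time scale decorrelate at sigma = 50 ms but merge at sigma = 2 s."""
    a = np.arange(500.0, 60000.0, 400.0)         # regular train
    b = a + 200.0                                 # antiphase partner
    r = {}
    for sigma in (50.0, 2000.0):
        ra = instantaneous_rate(a, 60.0, sigma_ms=sigma)
        rb = instantaneous_rate(b, 60.0, sigma_ms=sigma)
        r[sigma] = np.corrcoef(ra.rate_hz, rb.rate_hz)[0, 1]
    assert r[50.0] < 0.0 < r[2000.0]
    assert abs(r[50.0] - r[2000.0]) > 0.5


def _series(arr):
    return RateSeries(1.0, np.asarray(arr, float), 50.0)


def test_output_correlations_identical_and_mirrored_series():
    x = np.sin(np.linspace(0.0, 20.0, 500)) + 1.5
    m = output_correlation_matrix([_series(x), _series(x),
                                   _series(2.0 * x.mean() - x)])
    assert m[0, 1] == pytest.approx(1.0)
    assert m[0, 2] == pytest.approx(-1.0)
    assert np.allclose(m, m.T)
    assert np.all(np.diag(m) == 1.0)


def test_independent_series_concentrate_near_zero():
    rng = np.random.default_rng(5)
    series = [_series(rng.normal(size=20000)) for _ in range(6)]
    vals = lower_triangle(output_correlation_matrix(series))
    assert np.max(np.abs(vals)) < 0.05


def test_zero_variance_series_flagged_not_propagated():
    x = np.sin(np.linspace(0.0, 20.0, 500))
    m = output_correlation_matrix([_series(x), _series(np.zeros(500))])
    assert np.isnan(m[0, 1])
    assert m[0, 0] == 1.0
    assert lower_triangle(m).size == 0


def test_input_correlation_scale_invariance():
    rng = np.random.default_rng(2)
    base = rng.normal(size=(3, 1000)) + 5.0
    m1 = input_correlation_matrix(base)
    scaled = base.copy()
    scaled[1] *= 7.3
    m2 = input_correlation_matrix(scaled)
    np.testing.assert_allclose(m1, m2, atol=1e-12)


def test_delta_firing_is_plain_difference():
    assert delta_firing(6.0, 9.0) == 3.0
    assert delta_firing(6.0, 6.0) == 0.0


def test_delta_correlation_percentage_and_near_zero_guard():
    assert delta_correlation(0.5, 0.25) == pytest.approx(-50.0)
    assert delta_correlation(0.4, 0.4) == 0.0
    assert np.isnan(delta_correlation(0.005, 0.5))

    base = np.array([[1.0, 0.5, 0.004], [0.5, 1.0, -0.2],
                     [0.004, -0.2, 1.0]])
    after = np.array([[1.0, 0.25, 0.5], [0.25, 1.0, -0.1],
                      [0.5, -0.1, 1.0]])
    dr, excluded = delta_correlation_matrix(base, after)
    assert dr[1, 0] == pytest.approx(-50.0)
    assert dr[2, 1] == pytest.approx(-50.0)
    assert np.isnan(dr[2, 0]) and excluded == 1
    # pair order does not matter: the matrix stays symmetric
    assert dr[1, 0] == dr[0, 1]


def test_binned_summary_matches_hand_computation():
    out = np.eye(4)
    inp = np.eye(4)
    pairs = [((1, 0), 0.62, 0.30), ((2, 0), 0.68, 0.20),
             ((2, 1), 0.95, 0.70), ((3, 0), 1.0, 0.80)]
    for (i, j), ic, oc in pairs:
        inp[i, j] = inp[j, i] = ic
        out[i, j] = out[j, i] = oc
    bundle = CorrelationBundle(out, inp)
    summary = bin_by_input_correlation(bundle, bin_width=0.1)
    by_center = {round(b["bin_center"], 2): b for b in summary}
    b6 = by_center[0.65]  # pairs at input correlation 0.62 and 0.68
    assert b6["n"] == 2 and b6["mean"] == pytest.approx(0.25)
    assert b6["sem"] == pytest.approx(np.std([0.3, 0.2], ddof=1) / np.sqrt(2))
    b9 = by_center[0.95]  # the 0.95 and the exactly-1.0 pair share the top bin
    assert b9["n"] == 2 and b9["mean"] == pytest.approx(0.75)


def test_identical_inputs_collapse_to_single_bin():
    out = np.full((5, 5), 0.8)
    np.fill_diagonal(out, 1.0)
    bundle = CorrelationBundle(out, np.ones((5, 5)))
    summary = bin_by_input_correlation(bundle)
    assert len(summary) == 1
    assert summary[0]["n"] == 10
    assert summary[0]["mean"] == pytest.approx(0.8)


def test_rate_map_flat_field_and_conservation():
    traj = generate_trajectory(20.0, seed=6)
    rs = RateSeries(1.0, np.full(traj.n_samples, 3.0), 2000.0)
    rmap = spatial_rate_map(rs, traj, n_bins=10)
    visited = rmap.visited
    assert np.allclose(rmap.rate_hz[visited], 3.0)
    # map-aggregated activity equals time-aggregated activity
    total_map = np.nansum(rmap.rate_hz[visited] * rmap.occupancy_s[visited])
    total_time = np.sum(rs.rate_hz) * 1e-3
    assert total_map == pytest.approx(total_time, rel=1e-9)
    with pytest.raises(ValueError):
        spatial_rate_map(RateSeries(1.0, np.zeros(10), 2000.0), traj)


def test_rate_map_tracks_grid_field_peaks():
    traj = generate_trajectory(300.0, seed=8)
    spec = sample_grid_spec(np.random.default_rng(4))
    drive = grid_current(traj.x_m, traj.y_m, spec)
    rmap = spatial_rate_map(RateSeries(1.0, 10.0 * drive, 2000.0), traj,
                            n_bins=20)
    r, c = np.unravel_index(np.nanargmax(np.where(rmap.visited,
                                                  rmap.rate_hz, -1.0)),
                            rmap.rate_hz.shape)
    x, y = (c + 0.5) / 20, (r + 0.5) / 20
    # the hottest map bin sits on a high-psi region of the driving field
    assert grid_current(x, y, spec) > 0.8
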