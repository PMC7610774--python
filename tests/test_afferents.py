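"""Trajectory, grid/LEC drives and afferent-bank invariants."""

import numpy as np
import pytest

from dgnet.afferents import (AfferentBank, Arena, GridCellSpec, LECCellSpec,
                             afferent_current_matrix, generate_trajectory,
                             grid_current, lec_current, sample_grid_spec,
                             sample_lec_spec, scale_drive_by_geometry,
                             total_afferent_current)


@pytest.fixture(scope="module")
def walk():
    return generate_trajectory(20.0, seed=42)


def test_trajectory_respects_arena_and_speed_band(walk):
    assert walk.arena.contains(walk.x_m, walk.y_m)
    steps = np.hypot(np.diff(walk.x_m), np.diff(walk.y_m)) * 1e3  # mm/ms
    assert steps.min() >= 2.5 - 1e-9
    assert steps.max() <= 3.5 + 1e-9


def test_trajectory_reproducible_and_starts_near_center():
    a = generate_trajectory(1.0, seed=9)
    b = generate_trajectory(1.0, seed=9)
    np.testing.assert_array_equal(a.x_m, b.x_m)
    assert np.hypot(a.x_m[0] - 0.5, a.y_m[0] - 0.5) < 0.005


def test_long_traversal_covers_the_arena():
    """~1000 s suffices to visit essentially every LEC tile."""
    traj = generate_trajectory(1000.0, seed=1)
    col = np.minimum((traj.x_m * 5).astype(int), 4)
    row = np.minimum((traj.y_m * 5).astype(int), 4)
    visited = len(set(zip(row.tolist(), col.tolist())))
    assert visited >= 24


def test_grid_field_peaks_at_offset_and_stays_normalized():
    rng = np.random.default_rng(0)
    xs = np.linspace(0.0, 1.0, 200)
    X, Y = np.meshgrid(xs, xs)
    mins = []
    for _ in range(20):
        spec = sample_grid_spec(rng)
        assert grid_current(spec.x0_m, spec.y0_m, spec) == pytest.approx(1.0)
        field = grid_current(X, Y, spec)
        assert field.min() >= 0.0 and field.max() <= 1.0 + 1e-12
        mins.append(field.min())
    assert min(mins) < 1e-3  # the three-cosine sum reaches its -1.5 floor


def test_grid_field_has_sixfold_rotational_symmetry():
    rng = np.random.default_rng(3)
    spec = sample_grid_spec(rng)
    pts = rng.uniform(0.2, 0.8, size=(50, 2))
    c, s = np.cos(np.pi / 3), np.sin(np.pi / 3)
    dx, dy = pts[:, 0] - spec.x0_m, pts[:, 1] - spec.y0_m
    rx = spec.x0_m + c * dx - s * dy
    ry = spec.y0_m + s * dx + c * dy
    np.testing.assert_allclose(grid_current(rx, ry, spec),
                               grid_current(pts[:, 0], pts[:, 1], spec),
                               atol=1e-9)


def test_lec_tiles_partition_the_arena():
    rng = np.random.default_rng(7)
    spec = sample_lec_spec(rng)
    # tile membership at interior points
    for r in range(5):
        for col in range(5):
            x, y = (col + 0.5) / 5, (r + 0.5) / 5
            assert lec_current(x, y, spec) == spec.tile_array[r, col]
    # mean drive over a dense grid equals the active-tile fraction
    xs = np.linspace(0.0, 0.999, 400)
    X, Y = np.meshgrid(xs, xs)
    assert lec_current(X, Y, spec).mean() == pytest.approx(
        spec.tile_array.mean(), abs=1e-3)


def test_lec_specs_differ_across_seeds():
    a = sample_lec_spec(np.random.default_rng(1))
    b = sample_lec_spec(np.random.default_rng(2))
    assert a.tiles != b.tiles


def test_drive_scaling_law():
    assert scale_drive_by_geometry(63.0) == 1.0
    assert scale_drive_by_geometry(31.5) == pytest.approx(0.25)
    d = [scale_drive_by_geometry(x) for x in (2.0, 9.0, 63.0)]
    assert d[0] <= d[1] < d[2]
    assert d[0] > 0
    with pytest.raises(ValueError):
        scale_drive_by_geometry(0.0)


def test_identical_bank_yields_unit_input_correlations(walk):
    bank = AfferentBank.build(6, gain_pA=100.0, identical=True, seed=11)
    m = afferent_current_matrix(bank, walk)
    for row in m[1:]:
        np.testing.assert_array_equal(row, m[0])
    corr = np.corrcoef(m.astype(float))
    np.testing.assert_allclose(corr, 1.0, atol=1e-12)


def test_heterogeneous_bank_spans_subunity_correlations(walk):
    bank = AfferentBank.build(8, gain_pA=100.0, identical=False, seed=11)
    m = afferent_current_matrix(bank, walk)
    corr = np.corrcoef(m.astype(float))
    off = corr[np.tril_indices(8, k=-1)]
    assert off.max() < 0.999
    assert off.max() - off.min() > 0.05


def test_afferent_current_is_linear_in_gain(walk):
    b1 = AfferentBank.build(3, gain_pA=50.0, identical=False, seed=4)
    b2 = AfferentBank.build(3, gain_pA=100.0, identical=False, seed=4)
    x, y = walk.x_m[:100], walk.y_m[:100]
    i1 = total_afferent_current(1, x, y, b1)
    i2 = total_afferent_current(1, x, y, b2)
    np.testing.assert_allclose(i2, 2.0 * i1, rtol=1e-12)
    with pytest.raises(IndexError):
        total_afferent_current(5, x, y, b1)


def test_zero_gain_means_zero_current(walk):
    bank = AfferentBank.build(2, gain_pA=0.0, identical=True, seed=0)
    assert np.all(afferent_current_matrix(bank, walk) == 0.0)
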