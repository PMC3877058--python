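"""FFT correlation against the direct oracle, rotations and recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pockalign.errors import GridError
from pockalign.grid_builder import grid_from_points
from pockalign.superposer import (RotationSample,
                                  brute_force_correlation, correlate_fft,
                                  cyclic_correlation_fft, euler_matrix,
                                  find_best_superposition, pad_to_common,
                                  rotation_lattice, rotate_template)


def _direct_all_shifts(fa, ga):
    out = np.zeros(fa.shape)
    for t in np.ndindex(fa.shape):
        out[t] = np.sum(fa * np.roll(ga, [-x for x in t], axis=(0, 1, 2)))
    return out


# --- rotations --------------------------------------------------------------

def test_identity_rotation_is_noop(dense_pocket):
    rotated = rotate_template(dense_pocket, RotationSample(0, 0, 0))
    np.testing.assert_allclose(rotated.surface_coords,
                               dense_pocket.surface_coords, atol=1e-12)
    np.testing.assert_allclose(rotated.sphere_centers,
                               dense_pocket.sphere_centers, atol=1e-12)


def test_z180_flips_xy_about_centroid(dense_pocket):
    rotated = rotate_template(dense_pocket, RotationSample(0, 0, 180))
    c = dense_pocket.sphere_centroid
    rel = dense_pocket.surface_coords - c
    expect = np.column_stack([-rel[:, 0], -rel[:, 1], rel[:, 2]]) + c
    np.testing.assert_allclose(rotated.surface_coords, expect, atol=1e-9)


def test_rotation_composition_matches_matrix_product():
    r20 = euler_matrix(20, 0, 0)
    r40 = euler_matrix(40, 0, 0)
    np.testing.assert_allclose(r20 @ r20, r40, atol=1e-9)
    # general composition oracle
    a = euler_matrix(20, 40, 60)
    assert np.allclose(a @ a.T, np.eye(3), atol=1e-12)
    assert np.isclose(np.linalg.det(a), 1.0)


def test_rotation_lattice_size():
    assert len(rotation_lattice(20)) == 18 ** 3
    assert len(rotation_lattice(90)) == 4 ** 3


# --- FFT vs direct correlation ---------------------------------------------

def test_zero_template_gives_zero_correlation():
    f = np.ones((4, 4, 4))
    g = np.zeros((4, 4, 4))
    c = cyclic_correlation_fft(f, g)
    np.testing.assert_allclose(c, 0.0, atol=1e-12)


def test_single_cell_match():
    f = np.zeros((5, 5, 5))
    g = np.zeros((5, 5, 5))
    f[1, 2, 3] = 1.0
    g[1, 2, 3] = 1.0
    c = cyclic_correlation_fft(f, g)
    assert c[0, 0, 0] == pytest.approx(1.0, abs=1e-9)
    assert np.sum(np.abs(c) > 1e-9) == 1


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_fft_equals_direct_on_random_grids(seed):
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(3, 9, size=3))
    fa = rng.normal(size=shape)
    ga = rng.normal(size=shape)
    c_fft = cyclic_correlation_fft(fa, ga)
    c_direct = _direct_all_shifts(fa, ga)
    scale = np.max(np.abs(c_direct)) or 1.0
    assert np.max(np.abs(c_fft - c_direct)) / scale < 1e-6


def test_brute_force_shift_wraps_cyclically():
    rng = np.random.default_rng(1)
    fa = rng.normal(size=(6, 6, 6))
    ga = rng.normal(size=(6, 6, 6))
    fp, gp, shape = pad_to_common(fa, ga)
    a = brute_force_correlation(fa, ga, (2, 3, 4))
    b = brute_force_correlation(fa, ga, (2 + shape[0], 3, 4))
    assert a == pytest.approx(b, rel=1e-12)


def test_autocorrelation_peak_at_zero_lag():
    rng = np.random.default_rng(4)
    fa = rng.normal(size=(7, 7, 7))
    c = cyclic_correlation_fft(fa, fa)
    assert c[0, 0, 0] == pytest.approx(np.sum(fa ** 2), rel=1e-9)
    assert np.argmax(c) == 0  # Cauchy-Schwarz


def test_correlate_fft_pads_grids_of_unequal_dims(dense_pocket):
    f = grid_from_points(dense_pocket.surface_coords,
                         dense_pocket.sphere_centers)
    g = grid_from_points(dense_pocket.surface_coords[:10],
                         dense_pocket.sphere_centers[:3])
    c = correlate_fft(f, g)
    assert all(cs >= fs + gs for cs, fs, gs in
               zip(c.shape, f.values.shape, g.values.shape))
    # spot-check a few shifts against the direct oracle
    rng = np.random.default_rng(0)
    for _ in range(5):
        t = tuple(int(rng.integers(0, s)) for s in c.shape)
        assert c[t] == pytest.approx(
            brute_force_correlation(f, g, t) + 1e-30, rel=1e-6, abs=1e-6)


# --- best-superposition search ---------------------------------------------

def test_self_superposition_is_identity(dense_pocket):
    res = find_best_superposition(dense_pocket, dense_pocket, angle_step=90)
    assert (res.rotation.alpha, res.rotation.beta, res.rotation.gamma) \
        == (0, 0, 0)
    f = grid_from_points(dense_pocket.surface_coords,
                         dense_pocket.sphere_centers)
    assert res.correlation == pytest.approx(np.sum(f.values ** 2), rel=1e-9)
    # recovered transform is (numerically) the identity
    pts = dense_pocket.surface_coords
    np.testing.assert_allclose(res.transform.apply(pts), pts, atol=1e-6)


def test_reported_correlation_equals_direct_product_sum(dense_pocket):
    res = find_best_superposition(dense_pocket, dense_pocket, angle_step=180)
    rotated = rotate_template(dense_pocket, res.rotation)
    f = grid_from_points(dense_pocket.surface_coords,
                         dense_pocket.sphere_centers)
    g = grid_from_points(rotated.surface_coords, rotated.sphere_centers)
    fp, gp, shape = pad_to_common(f, g, shape=None)
    # same shift in the common box (modulo wrap)
    t = tuple(s % n for s, n in zip(res.shift, shape))
    direct = float(np.sum(fp * np.roll(gp, [-x for x in t], axis=(0, 1, 2))))
    assert res.correlation == pytest.approx(direct, rel=1e-6)


def test_coarse_lattice_membership(dense_pocket):
    res = find_best_superposition(dense_pocket, dense_pocket, angle_step=180)
    for angle in (res.rotation.alpha, res.rotation.beta, res.rotation.gamma):
        assert angle in (0.0, 180.0)


def test_shift_covariance_under_integer_translation(dense_pocket):
    """Moving the template by whole cells changes the shift, not the max."""
    from dataclasses import replace as dc_replace
    from pockalign.pocket_model import PocketModel

    k = np.array([2.0, 0.0, 0.0])
    moved = PocketModel(
        sphere_centers=dense_pocket.sphere_centers + k,
        pocket_box=(dense_pocket.pocket_box[0] + k,
                    dense_pocket.pocket_box[1] + k),
        ligand_box=(dense_pocket.ligand_box[0] + k,
                    dense_pocket.ligand_box[1] + k),
        surface_atoms=[dc_replace(a, pos=a.pos + k)
                       for a in dense_pocket.surface_atoms],
        structure=dense_pocket.structure)
    r0 = find_best_superposition(dense_pocket, dense_pocket, angle_step=180)
    r1 = find_best_superposition(dense_pocket, moved, angle_step=180)
    assert r1.correlation == pytest.approx(r0.correlation, rel=1e-9)
    # the real-space transforms agree: the moved template maps back
    pts = dense_pocket.surface_coords
    np.testing.assert_allclose(r1.transform.apply(pts + k),
                               r0.transform.apply(pts), atol=1e-6)


def test_empty_pocket_raises(dense_pocket):
    from pockalign.pocket_model import PocketModel
    empty = PocketModel(sphere_centers=np.zeros((0, 3)),
                        pocket_box=(np.zeros(3), np.zeros(3)),
                        ligand_box=(np.zeros(3), np.zeros(3)),
                        surface_atoms=[])
    with pytest.raises(GridError):
        find_best_superposition(dense_pocket, empty)
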