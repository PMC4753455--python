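import numpy as np
import pytest

from hapi3d.transforms import (Affine2D, Affine3D, CompositeTransform, FFD3D,
                               Rigid3D, bspline_basis_matrix, euler_zyx_matrix,
                               load_transform, save_transform)


def _pts2(rng, n=20):
    return rng.uniform(-100, 100, (n, 2))


def _pts3(rng, n=20):
    return rng.uniform(-100, 100, (n, 3))


def test_affine2d_compose_matches_nested_apply(rng):
    a = Affine2D(np.array([[1.1, 0.05], [-0.02, 0.95]]), [3.0, -2.0],
                 center=[10.0, 5.0])
    b = Affine2D(np.array([[0.98, -0.1], [0.1, 1.02]]), [-1.0, 4.0])
    pts = _pts2(rng)
    assert np.allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)))


def test_affine2d_inverse_round_trip(rng):
    a = Affine2D(np.array([[1.2, 0.1], [0.0, 0.9]]), [5.0, -3.0], center=[7.0, 7.0])
    pts = _pts2(rng)
    assert np.allclose(a.inverse().apply(a.apply(pts)), pts)
    assert np.allclose(a.apply(a.inverse().apply(pts)), pts)


def test_affine_singular_matrix_rejected():
    with pytest.raises(ValueError):
        Affine2D(np.array([[1.0, 2.0], [2.0, 4.0]]), [0, 0])
    with pytest.raises(ValueError):
        Affine3D(np.zeros((3, 3)), [0, 0, 0])


def test_center_semantics():
    # pure rotation about the center leaves the center fixed
    ang = np.deg2rad(30)
    m = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    c = np.array([50.0, 25.0])
    a = Affine2D(m, [0.0, 0.0], center=c)
    assert np.allclose(a.apply(c[None]), c[None])


def test_euler_zyx_matrix_is_rotation():
    m = euler_zyx_matrix([10.0, -5.0, 3.0])
    assert np.allclose(m @ m.T, np.eye(3), atol=1e-12)
    assert np.isclose(np.linalg.det(m), 1.0)
    assert np.allclose(euler_zyx_matrix([0, 0, 0]), np.eye(3))


def test_rigid3d_inverse_round_trip(rng):
    r = Rigid3D([12.0, -4.0, 7.0], [30.0, -10.0, 5.0], center=[100.0, 80.0, 60.0])
    pts = _pts3(rng)
    assert np.allclose(r.inverse().apply(r.apply(pts)), pts)


def test_affine3d_compose_with_rigid(rng):
    r = Rigid3D([5.0, 0.0, -3.0], [10.0, 0.0, -5.0])
    a = Affine3D(np.diag([1.05, 0.95, 1.0]), [1.0, 2.0, 3.0])
    pts = _pts3(rng)
    assert np.allclose(a.compose(r).apply(pts), a.apply(r.apply(pts)))


def test_bspline_basis_partition_of_unity():
    basis = bspline_basis_matrix(np.linspace(0, 200, 57), 200.0, 8)
    assert basis.shape == (57, 8)
    assert np.allclose(basis.sum(axis=1), 1.0)
    assert (basis >= 0).all()
    with pytest.raises(ValueError):
        bspline_basis_matrix(np.array([0.0]), 100.0, 3)


def test_ffd_zero_lattice_is_bulk(rng):
    bulk = Affine3D(np.diag([1.02, 0.98, 1.0]), [5.0, -3.0, 2.0])
    ffd = FFD3D.zero((200.0, 150.0, 100.0), (5, 5, 4), bulk=bulk)
    pts = rng.uniform(0, 100, (15, 3))
    assert np.allclose(ffd.apply(pts), bulk.apply(pts))
    u = ffd.displacement_on_grid((8, 6, 4), (25.0, 25.0, 25.0))
    assert np.allclose(u, 0.0)


def test_ffd_grid_and_pointwise_displacement_agree(rng):
    grid = rng.normal(0, 10.0, (5, 4, 4, 3))
    ffd = FFD3D(grid, (200.0, 150.0, 100.0))
    shape, vox = (6, 5, 4), (200.0 / 6, 150.0 / 5, 100.0 / 4)
    dense = ffd.displacement_on_grid(shape, vox)
    centers = np.stack(np.meshgrid(*[(np.arange(n) + 0.5) * d
                                     for n, d in zip(shape, vox)],
                                   indexing="ij"), axis=-1).reshape(-1, 3)
    assert np.allclose(ffd.displacement_at(centers), dense.reshape(-1, 3))


def test_ffd_validation():
    with pytest.raises(ValueError):
        FFD3D(np.zeros((3, 4, 4, 3)), (100, 100, 100))  # < 4 per axis
    with pytest.raises(ValueError):
        FFD3D(np.zeros((4, 4, 4, 2)), (100, 100, 100))  # not vectors
    with pytest.raises(ValueError):
        FFD3D(np.zeros((4, 4, 4, 3)), (100, -1, 100))


def test_composite_apply_order(rng):
    a = Affine3D(np.diag([2.0, 1.0, 1.0]), [0.0, 0.0, 0.0])
    b = Affine3D(np.eye(3), [10.0, 0.0, 0.0])
    comp = CompositeTransform([a, b])  # a(b(x))
    pts = _pts3(rng)
    assert np.allclose(comp.apply(pts), a.apply(b.apply(pts)))


@pytest.mark.parametrize("make", [
    lambda: Affine2D(np.array([[1.1, 0.0], [0.05, 0.9]]), [2.0, -7.0],
                     center=[10.0, 20.0]),
    lambda: Rigid3D([4.0, -2.0, 1.0], [10.0, 0.0, -3.0], center=[5.0, 5.0, 5.0]),
    lambda: Affine3D(np.diag([1.05, 0.95, 1.0]), [1.0, 2.0, 3.0]),
    lambda: FFD3D(np.arange(4 * 4 * 4 * 3, dtype=float).reshape(4, 4, 4, 3),
                  (100.0, 100.0, 100.0),
                  Affine3D(np.diag([1.1, 1.0, 1.0]), [0.0, 1.0, 0.0])),
])
def test_save_load_round_trip(tmp_path, rng, make):
    t = make()
    back = load_transform(save_transform(t, tmp_path / "t.json"))
    pts = rng.uniform(0, 90, (10, 3 if not isinstance(t, Affine2D) else 2))
    assert np.allclose(back.apply(pts), t.apply(pts))


def test_save_load_composite(tmp_path, rng):
    comp = CompositeTransform([
        Affine3D(np.diag([1.02, 1.0, 0.98]), [1.0, -1.0, 0.0]),
        Rigid3D([2.0, 0.0, 0.0], [5.0, 0.0, 0.0]),
    ])
    back = load_transform(save_transform(comp, tmp_path / "c.json"))
    pts = rng.uniform(0, 90, (10, 3))
    assert np.allclose(back.apply(pts), comp.apply(pts))
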