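"""Spatial transforms between image/volume world spaces.

All transforms use the *pull-back* (resampling) convention: a transform
estimated by registering a floating image onto a reference maps reference
world coordinates (um) to floating world coordinates, so resampling the
floating image through it yields the aligned image on the reference grid.

Rotations use intrinsic z-y-x Euler angles in degrees. Linear transforms
optionally act about a ``center`` point: ``y = M (x - c) + c + t``.

The elastic transform (:class:`FFD3D`) is a free-form deformation: a
coarse lattice of control-point displacement vectors, interpolated with
cubic B-spline weights, added on top of a bulk affine. It is invertible
only approximately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Affine2D",
    "Rigid3D",
    "Affine3D",
    "FFD3D",
    "CompositeTransform",
    "bspline_basis_matrix",
    "save_transform",
    "load_transform",
]


def _as_matrix(m, n):
    m = np.asarray(m, dtype=float)
    if m.shape != (n, n):
        raise ValueError(f"expected {n}x{n} matrix, got {m.shape}")
    if abs(np.linalg.det(m)) < 1e-8:
        raise ValueError("linear part is singular")
    return m


@dataclass
class Affine2D:
    """2D affine map in coronal-plane world coordinates (um)."""

    matrix: np.ndarray
    translation: np.ndarray
    center: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = _as_matrix(self.matrix, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        self.center = (np.zeros(2) if self.center is None
                       else np.asarray(self.center, dtype=float).reshape(2))

    @classmethod
    def identity(cls) -> "Affine2D":
        return cls(np.eye(2), np.zeros(2))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - self.center) @ self.matrix.T + self.center + self.translation

    def compose(self, inner: "Affine2D") -> "Affine2D":
        """Return the affine ``x -> self(inner(x))``."""
        a1, t1 = self._homogeneous()
        a2, t2 = inner._homogeneous()
        return Affine2D(a1 @ a2, a1 @ t2 + t1)

    def _homogeneous(self):
        """(A, t) with apply(x) = A x + t (center folded in)."""
        t = -self.matrix @ self.center + self.center + self.translation
        return self.matrix, t

    def inverse(self) -> "Affine2D":
        a, t = self._homogeneous()
        ai = np.linalg.inv(a)
        return Affine2D(ai, -ai @ t)

    def to_dict(self) -> dict:
        return {"type": "affine2d", "units": "um",
                "matrix": self.matrix.tolist(),
                "translation": self.translation.tolist(),
                "center": self.center.tolist()}


def euler_zyx_matrix(angles_deg) -> np.ndarray:
    """Rotation matrix for intrinsic z-y-x Euler angles in degrees."""
    az, ay, ax = np.deg2rad(np.asarray(angles_deg, dtype=float))
    cz, sz = np.cos(az), np.sin(az)
    cy, sy = np.cos(ay), np.sin(ay)
    cx, sx = np.cos(ax), np.sin(ax)
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1.0]])
    ry = np.array([[cy, 0, sy], [0, 1.0, 0], [-sy, 0, cy]])
    rx = np.array([[1.0, 0, 0], [0, cx, -sx], [0, sx, cx]])
    return rz @ ry @ rx


@dataclass
class Rigid3D:
    """6-parameter rigid motion: intrinsic z-y-x Euler angles (deg) + translation (um)."""

    rotation_deg: np.ndarray
    translation: np.ndarray
    center: np.ndarray | None = None

    def __post_init__(self):
        self.rotation_deg = np.asarray(self.rotation_deg, dtype=float).reshape(3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = (np.zeros(3) if self.center is None
                       else np.asarray(self.center, dtype=float).reshape(3))

    @classmethod
    def identity(cls, center=None) -> "Rigid3D":
        return cls(np.zeros(3), np.zeros(3), center)

    @property
    def matrix(self) -> np.ndarray:
        return euler_zyx_matrix(self.rotation_deg)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - self.center) @ self.matrix.T + self.center + self.translation

    def as_affine(self) -> "Affine3D":
        return Affine3D(self.matrix, self.translation, self.center)

    def inverse(self) -> "Affine3D":
        return self.as_affine().inverse()

    def to_dict(self) -> dict:
        return {"type": "rigid3d", "units": "um", "angle_convention": "intrinsic z-y-x, degrees",
                "rotation_deg": self.rotation_deg.tolist(),
                "translation": self.translation.tolist(),
                "center": self.center.tolist()}


@dataclass
class Affine3D:
    """3D affine map in world coordinates (um)."""

    matrix: np.ndarray
    translation: np.ndarray
    center: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = _as_matrix(self.matrix, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = (np.zeros(3) if self.center is None
                       else np.asarray(self.center, dtype=float).reshape(3))

    @classmethod
    def identity(cls, center=None) -> "Affine3D":
        return cls(np.eye(3), np.zeros(3), center)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - self.center) @ self.matrix.T + self.center + self.translation

    def _homogeneous(self):
        t = -self.matrix @ self.center + self.center + self.translation
        return self.matrix, t

    def compose(self, inner: "Affine3D | Rigid3D") -> "Affine3D":
        if isinstance(inner, Rigid3D):
            inner = inner.as_affine()
        a1, t1 = self._homogeneous()
        a2, t2 = inner._homogeneous()
        return Affine3D(a1 @ a2, a1 @ t2 + t1)

    def inverse(self) -> "Affine3D":
        a, t = self._homogeneous()
        ai = np.linalg.inv(a)
        return Affine3D(ai, -ai @ t)

    def to_dict(self) -> dict:
        return {"type": "affine3d", "units": "um",
                "matrix": self.matrix.tolist(),
                "translation": self.translation.tolist(),
                "center": self.center.tolist()}


# ---------------------------------------------------------------------------
# Free-form deformation
# ---------------------------------------------------------------------------

def _bspline_weights(u: np.ndarray) -> np.ndarray:
    """Uniform cubic B-spline weights for fractional offsets ``u`` in [0,1).

    Returns an array of shape ``u.shape + (4,)`` (weights of the 4 control
    points supporting each sample); partition of unity holds exactly.
    """
    u = np.asarray(u, dtype=float)
    u2, u3 = u * u, u * u * u
    w = np.empty(u.shape + (4,))
    w[..., 0] = (1 - 3 * u + 3 * u2 - u3) / 6.0
    w[..., 1] = (3 * u3 - 6 * u2 + 4) / 6.0
    w[..., 2] = (-3 * u3 + 3 * u2 + 3 * u + 1) / 6.0
    w[..., 3] = u3 / 6.0
    return w


def bspline_basis_matrix(coords: np.ndarray, extent: float, n_ctrl: int) -> np.ndarray:
    """Dense (len(coords), n_ctrl) cubic B-spline basis over [0, extent].

    The ``n_ctrl`` control points per axis span the domain with
    ``n_ctrl - 3`` knot spans, so every world coordinate in [0, extent]
    has full 4-point support. Rows sum to 1.
    """
    if n_ctrl < 4:
        raise ValueError("need at least 4 control points per axis")
    coords = np.asarray(coords, dtype=float)
    s = np.clip(coords / extent, 0.0, 1.0) * (n_ctrl - 3)
    i = np.minimum(s.astype(int), n_ctrl - 4)
    u = s - i
    w = _bspline_weights(u)
    basis = np.zeros((coords.size, n_ctrl))
    rows = np.arange(coords.size)
    for k in range(4):
        basis[rows, i + k] += w[:, k]
    return basis


@dataclass
class FFD3D:
    """Free-form deformation on a regular control lattice plus a bulk affine.

    ``control_grid`` holds displacement vectors (um) at
    ``(ncx, ncy, ncz, 3)`` lattice sites spanning ``domain_extent`` (the
    reference volume's physical size). The dense displacement field is the
    cubic B-spline interpolation of the lattice; the transform is
    ``x -> bulk(x) + u(x)``. A zero lattice therefore reduces exactly to
    the bulk transform.
    """

    control_grid: np.ndarray
    domain_extent: np.ndarray
    bulk_transform: Affine3D = field(default_factory=Affine3D.identity)
    interpolation_order: int = 3  # cubic B-spline lattice weights

    def __post_init__(self):
        self.control_grid = np.asarray(self.control_grid, dtype=float)
        if self.control_grid.ndim != 4 or self.control_grid.shape[-1] != 3:
            raise ValueError("control_grid must have shape (ncx, ncy, ncz, 3)")
        if min(self.control_grid.shape[:3]) < 4:
            raise ValueError("need >= 4 control points per axis")
        self.domain_extent = np.asarray(self.domain_extent, dtype=float).reshape(3)
        if (self.domain_extent <= 0).any():
            raise ValueError("domain extent must be positive")

    @classmethod
    def zero(cls, domain_extent, grid_shape=(10, 10, 10),
             bulk: Affine3D | None = None) -> "FFD3D":
        grid = np.zeros(tuple(grid_shape) + (3,))
        return cls(grid, domain_extent, bulk or Affine3D.identity())

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.control_grid.shape[:3]

    def axis_bases(self, world_coords: list[np.ndarray]) -> list[np.ndarray]:
        """Per-axis basis matrices for separable field evaluation on a grid."""
        return [bspline_basis_matrix(c, self.domain_extent[a], self.grid_shape[a])
                for a, c in enumerate(world_coords)]

    def displacement_on_grid(self, shape, voxel_size) -> np.ndarray:
        """Dense displacement field (um) at the voxel centers of a grid.

        Separable tensor contraction: cost O(nvox * n_ctrl) per axis.
        """
        coords = [(np.arange(shape[a]) + 0.5) * voxel_size[a] for a in range(3)]
        bx, by, bz = self.axis_bases(coords)
        u = np.tensordot(bx, self.control_grid, axes=(1, 0))       # (nx, ncy, ncz, 3)
        u = np.tensordot(by, u, axes=(1, 1)).transpose(1, 0, 2, 3)  # (nx, ny, ncz, 3)
        u = np.tensordot(bz, u, axes=(1, 2)).transpose(1, 2, 0, 3)  # (nx, ny, nz, 3)
        return u

    def displacement_at(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        out = np.zeros_like(pts)
        bases = [bspline_basis_matrix(pts[:, a], self.domain_extent[a], self.grid_shape[a])
                 for a in range(3)]
        # contract: u_n = sum_{abc} Bx[n,a] By[n,b] Bz[n,c] grid[a,b,c,:]
        g = np.tensordot(bases[0], self.control_grid, axes=(1, 0))  # (n, ncy, ncz, 3)
        g = np.einsum("nb,nbcd->ncd", bases[1], g)
        out = np.einsum("nc,ncd->nd", bases[2], g)
        return out

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return self.bulk_transform.apply(pts) + self.displacement_at(pts)

    def to_dict(self) -> dict:
        return {"type": "ffd3d", "units": "um",
                "grid_shape": list(self.grid_shape),
                "control_grid": self.control_grid.tolist(),
                "domain_extent": self.domain_extent.tolist(),
                "interpolation_order": self.interpolation_order,
                "bulk_transform": self.bulk_transform.to_dict()}


@dataclass
class CompositeTransform:
    """Right-to-left chain: ``apply(x) = t[0](t[1](...t[-1](x)))``."""

    transforms: list

    def apply(self, pts: np.ndarray) -> np.ndarray:
        for t in reversed(self.transforms):
            pts = t.apply(pts)
        return pts

    def to_dict(self) -> dict:
        return {"type": "composite",
                "transforms": [t.to_dict() for t in self.transforms]}


def transform_from_dict(d: dict):
    kind = d["type"]
    if kind == "affine2d":
        return Affine2D(np.array(d["matrix"]), np.array(d["translation"]),
                        np.array(d.get("center", (0, 0))))
    if kind == "rigid3d":
        return Rigid3D(np.array(d["rotation_deg"]), np.array(d["translation"]),
                       np.array(d.get("center", (0, 0, 0))))
    if kind == "affine3d":
        return Affine3D(np.array(d["matrix"]), np.array(d["translation"]),
                        np.array(d.get("center", (0, 0, 0))))
    if kind == "ffd3d":
        return FFD3D(np.array(d["control_grid"]), np.array(d["domain_extent"]),
                     transform_from_dict(d["bulk_transform"]),
                     d.get("interpolation_order", 3))
    if kind == "composite":
        return CompositeTransform([transform_from_dict(t) for t in d["transforms"]])
    raise ValueError(f"unknown transform type {kind!r}")


def save_transform(t, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(t.to_dict(), indent=1))
    return path


def load_transform(path: str | Path):
    return transform_from_dict(json.loads(Path(path).read_text()))
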