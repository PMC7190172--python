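"""Rigid-body transforms between MRI and MEG head coordinates.

A co-registration is a 4x4 homogeneous rigid-body transform mapping MRI
coordinates (mm) into the MEG head coordinate frame.  This module provides
the transform container, composition/inversion, least-squares estimation
from matched landmarks (orthogonal Procrustes / Kabsch), and the
decomposition into the six parameters conventionally reported for head
transforms: translation in mm along x, y, z and rotation in degrees about
x, y, z (pitch, roll, yaw).

Euler convention
----------------
Angles are extrinsic rotations about the fixed x, y, z axes applied in
that order, i.e. ``R = Rz(yaw) @ Ry(roll) @ Rx(pitch)``.  Under this
convention roll is confined to [-90, 90] degrees and the decomposition is
unique away from gimbal lock (|roll| = 90).  The convention is applied
identically to every transform, so statistics comparing two methods'
parameters (e.g. inter-method ICCs) are unaffected by the choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np

__all__ = [
    "RigidTransform",
    "TransformParams",
    "LandmarkFit",
    "TransformError",
    "DegenerateGeometryError",
    "compose",
    "invert",
    "decompose",
    "recompose",
    "fit_landmarks",
]

#: absolute tolerance used for rigidity / round-trip checks (mm, unitless)
RIGID_ATOL = 1e-9


class TransformError(ValueError):
    """Raised for matrices that are not valid rigid-body transforms."""


class DegenerateGeometryError(ValueError):
    """Raised when point geometry cannot constrain a rigid transform."""


@dataclass(frozen=True)
class RigidTransform:
    """A 4x4 homogeneous rigid-body transform (rotation + translation, mm).

    By package convention stored transforms map MRI coordinates into MEG
    head coordinates.  The matrix is validated on construction: the 3x3
    rotation block must be orthonormal with determinant +1 (no scaling,
    no reflection) and the bottom row must be exactly ``(0, 0, 0, 1)``.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.array(self.matrix, dtype=float, copy=True)
        if m.shape != (4, 4):
            raise TransformError(f"expected a 4x4 matrix, got shape {m.shape}")
        if not np.all(np.isfinite(m)):
            raise TransformError("transform matrix contains non-finite values")
        if not np.array_equal(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise TransformError("bottom row must be exactly (0, 0, 0, 1)")
        r = m[:3, :3]
        if np.linalg.norm(r.T @ r - np.eye(3)) > 1e-9:
            raise TransformError("rotation block is not orthonormal (scaling/shear?)")
        if np.linalg.det(r) < 0:
            raise TransformError("rotation block is a reflection (det = -1)")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    # -- basic accessors ---------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        """The 3x3 rotation block."""
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        """The translation vector in mm."""
        return self.matrix[:3, 3]

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, rotation: np.ndarray,
                                  translation: Iterable[float]) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m)

    # -- algebra -----------------------------------------------------------
    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)

    def inverse(self) -> "RigidTransform":
        return invert(self)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply the transform to an (n, 3) array (or single point) of mm."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    # -- file I/O ----------------------------------------------------------
    @classmethod
    def from_file(cls, path: str | Path) -> "RigidTransform":
        """Read a transform from plain text: 4 rows of 4 floats, '#' comments."""
        m = np.loadtxt(path, comments="#", dtype=float)
        if m.shape != (4, 4):
            raise TransformError(f"{path}: expected 4x4 matrix, got {m.shape}")
        return cls(m)

    def to_file(self, path: str | Path, header: str | None = None) -> None:
        hdr = header if header is not None else "4x4 rigid transform, MRI -> head, mm"
        np.savetxt(path, self.matrix, fmt="%.17g", header=hdr)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        p = decompose(self)
        return (f"RigidTransform(t=({p.tx:.2f}, {p.ty:.2f}, {p.tz:.2f}) mm, "
                f"rot=({p.pitch:.2f}, {p.roll:.2f}, {p.yaw:.2f}) deg)")


@dataclass(frozen=True)
class TransformParams:
    """Six-parameter description of a rigid transform.

    Translations in mm; pitch/roll/yaw in degrees about the fixed x/y/z
    axes (see module docstring for the convention).  ``gimbal_lock`` is set
    when |roll| was within 1e-7 degrees of 90 during decomposition, in
    which case yaw was fixed to 0 and pitch absorbed the remaining
    rotation.
    """

    tx: float
    ty: float
    tz: float
    pitch: float
    roll: float
    yaw: float
    gimbal_lock: bool = field(default=False, compare=False)

    def as_array(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz,
                         self.pitch, self.roll, self.yaw])


class LandmarkFit(NamedTuple):
    """Result of a least-squares landmark fit."""

    transform: RigidTransform
    rms: float  #: root-mean-square residual over the point pairs, mm


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Return the transform applying ``b`` first, then ``a``."""
    return RigidTransform(a.matrix @ b.matrix)


def invert(t: RigidTransform) -> RigidTransform:
    """Invert a rigid transform (transpose rotation, back-rotate translation)."""
    r = t.rotation.T
    return RigidTransform.from_rotation_translation(r, -r @ t.translation)


def _rot_x(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def recompose(params: TransformParams) -> RigidTransform:
    """Build the rigid transform with the given six parameters.

    ``R = Rz(yaw) @ Ry(roll) @ Rx(pitch)``, translation appended.
    """
    arr = params.as_array()
    if not np.all(np.isfinite(arr)):
        raise TransformError("non-finite transform parameters")
    r = _rot_z(params.yaw) @ _rot_y(params.roll) @ _rot_x(params.pitch)
    # renormalize to keep the strict orthonormality invariant after the
    # triple product accumulates float error
    u, _, vt = np.linalg.svd(r)
    return RigidTransform.from_rotation_translation(
        u @ vt, (params.tx, params.ty, params.tz))


def decompose(t: RigidTransform, *, gimbal_tol_deg: float = 1e-7) -> TransformParams:
    """Decompose a rigid transform into translations (mm) and pitch/roll/yaw (deg).

    Inverse of :func:`recompose`; ``recompose(decompose(t))`` reproduces the
    matrix to better than 1e-9 away from gimbal lock.  At gimbal lock
    (|roll| = 90 deg, where pitch and yaw rotate about the same physical
    axis) the convention yaw = 0 is applied and the result is flagged.
    """
    r = t.rotation
    sin_roll = -r[2, 0]
    cos_roll = float(np.hypot(r[2, 1], r[2, 2]))
    roll = np.rad2deg(np.arctan2(sin_roll, cos_roll))
    if 90.0 - abs(roll) < gimbal_tol_deg:
        # r reduces to [[0, +/-sin(p-/+y)...]]; fix yaw=0, pitch absorbs.
        if sin_roll > 0:
            pitch = np.rad2deg(np.arctan2(r[0, 1], r[0, 2]))
        else:
            pitch = np.rad2deg(np.arctan2(-r[0, 1], -r[0, 2]))
        yaw = 0.0
        lock = True
    else:
        pitch = np.rad2deg(np.arctan2(r[2, 1], r[2, 2]))
        yaw = np.rad2deg(np.arctan2(r[1, 0], r[0, 0]))
        lock = False
    tx, ty, tz = t.translation
    return TransformParams(float(tx), float(ty), float(tz),
                           float(pitch), float(roll), float(yaw),
                           gimbal_lock=lock)


def fit_landmarks(source: np.ndarray, target: np.ndarray) -> LandmarkFit:
    """Least-squares rigid transform mapping ``source`` points onto ``target``.

    Orthogonal Procrustes (Kabsch): centroids are aligned, the rotation is
    the SVD polar factor of the cross-covariance, and a reflection (which a
    plain SVD can return for planar configurations) is corrected by flipping
    the sign of the smallest singular vector.  No scaling is estimated.

    Parameters
    ----------
    source, target : (n, 3) arrays, n >= 3, in mm, matched row-by-row.

    Returns
    -------
    LandmarkFit
        The rigid transform and the RMS residual of ``T(source) - target``.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 3 pairs or (near-)collinear source/target points,
        where the rotation about the line is unconstrained.
    """
    src = np.atleast_2d(np.asarray(source, dtype=float))
    tgt = np.atleast_2d(np.asarray(target, dtype=float))
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("source and target must be matching (n, 3) arrays")
    n = src.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 point pairs, got {n}")

    src_c = src - src.mean(axis=0)
    tgt_c = tgt - tgt.mean(axis=0)
    for name, pts in (("source", src_c), ("target", tgt_c)):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1.0):
            raise DegenerateGeometryError(f"{name} landmarks are collinear")

    h = src_c.T @ tgt_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = tgt.mean(axis=0) - rot @ src.mean(axis=0)
    transform = RigidTransform.from_rotation_translation(rot, trans)
    resid = transform.apply(src) - tgt
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return LandmarkFit(transform, rms)
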