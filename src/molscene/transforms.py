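"""Rigid-body transform algebra, screw-axis decomposition, and shadow projection.

A :class:`RigidTransform` is a proper rigid motion of 3-space, stored as a
3x3 rotation matrix ``R`` and a translation 3-vector ``t`` (Angstroms), acting
on column-vector points as ``p' = R @ p + t``.  Composition ``T1 * T2`` applies
``T2`` first, so a copy placed "in A's local frame" reads left-to-right:
``T_B = T_A * T_AB``.

Any rigid motion is a screw motion (Chasles): a rotation by ``angle`` about an
axis through ``axis_point`` with direction ``axis_direction``, plus a ``rise``
along that axis.  :func:`screw_decompose` recovers these parameters and
:func:`screw_transform` rebuilds the motion; repeated application of a screw
traces a helix, which is how actin-like filaments are described.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "InvalidTransformError",
    "RigidTransform",
    "ScrewParameters",
    "compose",
    "invert",
    "relative_transform",
    "transform_power",
    "screw_decompose",
    "screw_transform",
    "project_to_ground",
]

_ORTHO_TOL = 1e-9


class InvalidTransformError(ValueError):
    """Raised when a matrix does not describe a proper rigid motion."""


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise InvalidTransformError(f"rotation must be 3x3, got {R.shape}")
    if not np.all(np.isfinite(R)):
        raise InvalidTransformError("rotation contains non-finite entries")
    err = np.abs(R.T @ R - np.eye(3)).max()
    if err > 1e-7:
        raise InvalidTransformError(f"rotation is not orthonormal (|R^T R - I| = {err:.2e})")
    det = np.linalg.det(R)
    if abs(det - 1.0) > 1e-7:
        raise InvalidTransformError(f"rotation determinant is {det:.12f}, expected +1")
    if err > _ORTHO_TOL or abs(det - 1.0) > _ORTHO_TOL:
        # Small drift from accumulated composition: project back onto SO(3).
        U, _, Vt = np.linalg.svd(R)
        R = U @ Vt
    return R


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``p' = rotation @ p + translation``."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = _check_rotation(self.rotation)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise InvalidTransformError("translation contains non-finite entries")
        R.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors ----------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform()

    @staticmethod
    def from_translation(t) -> "RigidTransform":
        return RigidTransform(np.eye(3), np.asarray(t, dtype=float))

    @staticmethod
    def from_rotvec(rotvec, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return RigidTransform(Rotation.from_rotvec(rotvec).as_matrix(), translation)

    @staticmethod
    def from_matrix(M) -> "RigidTransform":
        M = np.asarray(M, dtype=float)
        if M.shape != (4, 4):
            raise InvalidTransformError(f"homogeneous matrix must be 4x4, got {M.shape}")
        if not np.allclose(M[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise InvalidTransformError("bottom row of homogeneous matrix must be [0 0 0 1]")
        return RigidTransform(M[:3, :3], M[:3, 3])

    # -- conversions -----------------------------------------------------
    def matrix(self) -> np.ndarray:
        """Return the 4x4 homogeneous matrix (row-major)."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def apply(self, points) -> np.ndarray:
        """Transform a point or an (N, 3) array of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    # -- algebra ---------------------------------------------------------
    def __mul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)

    def inverse(self) -> "RigidTransform":
        return invert(self)

    def almost_equal(self, other: "RigidTransform", tol: float = 1e-9) -> bool:
        return (
            np.abs(self.rotation - other.rotation).max() <= tol
            and np.abs(self.translation - other.translation).max() <= tol
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        rv = Rotation.from_matrix(self.rotation).as_rotvec()
        return f"RigidTransform(rotvec={np.round(rv, 6)}, t={np.round(self.translation, 6)})"


@dataclass(frozen=True)
class ScrewParameters:
    """Chasles decomposition of a rigid motion.

    ``angle`` is in (-pi, pi] (by construction non-negative here: the axis
    direction absorbs the sign); ``rise`` is the signed translation along
    ``axis_direction`` in Angstroms.
    """

    axis_direction: np.ndarray
    axis_point: np.ndarray
    angle: float
    rise: float

    def __post_init__(self) -> None:
        u = np.asarray(self.axis_direction, dtype=float).reshape(3)
        n = np.linalg.norm(u)
        if abs(n - 1.0) > 1e-6:
            raise ValueError(f"axis_direction must be unit length, |u| = {n}")
        u = u / n
        p = np.asarray(self.axis_point, dtype=float).reshape(3)
        u.setflags(write=False)
        p.setflags(write=False)
        object.__setattr__(self, "axis_direction", u)
        object.__setattr__(self, "axis_point", p)


def compose(T1: RigidTransform, T2: RigidTransform) -> RigidTransform:
    """Composition applying ``T2`` first: ``(T1 * T2) p = T1 (T2 p)``."""
    return RigidTransform(
        T1.rotation @ T2.rotation, T1.rotation @ T2.translation + T1.translation
    )


def invert(T: RigidTransform) -> RigidTransform:
    Rt = T.rotation.T
    return RigidTransform(Rt, -Rt @ T.translation)


def relative_transform(TA: RigidTransform, TB: RigidTransform) -> RigidTransform:
    """The transform ``T_AB`` with ``T_B = T_A * T_AB`` (B in A's local frame)."""
    return compose(invert(TA), TB)


def transform_power(T: RigidTransform, k: int) -> RigidTransform:
    """k-fold composition of ``T`` with itself; ``k = 0`` gives the identity."""
    if not isinstance(k, (int, np.integer)) or k < 0:
        raise ValueError(f"power requires a non-negative integer, got {k!r}")
    result = RigidTransform.identity()
    base = T
    k = int(k)
    while k:  # square-and-multiply keeps round-off flat for long chains
        if k & 1:
            result = compose(result, base)
        k >>= 1
        if k:
            base = compose(base, base)
    return result


def screw_transform(axis_direction, angle: float, rise: float, axis_point=(0.0, 0.0, 0.0)) -> RigidTransform:
    """Build the rigid motion rotating by ``angle`` about the given axis and
    translating ``rise`` along it."""
    u = np.asarray(axis_direction, dtype=float).reshape(3)
    n = np.linalg.norm(u)
    if n < 1e-12:
        raise ValueError("axis_direction must be non-zero")
    u = u / n
    p = np.asarray(axis_point, dtype=float).reshape(3)
    R = Rotation.from_rotvec(angle * u).as_matrix()
    t = (np.eye(3) - R) @ p + rise * u
    return RigidTransform(R, t)


def screw_decompose(T: RigidTransform) -> ScrewParameters:
    """Recover screw parameters: rebuilding with :func:`screw_transform`
    reproduces ``T`` to 1e-7.

    Tie-breaks: a pure translation reports ``angle = 0`` with the axis along
    the translation (through the origin); the identity reports axis ``+x``.
    For a half-turn the axis sign is chosen so its first non-zero component
    is positive.
    """
    rot = Rotation.from_matrix(T.rotation)
    rotvec = rot.as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    t = T.translation

    if angle < 1e-9:
        norm_t = np.linalg.norm(t)
        if norm_t < 1e-12:
            u = np.array([1.0, 0.0, 0.0])
            rise = 0.0
        else:
            u = t / norm_t
            rise = norm_t
        return ScrewParameters(u, np.zeros(3), 0.0, float(rise))

    u = rotvec / angle
    if abs(angle - np.pi) < 1e-9:
        # Half turn: rotvec sign is arbitrary; pick deterministic axis sign.
        nz = np.flatnonzero(np.abs(u) > 1e-9)
        if nz.size and u[nz[0]] < 0:
            u = -u
        angle = np.pi
    rise = float(t @ u)
    t_perp = t - rise * u
    # Axis point: minimal-norm solution of (I - R) p = t_perp with p ⟂ u.
    A = np.eye(3) - T.rotation
    p, *_ = np.linalg.lstsq(A, t_perp, rcond=None)
    p = p - (p @ u) * u
    return ScrewParameters(u, p, float(angle), rise)


def project_to_ground(points, ground_height: float, up) -> np.ndarray:
    """Project points onto the plane ``{p : p . up = ground_height}`` along
    ``up`` — the shadow cast by a light infinitely far away in the up
    direction onto the ground plane."""
    u = np.asarray(up, dtype=float).reshape(3)
    n = np.linalg.norm(u)
    if n < 1e-12:
        raise ValueError("up vector must be non-zero")
    u = u / n
    p = np.atleast_2d(np.asarray(points, dtype=float))
    # replace (rather than correct) the along-up component so the operation
    # is exactly idempotent when up is exactly representable
    out = p - (p @ u)[:, None] * u[None, :] + ground_height * u[None, :]
    return out if np.asarray(points).ndim == 2 else out[0]
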