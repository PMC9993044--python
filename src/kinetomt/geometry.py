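"""Rigid-body mathematics: rotations, transforms, least-squares superposition.

Conventions used throughout the package
---------------------------------------
* All angles at public interfaces are in **degrees**; radians appear only
  inside function bodies.
* Rotations follow the **right-hand rule** about the axis direction: looking
  down the axis vector (axis pointing toward the viewer), a positive angle
  turns counter-clockwise.  A negative inter-protofilament twist therefore
  winds clockwise when viewed from the microtubule plus end (+z).
* Transforms act on column points as ``R @ p + t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError

__all__ = ["RigidTransform", "axis_rotation", "superpose", "angle_between"]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``p -> rotation @ p + translation``.

    The rotation must be a proper orthogonal 3x3 matrix (determinant +1
    within 1e-9); this is checked at construction.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise InvalidArgumentError("non-finite rigid transform components")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise InvalidArgumentError(
                f"rotation determinant {np.linalg.det(R):.6g} != +1 (improper or scaled)"
            )
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise InvalidArgumentError("rotation matrix is not orthogonal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_translation(cls, shift) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(shift, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array (or a single 3-vector) of positions."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def is_identity(self, atol: float = 1e-9) -> bool:
        return np.allclose(self.rotation, np.eye(3), atol=atol) and np.allclose(
            self.translation, 0.0, atol=atol
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Composition ``(a o b)(p) = a(b(p))``."""
    return a.compose(b)


def axis_rotation(axis, angle_deg: float, point_on_axis=(0.0, 0.0, 0.0)) -> RigidTransform:
    """Proper rotation by ``angle_deg`` about ``axis`` through ``point_on_axis``.

    Positive angles follow the right-hand rule about the axis direction.

    Raises
    ------
    InvalidArgumentError
        If the axis has (near-)zero length.
    """
    a = np.asarray(axis, dtype=float).reshape(3)
    norm = np.linalg.norm(a)
    if norm < 1e-12:
        raise InvalidArgumentError("rotation axis must be non-zero")
    a = a / norm
    theta = np.deg2rad(angle_deg)
    # Rodrigues' formula
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    R = np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)
    p = np.asarray(point_on_axis, dtype=float).reshape(3)
    return RigidTransform(R, p - R @ p)


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares superposition of ``mobile`` onto ``reference`` (Kabsch).

    Returns the proper rigid motion minimizing the RMSD of the mobile set
    onto the reference set, together with that RMSD in Angstrom.  A
    reflection is never returned: when the optimal orthogonal map would be
    improper, the smallest singular direction is flipped, which yields the
    best proper rotation.

    Raises
    ------
    DegenerateInputError
        Fewer than three point pairs, mismatched counts, or a collinear set
        (rotation about the common line would be unconstrained).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or P.shape != Q.shape:
        raise DegenerateInputError("point sets must both be (N, 3) with equal N")
    n = P.shape[0]
    if n < 3:
        raise DegenerateInputError(f"need >= 3 point pairs for superposition, got {n}")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # collinearity check: centered set of rank < 2 leaves a free rotation
    for centered, label in ((Pc, "mobile"), (Qc, "reference")):
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise DegenerateInputError(f"{label} point set is collinear (rank < 2)")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(P) - Q) ** 2, axis=1))))
    return transform, rmsd


def angle_between(u, v) -> float:
    """Unsigned angle between two direction vectors, in degrees (0..180)."""
    u = np.asarray(u, dtype=float).reshape(3)
    v = np.asarray(v, dtype=float).reshape(3)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise InvalidArgumentError("cannot measure the angle of a zero vector")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.rad2deg(np.arccos(c)))
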