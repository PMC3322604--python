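"""Rigid-body least-squares superposition and quaternion rotation algebra.

The superposition uses the quaternion eigenvalue formulation (Kearsley,
1989): the optimal proper rotation between two centred point sets is the
eigenvector of a 4x4 symmetric matrix belonging to its smallest eigenvalue,
and that eigenvalue equals the residual sum of squares.  Unlike naive SVD
this never returns a reflection.

Quaternions are stored as (w, x, y, z) with the scalar part canonicalised
to be non-negative (q and -q encode the same rotation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegenerateInputError(ValueError):
    """Point set is collinear or coincident; rotation is underdetermined."""


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion (w, x, y, z)."""
    w, x, y, z = q
    return np.array(
        [
            [w * w + x * x - y * y - z * z, 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), w * w - x * x + y * y - z * z, 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), w * w - x * x - y * y + z * z],
        ]
    )


def matrix_to_quaternion(rot: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z), scalar part >= 0, of a rotation matrix."""
    rot = np.asarray(rot, dtype=float)
    # Shepperd's method: pick the largest diagonal combination for stability.
    t = np.trace(rot)
    cand = np.array([t, rot[0, 0], rot[1, 1], rot[2, 2]])
    i = int(np.argmax(cand))
    if i == 0:
        w = np.sqrt(1.0 + t) / 2.0
        x = (rot[2, 1] - rot[1, 2]) / (4 * w)
        y = (rot[0, 2] - rot[2, 0]) / (4 * w)
        z = (rot[1, 0] - rot[0, 1]) / (4 * w)
    elif i == 1:
        x = np.sqrt(1.0 + rot[0, 0] - rot[1, 1] - rot[2, 2]) / 2.0
        w = (rot[2, 1] - rot[1, 2]) / (4 * x)
        y = (rot[0, 1] + rot[1, 0]) / (4 * x)
        z = (rot[0, 2] + rot[2, 0]) / (4 * x)
    elif i == 2:
        y = np.sqrt(1.0 - rot[0, 0] + rot[1, 1] - rot[2, 2]) / 2.0
        w = (rot[0, 2] - rot[2, 0]) / (4 * y)
        x = (rot[0, 1] + rot[1, 0]) / (4 * y)
        z = (rot[1, 2] + rot[2, 1]) / (4 * y)
    else:
        z = np.sqrt(1.0 - rot[0, 0] - rot[1, 1] + rot[2, 2]) / 2.0
        w = (rot[1, 0] - rot[0, 1]) / (4 * z)
        x = (rot[0, 2] + rot[2, 0]) / (4 * z)
        y = (rot[1, 2] + rot[2, 1]) / (4 * z)
    q = np.array([w, x, y, z])
    return canonical_quaternion(q / np.linalg.norm(q))


def canonical_quaternion(q: np.ndarray) -> np.ndarray:
    """Fix the q/-q sign ambiguity: scalar part >= 0 (x>=0 tie-break at w=0)."""
    q = np.asarray(q, dtype=float)
    if q[0] < 0 or (q[0] == 0 and (q[np.nonzero(q)[0][0]] < 0 if q.any() else False)):
        return -q
    return q


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion y = R x + t with the rotation kept in both
    matrix and unit-quaternion form."""

    rotation_matrix: np.ndarray
    translation: np.ndarray
    quaternion: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        rot = np.asarray(self.rotation_matrix, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation_matrix", rot)
        object.__setattr__(self, "translation", t)
        if self.quaternion is None:
            object.__setattr__(self, "quaternion", matrix_to_quaternion(rot))
        else:
            q = canonical_quaternion(np.asarray(self.quaternion, dtype=float))
            object.__setattr__(self, "quaternion", q)
        if abs(np.linalg.det(rot) - 1.0) > 1e-6:
            raise ValueError("rotation matrix must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        half = np.deg2rad(angle_deg) / 2.0
        q = np.concatenate([[np.cos(half)], np.sin(half) * axis])
        return cls(quaternion_to_matrix(q), np.asarray(translation, dtype=float), q)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation_matrix.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation_matrix.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self ∘ other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation_matrix @ other.rotation_matrix,
            self.rotation_matrix @ other.translation + self.translation,
        )

    @property
    def rotation_angle_deg(self) -> float:
        """Rotation angle in [0, 180] degrees."""
        return float(np.degrees(2.0 * np.arccos(min(1.0, abs(self.quaternion[0])))))

    def angle_to(self, other: "RigidTransform") -> float:
        return rotation_angle_between(self.quaternion, other.quaternion)


@dataclass(frozen=True)
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_points: int


def _kearsley_matrix(d: np.ndarray, s: np.ndarray) -> np.ndarray:
    dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
    sx, sy, sz = s[:, 0], s[:, 1], s[:, 2]
    F = np.empty((4, 4))
    F[0, 0] = np.sum(dx * dx + dy * dy + dz * dz)
    F[0, 1] = F[1, 0] = np.sum(sy * dz - dy * sz)
    F[0, 2] = F[2, 0] = np.sum(dx * sz - sx * dz)
    F[0, 3] = F[3, 0] = np.sum(sx * dy - dx * sy)
    F[1, 1] = np.sum(sy * sy + sz * sz + dx * dx)
    F[1, 2] = F[2, 1] = np.sum(dx * dy - sx * sy)
    F[1, 3] = F[3, 1] = np.sum(dx * dz - sx * sz)
    F[2, 2] = np.sum(sx * sx + sz * sz + dy * dy)
    F[2, 3] = F[3, 2] = np.sum(dy * dz - sy * sz)
    F[3, 3] = np.sum(sx * sx + sy * sy + dz * dz)
    return F


def superpose_lsq(moving, fixed) -> SuperpositionResult:
    """Least-squares rigid superposition of `moving` onto `fixed`.

    Returns the proper rotation + translation minimising the r.m.s. Ca
    deviation, together with that minimum.  Both point sets must have the
    same length (>= 3) and must not be collinear.
    """
    mov = np.atleast_2d(np.asarray(moving, dtype=float))
    fix = np.atleast_2d(np.asarray(fixed, dtype=float))
    if mov.shape != fix.shape or mov.ndim != 2 or mov.shape[1] != 3:
        raise ValueError(
            f"point sets must have identical (n, 3) shapes, got {mov.shape} vs {fix.shape}"
        )
    n = mov.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a rigid superposition")
    if not (np.isfinite(mov).all() and np.isfinite(fix).all()):
        raise ValueError("coordinates must be finite")

    cm_mov = mov.mean(axis=0)
    cm_fix = fix.mean(axis=0)
    x = mov - cm_mov
    y = fix - cm_fix
    for centred in (x, y):
        sv = np.linalg.svd(centred, compute_uv=False)
        if sv[1] < 1e-8:
            raise DegenerateInputError(
                "points are collinear or coincident; rotation underdetermined"
            )

    F = _kearsley_matrix(x - y, x + y)
    eigvals, eigvecs = np.linalg.eigh(F)
    q = canonical_quaternion(eigvecs[:, 0])
    rot = quaternion_to_matrix(q)
    # Kearsley's smallest eigenvalue equals the residual sum of squares, but
    # evaluating the residuals directly is better conditioned near zero.
    resid = x @ rot.T - y
    rmsd = float(np.sqrt(np.sum(resid * resid) / n))
    transform = RigidTransform(rot, cm_fix - rot @ cm_mov, q)
    return SuperpositionResult(transform=transform, rmsd=rmsd, n_points=n)


def pairwise_window_rmsd(windows_a: np.ndarray, windows_b: np.ndarray) -> np.ndarray:
    """Minimum superposition r.m.s.d. for every window pair, batched.

    windows_a: (na, L, 3), windows_b: (nb, L, 3).  Returns (na, nb) of
    r.m.s.d. values — the Kearsley smallest eigenvalues computed for all
    pairs at once, used to pre-screen stretch pairs cheaply.
    """
    A = np.asarray(windows_a, dtype=float)
    B = np.asarray(windows_b, dtype=float)
    na, L, _ = A.shape
    nb = B.shape[0]
    X = A - A.mean(axis=1, keepdims=True)
    Y = B - B.mean(axis=1, keepdims=True)
    # Cross/auto second-moment tensors over the window length.
    C = np.einsum("ila,jlb->ijab", X, Y)           # (na, nb, 3, 3)
    Sx = np.einsum("ila,ilb->iab", X, X)           # (na, 3, 3)
    Sy = np.einsum("jla,jlb->jab", Y, Y)           # (nb, 3, 3)
    Ct = np.swapaxes(C, 2, 3)
    Sxx = Sx[:, None, :, :]
    Syy = Sy[None, :, :, :]
    D = Sxx + Syy - C - Ct          # sum of d_a d_b  (d = x - y)
    S = Sxx + Syy + C + Ct          # sum of s_a s_b  (s = x + y)
    M = Sxx - Syy - C + Ct          # sum of s_a d_b
    F = np.empty((na, nb, 4, 4))
    F[..., 0, 0] = D[..., 0, 0] + D[..., 1, 1] + D[..., 2, 2]
    F[..., 0, 1] = F[..., 1, 0] = M[..., 1, 2] - M[..., 2, 1]
    F[..., 0, 2] = F[..., 2, 0] = M[..., 2, 0] - M[..., 0, 2]
    F[..., 0, 3] = F[..., 3, 0] = M[..., 0, 1] - M[..., 1, 0]
    F[..., 1, 1] = S[..., 1, 1] + S[..., 2, 2] + D[..., 0, 0]
    F[..., 1, 2] = F[..., 2, 1] = D[..., 0, 1] - S[..., 0, 1]
    F[..., 1, 3] = F[..., 3, 1] = D[..., 0, 2] - S[..., 0, 2]
    F[..., 2, 2] = S[..., 0, 0] + S[..., 2, 2] + D[..., 1, 1]
    F[..., 2, 3] = F[..., 3, 2] = D[..., 1, 2] - S[..., 1, 2]
    F[..., 3, 3] = S[..., 0, 0] + S[..., 1, 1] + D[..., 2, 2]
    lam = np.linalg.eigvalsh(F)[..., 0]
    return np.sqrt(np.maximum(lam, 0.0) / L)


def rotation_angle_between(q1, q2) -> float:
    """Angle in degrees, [0, 180], of the relative rotation between two unit
    quaternions; invariant under the q ≡ -q sign flip."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    for q in (q1, q2):
        if abs(np.linalg.norm(q) - 1.0) > 1e-6:
            raise ValueError(f"quaternion not unit norm: |q| = {np.linalg.norm(q)}")
    dot = abs(float(np.dot(q1, q2)))
    return float(np.degrees(2.0 * np.arccos(min(1.0, dot))))


def apply_transform(t: RigidTransform, points) -> np.ndarray:
    """y = R x + t for each point."""
    return t.apply(points)
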