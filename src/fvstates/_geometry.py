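"""Rigid-body and torsion geometry primitives.

All coordinates are in Angstrom, all angles in radians unless a function
name or argument says degrees. These primitives back every downstream
module (superposition, dihedral featurization, interface frames, sidechain
frames), so they are written for correctness first and vectorized over
leading batch dimensions where it matters.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError

__all__ = [
    "Superposition",
    "kabsch",
    "superpose",
    "apply_transform",
    "dihedral",
    "angle_between",
    "signed_angle",
    "rotation_about_axis",
    "rotate_about_line",
]


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid transform mapping a mobile point set onto a reference.

    ``transformed = coords @ rotation.T + translation``

    Attributes
    ----------
    rotation : (3, 3) ndarray
        Proper orthonormal matrix (det = +1).
    translation : (3,) ndarray
        Translation applied after rotation, in Angstrom.
    rmsd : float
        Root-mean-square deviation over the fitted selection after the
        transform, in Angstrom.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted transform to an (..., 3) coordinate array."""
        return coords @ self.rotation.T + self.translation


def _check_noncollinear(x: np.ndarray, name: str) -> None:
    if x.shape[0] < 3:
        raise GeometryError(f"{name}: need >= 3 points, got {x.shape[0]}")
    centered = x - x.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise GeometryError(f"{name}: points are collinear within tolerance")


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares optimal rotation/translation (Kabsch, via SVD).

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` best fits ``reference``.
    Works on stacked inputs of shape (..., n, 3); the rotation is always
    proper (reflections are corrected through the sign of the smallest
    singular value).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mc = mobile.mean(axis=-2, keepdims=True)
    rc = reference.mean(axis=-2, keepdims=True)
    p = mobile - mc
    q = reference - rc
    h = np.swapaxes(p, -1, -2) @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.swapaxes(vt, -1, -2) @ np.swapaxes(u, -1, -2)))
    flip = np.ones(h.shape[:-2] + (3,))
    flip[..., -1] = d
    r = np.swapaxes(vt, -1, -2) * flip[..., None, :] @ np.swapaxes(u, -1, -2)
    t = rc.squeeze(-2) - np.einsum("...ij,...j->...i", r, mc.squeeze(-2))
    return r, t


def superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Superpose ``mobile`` onto ``reference`` (both (n, 3), paired points).

    Raises
    ------
    GeometryError
        For fewer than 3 points or a collinear selection.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise GeometryError(
            f"selection size mismatch: {mobile.shape} vs {reference.shape}"
        )
    _check_noncollinear(reference, "reference selection")
    r, t = kabsch(mobile, reference)
    moved = mobile @ r.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=-1))))
    return Superposition(rotation=r, translation=t, rmsd=rmsd)


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, float) @ np.asarray(rotation).T + translation


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed torsion angle of four points, IUPAC convention, in (-pi, pi].

    Accepts arrays of shape (..., 3); broadcasts over leading dimensions.
    The cis arrangement is 0, trans is pi; the sign follows the
    right-hand rule about the p1->p2 axis.
    """
    b1 = np.asarray(p1, float) - np.asarray(p0, float)
    b2 = np.asarray(p2, float) - np.asarray(p1, float)
    b3 = np.asarray(p3, float) - np.asarray(p2, float)
    c12 = np.cross(b1, b2)
    c23 = np.cross(b2, b3)
    y = np.einsum("...i,...i->...", b1, c23) * np.linalg.norm(b2, axis=-1)
    x = np.einsum("...i,...i->...", c12, c23)
    ang = np.arctan2(y, x)
    # map -pi -> +pi so the range is (-pi, pi]
    return np.where(np.isclose(ang, -np.pi), np.pi, ang)


def angle_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Unsigned angle between vectors in [0, pi], numerically safe."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    cosang = np.einsum("...i,...i->...", u, v) / (nu * nv)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def signed_angle(u: np.ndarray, v: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Signed angle from u to v about ``axis`` (right-hand rule), (-pi, pi].

    Anti-symmetric in its first two arguments:
    ``signed_angle(u, v, n) == -signed_angle(v, u, n)``.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    n = np.asarray(axis, float)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    y = np.einsum("...i,...i->...", n, np.cross(u, v))
    x = np.einsum("...i,...i->...", u, v) - (
        np.einsum("...i,...i->...", u, n) * np.einsum("...i,...i->...", v, n)
    )
    return np.arctan2(y, x)


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about a unit axis."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    x, y, z = a
    c, s = np.cos(angle), np.sin(angle)
    cc = 1.0 - c
    return np.array(
        [
            [c + x * x * cc, x * y * cc - z * s, x * z * cc + y * s],
            [y * x * cc + z * s, c + y * y * cc, y * z * cc - x * s],
            [z * x * cc - y * s, z * y * cc + x * s, c + z * z * cc],
        ]
    )


def rotate_about_line(coords: np.ndarray, point: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotate coordinates about the line through ``point`` along ``axis``."""
    r = rotation_about_axis(axis, angle)
    return (np.asarray(coords, float) - point) @ r.T + point
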