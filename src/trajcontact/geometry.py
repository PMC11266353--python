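"""Geometric primitives: minimum-image distances, centers of mass,
ring-plane normals and Kabsch least-squares superposition."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "RotationResult",
    "minimum_image_displacement",
    "minimum_image_distance",
    "center_of_mass",
    "ring_plane_normal",
    "kabsch_superpose",
    "apply_transform",
    "interplanar_angle",
]


@dataclass(frozen=True)
class RotationResult:
    """Proper rotation + translation superposing mobile onto reference,
    with the weighted RMSD (Å) after the fit.

    The transform maps mobile coordinates x to ``x @ rotation.T + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


def minimum_image_displacement(delta: np.ndarray,
                               box: Optional[np.ndarray] = None) -> np.ndarray:
    """Fold displacement vector(s) to the nearest periodic image.

    For an orthorhombic box this componentwise rounding is exactly the
    minimum over the 27 neighbouring images.
    """
    delta = np.asarray(delta, dtype=float)
    if box is None:
        return delta
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray,
                           box: Optional[np.ndarray] = None) -> float:
    """Distance (Å) between two points under the minimum-image convention.

    Without a box this is the plain Euclidean distance.
    """
    d = minimum_image_displacement(np.asarray(b, float) - np.asarray(a, float), box)
    return float(np.linalg.norm(d, axis=-1)) if d.ndim == 1 else np.linalg.norm(d, axis=-1)


def center_of_mass(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted mean position of k points."""
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if coords.ndim != 2 or len(coords) == 0:
        raise ValueError("coords must be a non-empty k×3 array")
    if np.any(masses < 0):
        raise ValueError("masses must be non-negative")
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    return (coords * masses[:, None]).sum(axis=0) / total


def ring_plane_normal(coords: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane through ≥3 points.

    The normal is the smallest principal axis of the centered coordinates;
    its sign is arbitrary, so consumers should use unsigned angles.

    Raises
    ------
    ValueError
        If the points are (near-)collinear: the two smallest singular
        values are comparable (ratio > 0.99), so no plane is defined.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3:
        raise ValueError("need at least 3 points to define a plane")
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # s is descending; plane is ill-defined when s[1] ~ s[2] (collinear) or
    # everything is degenerate.
    if s[1] <= 1e-10 * max(s[0], 1.0) or (s[1] > 0 and s[2] / s[1] > 0.99):
        raise ValueError("degenerate (collinear) coordinates: plane undefined")
    return vt[2]


def interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Unsigned angle (degrees, folded to [0, 90]) between two plane normals."""
    c = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: Optional[np.ndarray] = None) -> RotationResult:
    """Least-squares optimal proper rigid transform of mobile onto reference.

    Point correspondence is by index.  Reflections are corrected by flipping
    the sign of the smallest singular vector, so the returned rotation always
    has determinant +1.  Coincident degenerate point sets yield the identity.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching k×3 arrays")
    k = mobile.shape[0]
    if weights is None:
        w = np.ones(k)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (k,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be k non-negative values with positive sum")
    wn = w / w.sum()

    cm = (mobile * wn[:, None]).sum(axis=0)
    cr = (reference * wn[:, None]).sum(axis=0)
    x = mobile - cm
    y = reference - cr

    h = (x * wn[:, None]).T @ y
    if np.allclose(h, 0.0, atol=1e-15):
        rot = np.eye(3)
    else:
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        diag = np.diag([1.0, 1.0, d])
        rot = vt.T @ diag @ u.T

    trans = cr - rot @ cm
    fitted = x @ rot.T + cr
    rmsd = float(np.sqrt((wn * ((fitted - reference) ** 2).sum(axis=1)).sum()))
    return RotationResult(rotation=rot, translation=trans, rmsd=rmsd)


def apply_transform(coords: np.ndarray, result: RotationResult) -> np.ndarray:
    """Apply a :class:`RotationResult` to an N×3 coordinate array."""
    return np.asarray(coords, float) @ result.rotation.T + result.translation
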