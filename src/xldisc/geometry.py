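"""Small geometric primitives shared by the model builder and fixtures."""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "rotation_matrix",
    "rotate_about_point",
    "golden_spiral_points",
    "helix_on_arc",
    "helix_on_line",
    "arc_between",
]


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("zero rotation axis")
    x, y, z = axis / norm
    c, s = math.cos(angle), math.sin(angle)
    t = 1.0 - c
    return np.array(
        [
            [t * x * x + c, t * x * y - s * z, t * x * z + s * y],
            [t * x * y + s * z, t * y * y + c, t * y * z - s * x],
            [t * x * z - s * y, t * y * z + s * x, t * z * z + c],
        ]
    )


def rotate_about_point(
    coords: np.ndarray, axis: np.ndarray, angle: float, point: np.ndarray
) -> np.ndarray:
    rot = rotation_matrix(axis, angle)
    return (coords - point) @ rot.T + point


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    if n < 12:
        raise ValueError("need at least 12 sphere points")
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def helix_on_arc(
    n: int,
    arc_radius: float,
    theta0: float,
    z: float,
    direction: int = 1,
    rise: float = 1.5,
    helix_radius: float = 2.3,
    twist: float = 100.0,
    phase0: float = 0.0,
) -> np.ndarray:
    """Ideal helix whose axis follows a circular arc of the given radius.

    The axis advances ``rise`` Angstrom of arc per residue at height ``z``,
    counterclockwise for direction=+1.  The helical wheel winds in the plane
    spanned by the outward radial direction and the z axis.
    """
    i = np.arange(n, dtype=float)
    theta = theta0 + direction * (rise * i) / arc_radius
    axis_pts = np.column_stack(
        [arc_radius * np.cos(theta), arc_radius * np.sin(theta), np.full(n, float(z))]
    )
    u = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n)])  # radial out
    v = np.array([0.0, 0.0, 1.0])
    phase = phase0 + np.deg2rad(twist) * i
    offs = helix_radius * (np.cos(phase)[:, None] * u + np.sin(phase)[:, None] * v)
    return axis_pts + offs


def helix_on_line(
    n: int,
    origin: np.ndarray,
    axis_dir: np.ndarray,
    rise: float = 1.5,
    helix_radius: float = 2.3,
    twist: float = 100.0,
    phase0: float = 0.0,
) -> np.ndarray:
    """Ideal helix along an arbitrary straight axis starting at ``origin``."""
    axis_dir = np.asarray(axis_dir, float)
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis_dir @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(axis_dir, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis_dir, u)
    i = np.arange(n, dtype=float)
    phase = phase0 + np.deg2rad(twist) * i
    return (
        np.asarray(origin, float)
        + rise * i[:, None] * axis_dir
        + helix_radius * (np.cos(phase)[:, None] * u + np.sin(phase)[:, None] * v)
    )


def arc_between(
    p: np.ndarray,
    q: np.ndarray,
    path_length: float,
    bulge_dir: np.ndarray,
    n_interior: int,
) -> np.ndarray:
    """Interior points of a circular arc from p to q with a given arc length.

    The arc bulges toward ``bulge_dir`` (component orthogonal to the chord is
    used).  Used to thread flexible linkers of a prescribed contour length
    between fixed anchor positions.  Returns an (n_interior, 3) array.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    chord = q - p
    d = np.linalg.norm(chord)
    if n_interior <= 0:
        return np.empty((0, 3))
    if path_length < d:
        raise ValueError(f"path length {path_length:.1f} shorter than chord {d:.1f}")
    if path_length < d * 1.0005 or d < 1e-9:
        t = np.linspace(0, 1, n_interior + 2)[1:-1]
        return p + t[:, None] * chord

    # chord = 2 rho sin(alpha), arc = 2 rho alpha  ->  sin(alpha)/alpha = d/L
    ratio = d / path_length

    def f(alpha: float) -> float:
        return math.sin(alpha) / alpha - ratio

    alpha = brentq(f, 1e-6, math.pi - 1e-9)
    rho = d / (2.0 * math.sin(alpha))

    e1 = chord / d
    b = np.asarray(bulge_dir, float)
    b = b - (b @ e1) * e1
    nb = np.linalg.norm(b)
    if nb < 1e-9:
        # pick any direction orthogonal to the chord
        ref = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        b = np.cross(e1, ref)
        nb = np.linalg.norm(b)
    e2 = b / nb

    mid = 0.5 * (p + q)
    center = mid - e2 * rho * math.cos(alpha)
    # angle of p and q about the center in the (e2, e1) plane
    angles = np.linspace(-alpha, alpha, n_interior + 2)[1:-1]
    return center + rho * (
        np.cos(angles)[:, None] * e2 + np.sin(angles)[:, None] * e1
    )
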