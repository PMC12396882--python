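"""Exact 3D primitives underlying every exposure metric.

All coordinates are millimetres in a right-handed specimen frame
(+x anterior, +y superior, +z lateral toward the opened mastoid);
areas are mm^2 and angles degrees.  This module deliberately stays
small: planes, line/plane intersection, triangle and polygon areas,
and angles between lines -- nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError

__all__ = [
    "Plane",
    "as_point",
    "fit_plane",
    "intersect_line_plane",
    "heron_area",
    "angle_between_lines",
    "angle_between_vectors",
    "transverse_plane_at",
    "plane_basis",
    "polygon_area_in_plane",
]

_UNIT_TOL = 1e-9

# Axis preference used to orient fitted plane normals reproducibly:
# positive dot with +y (superior) when possible, else +x (anterior), else +z.
_ORIENT_AXES = (np.array([0.0, 1.0, 0.0]),
                np.array([1.0, 0.0, 0.0]),
                np.array([0.0, 0.0, 1.0]))


def as_point(p) -> np.ndarray:
    """Coerce to a finite float (3,) array, raising GeometryError otherwise."""
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise GeometryError(f"expected a 3D point, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise GeometryError(f"point has non-finite coordinates: {a}")
    return a


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if not np.isfinite(n) or n < _UNIT_TOL:
        raise GeometryError(f"zero-length or non-finite {what}")
    return v / n


@dataclass(frozen=True)
class Plane:
    """A plane given by an origin point and a unit normal."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", as_point(self.origin))
        n = as_point(self.normal)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            n = _unit(n, "plane normal")
        object.__setattr__(self, "normal", n)

    def signed_distance(self, p) -> float:
        return float(np.dot(as_point(p) - self.origin, self.normal))

    def project(self, p) -> np.ndarray:
        p = as_point(p)
        return p - self.signed_distance(p) * self.normal


def _orient(normal: np.ndarray) -> np.ndarray:
    for axis in _ORIENT_AXES:
        d = float(np.dot(normal, axis))
        if abs(d) > _UNIT_TOL:
            return normal if d > 0 else -normal
    return normal  # unreachable for a unit vector


def fit_plane(points) -> Plane:
    """Least-squares plane through >=3 non-collinear points.

    Minimises the sum of squared orthogonal distances (smallest principal
    axis of the centred point cloud).  The normal is oriented to have a
    positive dot product with +y when possible, else +x, so that signed
    distances are reproducible.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise GeometryError("fit_plane needs at least 3 points of shape (n, 3)")
    if not np.all(np.isfinite(pts)):
        raise GeometryError("fit_plane received non-finite coordinates")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    cov = centred.T @ centred
    evals, evecs = np.linalg.eigh(cov)  # ascending
    scale = max(evals[-1], 1e-30)
    if evals[1] / scale < 1e-12:
        raise GeometryError("fit_plane: points are collinear (or coincident)")
    return Plane(centroid, _orient(evecs[:, 0]))


def intersect_line_plane(a, b, plane: Plane) -> np.ndarray:
    """Intersection of the infinite line through a and b with a plane.

    Raises GeometryError when the line is parallel to the plane
    (|direction . normal| below tolerance).
    """
    a = as_point(a)
    d = as_point(b) - a
    denom = float(np.dot(d, plane.normal))
    if abs(denom) < 1e-12 * max(1.0, np.linalg.norm(d)):
        raise GeometryError("line is parallel to the plane: no intersection")
    t = float(np.dot(plane.origin - a, plane.normal)) / denom
    return a + t * d


def heron_area(a: float, b: float, c: float) -> float:
    """Triangle area from its three side lengths (mm -> mm^2).

    Uses the numerically stable sorted-operand form (Kahan), so
    near-degenerate triangles do not lose precision to cancellation.
    A triangle-inequality violation beyond 1e-9 * max side raises.
    """
    sides = sorted((float(a), float(b), float(c)), reverse=True)
    x, y, z = sides  # x >= y >= z
    if z < 0 or not all(np.isfinite(sides)):
        raise GeometryError(f"invalid side lengths {sides}")
    tol = 1e-9 * max(x, 1e-300)
    if x - (y + z) > tol:
        raise GeometryError(f"sides {sides} violate the triangle inequality")
    # Kahan's stable product; clamp tiny negatives from round-off.
    p = (x + (y + z)) * (z - (x - y)) * (z + (x - y)) * (x + (y - z))
    return 0.25 * np.sqrt(max(p, 0.0))


def angle_between_vectors(d1, d2) -> float:
    """Angle in degrees between two directed vectors, in [0, 180]."""
    u1 = _unit(d1, "direction")
    u2 = _unit(d2, "direction")
    return float(np.degrees(np.arccos(np.clip(np.dot(u1, u2), -1.0, 1.0))))


def angle_between_lines(d1, d2) -> float:
    """Angle between two undirected lines, folded into [0, 90] degrees.

    Insensitive to the sign of either direction.
    """
    u1 = _unit(d1, "direction")
    u2 = _unit(d2, "direction")
    return float(np.degrees(np.arccos(np.clip(abs(np.dot(u1, u2)), 0.0, 1.0))))


def transverse_plane_at(point, tegmen: Plane) -> Plane:
    """The tegmen-parallel ('transverse') plane through a given point."""
    return Plane(as_point(point), tegmen.normal)


def plane_basis(plane: Plane, primary_hint) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane axes (u, v): u is the hint direction projected
    into the plane; v completes it via v = u x n (so for the canonical
    transverse plane with hint = anterior, v points lateral)."""
    n = plane.normal
    h = as_point(primary_hint)
    u = h - np.dot(h, n) * n
    u = _unit(u, "in-plane hint (hint parallel to the normal?)")
    v = np.cross(u, n)
    return u, v


def polygon_area_in_plane(points, coplanar_tol: float = 1e-6) -> float:
    """Shoelace area of an ordered coplanar 3D polygon, orientation-free.

    Collinear input has area 0; points off their common plane by more than
    `coplanar_tol` (mm) raise GeometryError.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3 or pts.shape[1] != 3:
        raise GeometryError("polygon needs >= 3 points of shape (n, 3)")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    cov = centred.T @ centred
    evals, evecs = np.linalg.eigh(cov)
    scale = max(evals[-1], 1e-30)
    if evals[1] / scale < 1e-20:
        return 0.0  # collinear: degenerate polygon
    normal = evecs[:, 0]
    if np.max(np.abs(centred @ normal)) > coplanar_tol:
        raise GeometryError("polygon points are not coplanar within tolerance")
    x = centred @ evecs[:, 2]
    y = centred @ evecs[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
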