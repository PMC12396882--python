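"""The four exposure quantities of one specimen.

* surgical freedom (SF): area on the craniotomy plane from which a
  straight instrument reaches the target point P unobstructed, measured
  by casting six constrained lines of sight from P, intersecting them
  with the least-squares craniotomy plane, and summing four Heron
  triangles over the resulting hexagon;
* exposure angle (EA): the angular mobility of an instrument in a
  tegmen-parallel transverse plane, bounded by common tangents of the
  sigmoid-sinus and facial-nerve cross-sections and the anterior
  craniotomy border, at the IAC level and at the jugular-bulb level;
* angle of attack (AA): the angle between the ray from P toward the
  anterior sinus border and the distal IAC direction in the transverse
  plane at P (obtuse = a more posterior approach is possible);
* presigmoid depth and (trapezoidal) presigmoid dural area.

All metrics are computed in an intrinsic anatomical frame derived from
the landmarks themselves, so they are exactly invariant under common
rigid motions of the specimen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from shapely.geometry import LineString, Point as ShapelyPoint, Polygon

from . import geometry
from .errors import GeometryError
from .geometry import Plane
from .landmarks import SpecimenLandmarks

__all__ = [
    "AnatomicalFrame",
    "LineOfSightSet",
    "SurgicalFreedomResult",
    "ExposureMeasures",
    "anatomical_frame",
    "cast_lines_of_sight",
    "surgical_freedom",
    "sf_triangle_areas",
    "exposure_angle",
    "angle_of_attack",
    "presigmoid_measures",
    "compute_exposure",
]

LINE_LABEL_RULES = {
    1: "most anterior SS above the IAC",
    2: "sinodural angle or tegmen",
    3: "superior-anterior craniotomy",
    4: "facial nerve or craniotomy (antero-lateral IAC)",
    5: "inferior-anterior craniotomy or facial nerve",
    6: "inferior-posterior craniotomy or SS",
}

# Triangle vertex sets of the SF hexagon (1-based point indices).
SF_TRIANGLES = {"a": (1, 2, 4), "b": (2, 3, 4), "c": (4, 5, 6), "d": (1, 4, 6)}


@dataclass(frozen=True)
class AnatomicalFrame:
    """Orthonormal intrinsic axes of one specimen.

    superior  = tegmen-plane normal oriented from P toward the tegmen;
    anterior  = (anterior craniotomy border - posterior SS/dura anchor)
                projected into the transverse plane;
    lateral   = anterior x superior (right-handed, toward the mastoid
                opening in the canonical frame).

    Built only from landmarks that no procedure displaces, so the frame
    is identical across TL-S / TL-R / TL-C states of a specimen.
    """

    anterior: np.ndarray
    superior: np.ndarray
    lateral: np.ndarray
    tegmen_plane: Plane


def anatomical_frame(lm: SpecimenLandmarks) -> AnatomicalFrame:
    teg = geometry.fit_plane(lm.tegmen_points)
    s = teg.normal
    if np.dot(s, lm.tegmen_points.mean(axis=0) - lm.P) < 0:
        s = -s
    teg = Plane(teg.origin, s)
    if lm.dura_posterior_ss is None:
        raise GeometryError("dura_posterior_ss is required to build the anatomical frame")
    a_raw = lm.anterior_rim_point - lm.dura_posterior_ss
    a = a_raw - np.dot(a_raw, s) * s
    norm = np.linalg.norm(a)
    if norm < 1e-9:
        raise GeometryError("degenerate anterior axis (rim anchor above the dura anchor?)")
    a = a / norm
    return AnatomicalFrame(anterior=a, superior=s, lateral=np.cross(a, s), tegmen_plane=teg)


@dataclass(frozen=True)
class LineOfSightSet:
    """The six constrained lines of sight cast from P (L1..L6)."""

    origin: np.ndarray
    endpoints: np.ndarray  # (6, 3)
    labels: tuple  # constraint that terminated each line

    def __post_init__(self):
        if self.endpoints.shape != (6, 3):
            raise GeometryError("expected exactly six line endpoints")
        lengths = np.linalg.norm(self.endpoints - self.origin, axis=1)
        if np.any(lengths < 1e-9):
            raise GeometryError("a line of sight has zero length")


@dataclass(frozen=True)
class SurgicalFreedomResult:
    """SF on the craniotomy plane: the six intersection points, the four
    Heron triangle areas (A-D) and their sum."""

    plane: Plane
    points: np.ndarray  # (6, 3), indexed 1..6 in anatomical order
    tri_a: float
    tri_b: float
    tri_c: float
    tri_d: float
    total: float
    convex: bool
    degenerate: bool


@dataclass(frozen=True)
class ExposureMeasures:
    ea_iac: float
    ea_bulb: float
    aa: float
    presigmoid_depth: float
    presigmoid_area: float


# ---------------------------------------------------------------------------
# obstruction volumes: the tube spanned by two stored cross-sections
# ---------------------------------------------------------------------------

def _tube_clearance(pts: np.ndarray, c0, r0, c1, r1) -> np.ndarray:
    """Signed clearance of points to the tube through cross-sections
    (c0, r0) and (c1, r1); negative inside.  The axis is extended a
    quarter-length beyond each cross-section (the structure continues
    past the measured levels) with the end radius held constant."""
    w = c1 - c0
    ww = float(np.dot(w, w))
    if ww < 1e-12:
        s = np.zeros(pts.shape[0])
    else:
        s = (pts - c0) @ w / ww
    s_pos = np.clip(s, -0.25, 1.25)
    axis_pts = c0 + s_pos[:, None] * w
    radii = r0 + np.clip(s, 0.0, 1.0) * (r1 - r0)
    return np.linalg.norm(pts - axis_pts, axis=1) - radii


def _first_tube_hit(origin, target, c0, r0, c1, r1, n_samples: int = 96):
    """First crossing (as fraction t of origin->target) of the tube
    surface along the segment, or None if the segment stays clear."""
    d = target - origin
    ts = np.linspace(1e-4, 1.0, n_samples)
    h = _tube_clearance(origin + ts[:, None] * d, c0, r0, c1, r1)
    inside = h < 0
    if not inside.any():
        return None
    i = int(np.argmax(inside))
    if i == 0:
        return float(ts[0])
    f = lambda t: float(_tube_clearance(origin[None, :] + t * d[None, :], c0, r0, c1, r1)[0])
    return float(brentq(f, ts[i - 1], ts[i], xtol=1e-12))


def _rim_extreme(P, rim: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Rim vertex whose viewing direction from P is angularly closest to
    `direction` (the 'as far ... as the craniotomy allows' rule)."""
    rel = rim - P
    rel = rel / np.linalg.norm(rel, axis=1, keepdims=True)
    return rim[int(np.argmax(rel @ direction))]


def _rim_polygon_2d(rim: np.ndarray, plane: Plane, frame: AnatomicalFrame):
    u, v = geometry.plane_basis(plane, frame.anterior)
    rel = rim - plane.origin
    return Polygon(np.column_stack([rel @ u, rel @ v])), u, v


def cast_lines_of_sight(lm: SpecimenLandmarks) -> LineOfSightSet:
    """Cast the six constrained lines of sight from P.

    L1 ends on the most anterior SS directly lateral to the IAC middle;
    L2 runs superior-posteriorly to the sinodural angle, clipped to the
    tegmen plane if that is met first; L3 to the superior-anterior rim;
    L4 over the antero-lateral IAC until the facial nerve or the
    craniotomy plane; L5 to the inferior-anterior rim unless the facial
    nerve intervenes; L6 to the inferior-posterior rim unless the sigmoid
    sinus intervenes.  Labels record the binding constraint.
    """
    frame = anatomical_frame(lm)
    P = lm.P
    rim_plane = geometry.fit_plane(lm.craniotomy_rim)
    ss = (lm.ss_cross_iac.center, lm.ss_cross_iac.radius,
          lm.ss_cross_bulb.center, lm.ss_cross_bulb.radius)
    fn = (lm.fn_cross_iac.center, lm.fn_cross_iac.radius,
          lm.fn_cross_bulb.center, lm.fn_cross_bulb.radius)

    if float(_tube_clearance(P[None, :], *ss)[0]) <= 0:
        raise GeometryError("line 1: the sigmoid sinus encloses the target point P")

    endpoints = np.zeros((6, 3))
    labels = [None] * 6

    # L1 -- anterior border of the sinus directly above (lateral to) the IAC
    endpoints[0] = lm.ss_anterior_above_iac
    labels[0] = "sigmoid sinus"

    # L2 -- superior-posterior: sinodural angle, or the tegmen if met first
    teg = frame.tegmen_plane
    if teg.signed_distance(lm.sinodural_angle) > 1e-9:
        endpoints[1] = geometry.intersect_line_plane(P, lm.sinodural_angle, teg)
        labels[1] = "tegmen"
    else:
        endpoints[1] = lm.sinodural_angle
        labels[1] = "sinodural angle"

    a_hat, s_hat = frame.anterior, frame.superior

    # L3 -- superior-anterior craniotomy
    d3 = (a_hat + s_hat) / np.sqrt(2.0)
    endpoints[2] = _rim_extreme(P, lm.craniotomy_rim, d3)
    labels[2] = "craniotomy"

    # L4 -- over the antero-lateral IAC: facial nerve, else craniotomy
    q4 = geometry.intersect_line_plane(P, lm.iac_anterolateral, rim_plane)
    if np.dot(q4 - P, lm.iac_anterolateral - P) <= 0:
        raise GeometryError("line 4: craniotomy plane lies behind the IAC direction")
    t_fn = _first_tube_hit(P, q4, *fn)
    if t_fn is not None:
        endpoints[3] = P + t_fn * (q4 - P)
        labels[3] = "facial nerve"
    else:
        poly, u, v = _rim_polygon_2d(lm.craniotomy_rim, rim_plane, frame)
        q2 = np.array([np.dot(q4 - rim_plane.origin, u), np.dot(q4 - rim_plane.origin, v)])
        if not poly.covers(ShapelyPoint(q2)):
            centroid = np.asarray(poly.centroid.coords[0])
            cut = poly.exterior.intersection(LineString([centroid, q2]))
            if cut.is_empty:
                raise GeometryError("line 4: cannot clamp endpoint to the craniotomy rim")
            pts2 = np.atleast_2d([g.coords[0] for g in getattr(cut, "geoms", [cut])])
            far = pts2[int(np.argmax(np.linalg.norm(pts2 - centroid, axis=1)))]
            q4 = rim_plane.origin + far[0] * u + far[1] * v
        endpoints[3] = q4
        labels[3] = "craniotomy"

    # L5 -- inferior-anterior craniotomy, unless the facial nerve intervenes
    e5 = _rim_extreme(P, lm.craniotomy_rim, (a_hat - s_hat) / np.sqrt(2.0))
    t5 = _first_tube_hit(P, e5, *fn)
    if t5 is not None:
        endpoints[4] = P + t5 * (e5 - P)
        labels[4] = "facial nerve"
    else:
        endpoints[4] = e5
        labels[4] = "craniotomy"

    # L6 -- inferior-posterior craniotomy, unless the sinus intervenes
    e6 = _rim_extreme(P, lm.craniotomy_rim, (-a_hat - s_hat) / np.sqrt(2.0))
    t6 = _first_tube_hit(P, e6, *ss)
    if t6 is not None:
        endpoints[5] = P + t6 * (e6 - P)
        labels[5] = "sigmoid sinus"
    else:
        endpoints[5] = e6
        labels[5] = "craniotomy"

    return LineOfSightSet(origin=P.copy(), endpoints=endpoints, labels=tuple(labels))


def sf_triangle_areas(points: np.ndarray) -> tuple[float, float, float, float]:
    """Heron areas of triangles A=(1,2,4), B=(2,3,4), C=(4,5,6), D=(1,4,6)
    over six plane points (0-based array, 1-based triangle indices)."""
    pts = np.asarray(points, dtype=float)

    def _tri(idx):
        p = pts[[i - 1 for i in idx]]
        d = (np.linalg.norm(p[0] - p[1]), np.linalg.norm(p[1] - p[2]),
             np.linalg.norm(p[2] - p[0]))
        return geometry.heron_area(*d)

    return tuple(_tri(SF_TRIANGLES[k]) for k in ("a", "b", "c", "d"))


def _is_convex_cycle(pts2: np.ndarray) -> bool:
    n = pts2.shape[0]
    cross = np.empty(n)
    for i in range(n):
        a, b, c = pts2[i], pts2[(i + 1) % n], pts2[(i + 2) % n]
        cross[i] = (b[0] - a[0]) * (c[1] - b[1]) - (b[1] - a[1]) * (c[0] - b[0])
    nz = cross[np.abs(cross) > 1e-9]
    return bool(len(nz) == 0 or np.all(nz > 0) or np.all(nz < 0))


def surgical_freedom(lm: SpecimenLandmarks,
                     lines: LineOfSightSet | None = None) -> SurgicalFreedomResult:
    """Surgical freedom of one specimen state.

    Fits the oblique craniotomy plane to the rim, intersects the six
    lines of sight with it, and sums the four Heron triangles.  The
    triangulation sum is always what ``total`` reports; a self-
    intersecting hexagon is flagged (``convex=False``) with a warning
    rather than rejected.
    """
    if lines is None:
        lines = cast_lines_of_sight(lm)
    plane = geometry.fit_plane(lm.craniotomy_rim)
    pts = np.vstack([
        geometry.intersect_line_plane(lines.origin, e, plane) for e in lines.endpoints
    ])
    tri = sf_triangle_areas(pts)
    total = float(sum(tri))
    frame = anatomical_frame(lm)
    u, v = geometry.plane_basis(plane, frame.anterior)
    rel = pts - plane.origin
    pts2 = np.column_stack([rel @ u, rel @ v])
    degenerate = total < 1e-9
    convex = _is_convex_cycle(pts2) if not degenerate else False
    if not convex and not degenerate:
        warnings.warn("surgical-freedom hexagon is non-convex; the triangulation "
                      "sum is reported as-is", stacklevel=2)
    return SurgicalFreedomResult(plane=plane, points=pts, tri_a=tri[0], tri_b=tri[1],
                                 tri_c=tri[2], tri_d=tri[3], total=total,
                                 convex=convex, degenerate=degenerate)


# ---------------------------------------------------------------------------
# exposure angle
# ---------------------------------------------------------------------------

def _tangent_normal(s2, rs, o2, ro, sign_s, sign_o):
    """Unit normal n (2D, in-plane [anterior, lateral] coordinates) of a
    line n.x = c tangent to circle (s2, rs) with signed distance
    sign_s*rs and to circle (o2, ro) with signed distance sign_o*ro.

    Of the two solutions the one whose normal points laterally (n[1] > 0,
    i.e. the sinus is touched on the stated anatomical side) is taken;
    if that is ambiguous, the more horizontal line wins.
    """
    w = s2 - o2
    L = float(np.hypot(*w))
    if L < 1e-9:
        raise GeometryError("coincident structures: no common tangent")
    rhs = sign_s * rs - sign_o * ro
    cosang = rhs / L
    if abs(cosang) > 1.0:
        raise GeometryError("structures overlap: no common tangent with the required sides")
    base = np.arctan2(w[1], w[0])
    dphi = float(np.arccos(np.clip(cosang, -1.0, 1.0)))
    cands = [np.array([np.cos(base + e * dphi), np.sin(base + e * dphi)])
             for e in (+1.0, -1.0)]
    lateral = [n for n in cands if n[1] > 1e-9]
    pool = lateral if len(lateral) == 1 else (lateral or cands)
    return max(pool, key=lambda n: abs(n[1]))  # most horizontal direction


def _ea_in_plane(s2, rs, f2, rf, a2) -> float:
    """Exposure angle from 2D cross-sections: sinus (s2, rs), facial
    nerve (f2, rf), anterior craniotomy border a2, in [anterior, lateral]
    coordinates.  Returns the wedge at the tangent-line crossing that
    contains the deep (medial) direction."""
    nA = _tangent_normal(s2, rs, f2, rf, -1.0, +1.0)
    t_ss_a = s2 + rs * nA
    t_fn = f2 - rf * nA
    d_a = t_fn - t_ss_a
    nB = _tangent_normal(s2, rs, a2, 0.0, +1.0, +1.0)
    t_ss_b = s2 - rs * nB
    d_b = a2 - t_ss_b
    if np.linalg.norm(d_a) < 1e-9 or np.linalg.norm(d_b) < 1e-9:
        raise GeometryError("degenerate tangent construction (tangency points coincide)")
    fan = geometry.angle_between_vectors(np.append(d_a, 0.0), np.append(d_b, 0.0))
    return 180.0 - fan


def exposure_angle(lm: SpecimenLandmarks, level: str = "iac") -> float:
    """Exposure angle (degrees) in the tegmen-parallel transverse plane
    at the IAC level (through P) or the jugular-bulb level.

    The two bounding lines are (i) the common tangent touching the
    lateral sinus and the medial facial nerve and (ii) the tangent
    touching the medial sinus and passing through the anterior craniotomy
    border; the EA is the wedge between them that contains the deep
    (medial) instrument direction, so it grows as the sinus moves
    posteriorly and the corridor opens.
    """
    frame = anatomical_frame(lm)
    if level == "iac":
        origin, ss, fnd = lm.P, lm.ss_cross_iac, lm.fn_cross_iac
    elif level == "bulb":
        origin, ss, fnd = lm.jugular_bulb_top, lm.ss_cross_bulb, lm.fn_cross_bulb
    else:
        raise ValueError(f"level must be 'iac' or 'bulb', got {level!r}")
    u, v = frame.anterior, frame.lateral

    def to2d(p):
        rel = np.asarray(p, float) - origin
        return np.array([np.dot(rel, u), np.dot(rel, v)])

    return _ea_in_plane(to2d(ss.center), ss.radius, to2d(fnd.center), fnd.radius,
                        to2d(lm.anterior_rim_point))


def angle_of_attack(lm: SpecimenLandmarks) -> float:
    """Angle of attack (degrees) in the transverse plane at P: the angle
    between the ray from P toward the anterior sinus border and the
    distal IAC direction (middle -> most anterolateral part).  90 means a
    straight top-down approach; obtuse values permit a more posterior
    approach."""
    frame = anatomical_frame(lm)
    u, v = frame.anterior, frame.lateral

    def to2d(p):
        rel = np.asarray(p, float) - lm.P
        return np.array([np.dot(rel, u), np.dot(rel, v)])

    ss_anterior = to2d(lm.ss_cross_iac.center) + np.array([lm.ss_cross_iac.radius, 0.0])
    iac_dir = to2d(lm.iac_anterolateral) - to2d(lm.iac_mid)
    if np.linalg.norm(iac_dir) < 1e-9:
        raise GeometryError("degenerate IAC axis (iac_mid equals iac_anterolateral)")
    if np.linalg.norm(ss_anterior) < 1e-9:
        raise GeometryError("sinus anterior border coincides with P")
    return geometry.angle_between_vectors(np.append(ss_anterior, 0.0),
                                          np.append(iac_dir, 0.0))


def presigmoid_measures(lm: SpecimenLandmarks) -> tuple[float, float]:
    """Presigmoid depth (mm) and trapezoidal presigmoid dural area (mm^2).

    depth = |P - medial sinus border|; the trapezoid has medial base
    = orthogonal distance from the jugular-bulb top to the tegmen plane,
    lateral base = the stored dural extent medial to the vertical sinus,
    and height = the presigmoid depth.
    """
    depth = float(np.linalg.norm(lm.P - lm.ss_medial_border))
    frame = anatomical_frame(lm)
    medial_base = abs(frame.tegmen_plane.signed_distance(lm.jugular_bulb_top))
    lateral_base = float(np.linalg.norm(lm.presigmoid_dura_sup - lm.presigmoid_dura_inf))
    if depth <= 0:
        raise GeometryError("non-positive presigmoid depth")
    if medial_base <= 0 or lateral_base <= 0:
        raise GeometryError("non-positive trapezoid base length")
    area = 0.5 * (medial_base + lateral_base) * depth
    return depth, area


def compute_exposure(lm: SpecimenLandmarks) -> ExposureMeasures:
    """All angular and presigmoid measures of one specimen state."""
    depth, area = presigmoid_measures(lm)
    return ExposureMeasures(
        ea_iac=exposure_angle(lm, "iac"),
        ea_bulb=exposure_angle(lm, "bulb"),
        aa=angle_of_attack(lm),
        presigmoid_depth=depth,
        presigmoid_area=area,
    )
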