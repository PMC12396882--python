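"""Specimen landmark model, JSON interchange format, and validation.

A specimen is described entirely by named anatomical landmarks in
millimetres: the surgical-freedom target point P (midpoint on the most
proximal IAC surface), the internal auditory canal axis, sigmoid-sinus
cross-sections (modelled as circular discs in tegmen-parallel planes),
facial-nerve cross-sections, the tegmen, the jugular bulb, the
craniotomy rim, and the presigmoid dura anchors.

Files are JSON with an explicit ``schema_version`` and declared units.
Left-sided specimens are mirrored (z -> -z) on load so all analysis code
assumes a single right-handed canonical frame (+x anterior, +y superior,
+z lateral); the side is preserved as metadata and the mirror is undone
on write, so read(write(lm)) is the identity.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pydantic
from shapely.geometry import Polygon

from . import geometry
from .errors import GeometryError, SchemaError, ValidationError

__all__ = [
    "Disc3",
    "SpecimenLandmarks",
    "read_specimen",
    "write_specimen",
    "landmark_schema",
]

SCHEMA_VERSION = "1.0"

POINT_FIELDS = (
    "P",
    "iac_mid",
    "iac_anterolateral",
    "ss_anterior_above_iac",
    "ss_medial_border",
    "sinodural_angle",
    "jugular_bulb_top",
    "anterior_rim_point",
    "dura_posterior_ss",
    "presigmoid_dura_sup",
    "presigmoid_dura_inf",
)
DISC_FIELDS = ("ss_cross_iac", "ss_cross_bulb", "fn_cross_iac", "fn_cross_bulb")


@dataclass(frozen=True)
class Disc3:
    """A circular cross-section stand-in (centre + radius) for a tubular
    structure, lying in the tegmen-parallel plane at its centre's level."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", geometry.as_point(self.center))
        r = float(self.radius)
        if not np.isfinite(r) or r < 0:
            raise GeometryError(f"disc radius must be finite and >= 0, got {r}")
        object.__setattr__(self, "radius", r)

    def translated(self, delta) -> "Disc3":
        return Disc3(self.center + np.asarray(delta, dtype=float), self.radius)


@dataclass
class SpecimenLandmarks:
    """The full named-landmark model of one translabyrinthine resection
    cavity, in the canonical right-handed frame (millimetres)."""

    specimen_id: str
    side: str  # "left" | "right"
    P: np.ndarray
    iac_mid: np.ndarray
    iac_anterolateral: np.ndarray
    ss_anterior_above_iac: np.ndarray
    ss_cross_iac: Disc3
    ss_cross_bulb: Disc3
    ss_medial_border: np.ndarray
    fn_cross_iac: Disc3
    fn_cross_bulb: Disc3
    sinodural_angle: np.ndarray
    tegmen_points: np.ndarray  # (>=3, 3)
    jugular_bulb_top: np.ndarray
    craniotomy_rim: np.ndarray  # (>=6, 3), ordered
    anterior_rim_point: np.ndarray
    dura_posterior_ss: Optional[np.ndarray]
    presigmoid_dura_sup: np.ndarray
    presigmoid_dura_inf: np.ndarray
    covering_thickness_mm: Optional[float] = None

    def __post_init__(self):
        for name in POINT_FIELDS:
            v = getattr(self, name)
            if v is None:
                continue
            setattr(self, name, geometry.as_point(v))
        self.tegmen_points = np.atleast_2d(np.asarray(self.tegmen_points, float))
        self.craniotomy_rim = np.atleast_2d(np.asarray(self.craniotomy_rim, float))

    # -- invariants ----------------------------------------------------

    def validate(self, strict_radii: bool = True) -> "SpecimenLandmarks":
        """Check all documented invariants; raises ValidationError naming
        the offending field.  ``strict_radii=False`` admits radius-0 discs
        (the in-memory collapsed-sinus state)."""
        if self.side not in ("left", "right"):
            raise ValidationError(f"side: must be 'left' or 'right', got {self.side!r}")
        for name in POINT_FIELDS:
            v = getattr(self, name)
            if v is None:
                if name == "dura_posterior_ss":
                    continue
                raise ValidationError(f"{name}: missing landmark")
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"{name}: non-finite coordinates")
        for name in ("tegmen_points", "craniotomy_rim"):
            arr = getattr(self, name)
            if arr.ndim != 2 or arr.shape[1] != 3 or not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name}: expected a finite (n, 3) array")
        if self.tegmen_points.shape[0] < 3:
            raise ValidationError("tegmen_points: need >= 3 points")
        if self.craniotomy_rim.shape[0] < 6:
            raise ValidationError("craniotomy_rim: need >= 6 points")
        for name in DISC_FIELDS:
            disc = getattr(self, name)
            if strict_radii and disc.radius <= 0:
                raise ValidationError(f"{name}.radius: must be > 0")
        if self.ss_medial_border[0] >= self.P[0]:
            raise ValidationError(
                "ss_medial_border: must be posterior of P (smaller x in the canonical frame)")
        if self.jugular_bulb_top[1] >= self.P[1]:
            raise ValidationError("jugular_bulb_top: must be inferior to P (smaller y)")
        # Rim must stay simple after projection onto its best-fit plane.
        try:
            plane = geometry.fit_plane(self.craniotomy_rim)
        except GeometryError as exc:
            raise ValidationError(f"craniotomy_rim: degenerate ({exc})") from exc
        u, v = geometry.plane_basis(plane, _any_inplane_hint(plane))
        rel = self.craniotomy_rim - plane.origin
        poly = Polygon(np.column_stack([rel @ u, rel @ v]))
        if not poly.is_simple or poly.area <= 0:
            raise ValidationError("craniotomy_rim: polygon is self-intersecting or degenerate")
        return self

    # -- convenience transforms (used heavily in tests/examples) -------

    def transformed(self, rotation=None, translation=None) -> "SpecimenLandmarks":
        """A copy with a common rigid motion applied to every coordinate."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        return self._mapped(lambda p: R @ p + t)

    def scaled(self, s: float) -> "SpecimenLandmarks":
        """A copy uniformly scaled about the origin (radii scale too)."""
        out = self._mapped(lambda p: s * p)
        for name in DISC_FIELDS:
            d = getattr(out, name)
            setattr(out, name, Disc3(d.center, d.radius * s))
        return out

    def _mapped(self, f) -> "SpecimenLandmarks":
        kw = {}
        for fld in dataclasses.fields(self):
            v = getattr(self, fld.name)
            if fld.name in POINT_FIELDS and v is not None:
                kw[fld.name] = f(v)
            elif fld.name in DISC_FIELDS:
                kw[fld.name] = Disc3(f(v.center), v.radius)
            elif fld.name in ("tegmen_points", "craniotomy_rim"):
                kw[fld.name] = np.apply_along_axis(f, 1, v)
            else:
                kw[fld.name] = v
        return SpecimenLandmarks(**kw)


def _any_inplane_hint(plane: geometry.Plane) -> np.ndarray:
    n = plane.normal
    hint = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(hint, n)) > 0.9:
        hint = np.array([0.0, 1.0, 0.0])
    return hint


# ---------------------------------------------------------------------------
# JSON interchange (pydantic models give field-path error messages)
# ---------------------------------------------------------------------------

Coord = tuple[float, float, float]


class _DiscModel(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    center: Coord
    radius: float = pydantic.Field(gt=0)


class _SpecimenFile(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    schema_version: str
    units: str = "mm"
    specimen_id: str
    side: str
    covering_thickness_mm: Optional[float] = None
    P: Coord
    iac_mid: Coord
    iac_anterolateral: Coord
    ss_anterior_above_iac: Coord
    ss_cross_iac: _DiscModel
    ss_cross_bulb: _DiscModel
    ss_medial_border: Coord
    fn_cross_iac: _DiscModel
    fn_cross_bulb: _DiscModel
    sinodural_angle: Coord
    tegmen_points: list[Coord] = pydantic.Field(min_length=3)
    jugular_bulb_top: Coord
    craniotomy_rim: list[Coord] = pydantic.Field(min_length=6)
    anterior_rim_point: Coord
    dura_posterior_ss: Coord
    presigmoid_dura_sup: Coord
    presigmoid_dura_inf: Coord


_MIRROR = np.array([1.0, 1.0, -1.0])


def _mirror_if_left(lm: SpecimenLandmarks) -> SpecimenLandmarks:
    if lm.side != "left":
        return lm
    out = lm._mapped(lambda p: p * _MIRROR)
    # a mirror reverses rim orientation; ordering stays valid (still simple)
    return out


def read_specimen(path) -> SpecimenLandmarks:
    """Read and validate one landmark JSON file.

    Left-sided specimens are mirrored (z -> -z) into the canonical
    right-handed frame; ``side`` is kept as metadata.  Schema failures
    raise SchemaError naming the field; invariant failures raise
    ValidationError.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SchemaError(f"{path}: cannot parse JSON ({exc})") from exc
    try:
        model = _SpecimenFile.model_validate(raw)
    except pydantic.ValidationError as exc:
        locs = "; ".join(
            "/".join(str(p) for p in err["loc"]) + f": {err['msg']}" for err in exc.errors())
        raise SchemaError(f"{path}: schema error at {locs}") from exc
    if model.schema_version.split(".")[0] != SCHEMA_VERSION.split(".")[0]:
        raise SchemaError(f"{path}: unsupported schema_version {model.schema_version!r}")
    if model.units != "mm":
        raise SchemaError(f"{path}: units: only 'mm' is supported, got {model.units!r}")
    lm = SpecimenLandmarks(
        specimen_id=model.specimen_id,
        side=model.side,
        covering_thickness_mm=model.covering_thickness_mm,
        tegmen_points=np.asarray(model.tegmen_points, float),
        craniotomy_rim=np.asarray(model.craniotomy_rim, float),
        **{name: np.asarray(getattr(model, name), float)
           for name in POINT_FIELDS if name not in ()},
        **{name: Disc3(np.asarray(getattr(model, name).center, float),
                       getattr(model, name).radius)
           for name in DISC_FIELDS},
    )
    lm = _mirror_if_left(lm)
    return lm.validate()


def write_specimen(lm: SpecimenLandmarks, path) -> Path:
    """Write a SpecimenLandmarks to JSON (inverse of read_specimen).

    Canonical-frame coordinates of left-sided specimens are mirrored back
    to their native orientation so that read(write(lm)) == lm bit-exactly.
    """
    lm.validate(strict_radii=True)
    native = _mirror_if_left(lm)  # mirror is its own inverse
    doc = {
        "schema_version": SCHEMA_VERSION,
        "units": "mm",
        "specimen_id": native.specimen_id,
        "side": native.side,
        "covering_thickness_mm": native.covering_thickness_mm,
    }
    for name in POINT_FIELDS:
        doc[name] = list(getattr(native, name))
    for name in DISC_FIELDS:
        d = getattr(native, name)
        doc[name] = {"center": list(d.center), "radius": d.radius}
    doc["tegmen_points"] = [list(p) for p in native.tegmen_points]
    doc["craniotomy_rim"] = [list(p) for p in native.craniotomy_rim]
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1))
    return path


def landmark_schema() -> dict:
    """The JSON Schema of the landmark interchange format."""
    return _SpecimenFile.model_json_schema()
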