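"""Cohort tables (CSV) and visualization mesh export.

The cohort table holds one row per specimen x procedure with the full set
of exposure metrics; it is the interchange between the measurement
pipeline and the statistical layer.  CSV dialect: comma-separated, UTF-8,
'.' decimal, fixed ISO header names, for locale-independent round trips.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .errors import GeometryError, ValidationError

__all__ = ["CohortRecord", "COHORT_COLUMNS", "records_to_table", "write_cohort",
           "read_cohort", "export_sf_cone"]

PROCEDURES = ("TL-S", "TL-R", "TL-C")

COHORT_COLUMNS = [
    "specimen_id", "side", "procedure", "wedge_count",
    "sf_total", "tri_a", "tri_b", "tri_c", "tri_d",
    "ea_iac", "ea_bulb", "aa",
    "presigmoid_depth", "presigmoid_area", "patent",
]


@dataclass(frozen=True)
class CohortRecord:
    """One specimen x procedure row of exposure metrics."""

    specimen_id: str
    side: str
    procedure: str  # TL-S | TL-R | TL-C
    wedge_count: int
    sf_total: float
    tri_a: float
    tri_b: float
    tri_c: float
    tri_d: float
    ea_iac: float
    ea_bulb: float
    aa: float
    presigmoid_depth: float
    presigmoid_area: float
    patent: bool

    def validate(self) -> "CohortRecord":
        if self.procedure not in PROCEDURES:
            raise ValidationError(f"procedure: unknown value {self.procedure!r}")
        if self.wedge_count < 0 or (self.procedure != "TL-R" and self.wedge_count != 0):
            raise ValidationError(
                f"wedge_count: must be 0 unless procedure is TL-R "
                f"(got {self.wedge_count} for {self.procedure})")
        tri_sum = self.tri_a + self.tri_b + self.tri_c + self.tri_d
        if abs(tri_sum - self.sf_total) > 1e-6:
            raise ValidationError(
                f"sf_total: {self.sf_total} != sum of triangles {tri_sum}")
        return self


def records_to_table(records) -> pd.DataFrame:
    """Validated DataFrame (stable column order) from CohortRecords."""
    records = list(records)
    if not records:
        raise ValidationError("no cohort records given")
    rows = [asdict(r.validate()) for r in records]
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    dup = df.duplicated(subset=["specimen_id", "procedure"])
    if dup.any():
        keys = df.loc[dup, ["specimen_id", "procedure"]].to_records(index=False)
        raise ValidationError(f"duplicate (specimen_id, procedure) rows: {list(keys)}")
    return df


def write_cohort(records, path) -> Path:
    """Write cohort records (CohortRecords or an equivalent DataFrame) to CSV."""
    if isinstance(records, pd.DataFrame):
        df = records[COHORT_COLUMNS].copy()
        dup = df.duplicated(subset=["specimen_id", "procedure"])
        if dup.any():
            raise ValidationError("duplicate (specimen_id, procedure) rows")
        tri_sum = df[["tri_a", "tri_b", "tri_c", "tri_d"]].sum(axis=1)
        if (tri_sum - df["sf_total"]).abs().max() > 1e-6:
            raise ValidationError("sf_total does not equal the triangle sum")
    else:
        df = records_to_table(records)
    path = Path(path)
    # shortest round-trip repr => lossless, locale-independent numbers
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    return path


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort CSV missing columns: {missing}")
    return df[COHORT_COLUMNS]


def export_sf_cone(landmarks, sf, path) -> trimesh.Trimesh:
    """Export the surgical-freedom cone as a watertight mesh (STL or PLY).

    The cone has its apex at the target point P and its base at the
    polygon of plane-intersection points; the base is fan-triangulated
    around its centroid, giving 2n faces for an n-gon base.
    """
    apex = np.asarray(landmarks.P, dtype=float)
    base = np.asarray(sf.points, dtype=float)
    n = base.shape[0]
    if n < 3 or sf.total <= 1e-9:
        raise GeometryError("degenerate surgical-freedom polygon: cannot export cone")
    centroid = base.mean(axis=0)
    vertices = np.vstack([apex[None, :], base, centroid[None, :]])
    faces = []
    for i in range(n):
        j = (i + 1) % n
        faces.append([0, 1 + i, 1 + j])        # side
        faces.append([n + 1, 1 + j, 1 + i])    # base fan (opposite winding)
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces), process=False)
    if not mesh.is_watertight:
        raise GeometryError("exported cone mesh is not watertight")
    mesh.export(str(path))
    return mesh
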