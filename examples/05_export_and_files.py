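"""Write a cohort to landmark JSON files and export a surgical-freedom
cone mesh.

The landmark files are the package's open interchange format (schema
version 1.0, millimetres, left sides stored in native orientation and
mirrored into the canonical frame on load).  The cone mesh has its apex
at the target point P and its base on the craniotomy plane; its base
area equals the surgical freedom.
"""

from pathlib import Path
from tempfile import mkdtemp

from presigmoid import (CohortConfig, export_sf_cone, generate_cohort,
                        read_cohort_dir, surgical_freedom, write_cohort_dir)

out = Path(mkdtemp(prefix="presigmoid_"))
cohort = generate_cohort(CohortConfig(n_specimens=4, seed=3))
write_cohort_dir(cohort, out)
print(f"wrote {len(cohort)} landmark files + truth.csv to {out}")

landmarks = read_cohort_dir(out)
lm = landmarks[0]
sf = surgical_freedom(lm)
mesh = export_sf_cone(lm, sf, out / f"{lm.specimen_id}_cone.stl")
print(f"{lm.specimen_id}: SF = {sf.total:.1f} mm^2; exported cone with "
      f"{len(mesh.vertices)} vertices / {len(mesh.faces)} faces, "
      f"watertight = {mesh.is_watertight}")
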