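"""Measure one synthetic specimen: surgical freedom, exposure angles,
angle of attack, and the presigmoid window.

Surgical freedom (SF, mm^2) is the area on the craniotomy plane from
which a straight instrument reaches the internal acoustic porus target
point P unobstructed.  The exposure angle (EA, degrees) is the angular
mobility of an instrument in a tegmen-parallel plane between the sigmoid
sinus, the facial nerve and the anterior craniotomy border.
"""

import numpy as np

from presigmoid import (CohortConfig, cast_lines_of_sight, compute_exposure,
                        generate_cohort, surgical_freedom)

specimen = generate_cohort(CohortConfig(n_specimens=1, seed=42))[0]
lm = specimen.landmarks

lines = cast_lines_of_sight(lm)
sf = surgical_freedom(lm, lines)
em = compute_exposure(lm)

print(f"specimen {lm.specimen_id} ({lm.side} side)")
print("lines of sight bound by:", ", ".join(lines.labels))
print(f"surgical freedom: {sf.total:7.1f} mm^2 "
      f"(triangles A-D: {sf.tri_a:.1f}, {sf.tri_b:.1f}, "
      f"{sf.tri_c:.1f}, {sf.tri_d:.1f})")
print(f"exposure angle, IAC level:  {em.ea_iac:6.1f} deg")
print(f"exposure angle, bulb level: {em.ea_bulb:6.1f} deg")
print(f"angle of attack:            {em.aa:6.1f} deg  (>90 = posterior "
      "approach possible)")
print(f"presigmoid depth: {em.presigmoid_depth:5.1f} mm, "
      f"dural window: {em.presigmoid_area:6.1f} mm^2")
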