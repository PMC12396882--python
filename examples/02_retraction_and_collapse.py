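"""Compare the three sigmoid-sinus handling strategies on one specimen.

TL-S leaves the skeletonized sinus in place; TL-R mobilizes it
posteriorly with 1.5 mm wedges while the lumen stays patent; TL-C models
a deskeletonized sinus collapsed flat against the posterior dura.  More
posterior sinus positions open the presigmoid corridor, so surgical
freedom and the exposure angles grow from TL-S through TL-C.
"""

from presigmoid import (CohortConfig, RetractionConfig, apply_collapse,
                        apply_retraction, compute_exposure, generate_cohort,
                        max_patent_retraction, surgical_freedom)

lm = generate_cohort(CohortConfig(n_specimens=1, seed=7))[0].landmarks
cfg = RetractionConfig()

k = max_patent_retraction(lm, cfg)
retracted, state_r = apply_retraction(lm, cfg, k)
collapsed, state_c = apply_collapse(lm)

print(f"maximal patent retraction: {k} wedges "
      f"({k * cfg.wedge_thickness:.1f} mm at the IAC level)")
print(f"{'state':6s} {'SF mm^2':>9s} {'EA-IAC':>8s} {'EA-bulb':>8s} {'AA':>7s}")
for tag, state_lm in (("TL-S", lm), ("TL-R", retracted), ("TL-C", collapsed)):
    sf = surgical_freedom(state_lm).total
    em = compute_exposure(state_lm)
    print(f"{tag:6s} {sf:9.1f} {em.ea_iac:8.1f} {em.ea_bulb:8.1f} {em.aa:7.1f}")
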