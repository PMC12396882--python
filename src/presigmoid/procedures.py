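"""The three sigmoid-sinus procedure states.

TL-S leaves the skeletonized sinus stationary.  TL-R mobilizes it
posteriorly with incremental 1.5 mm wedges until one more wedge would
threaten lumen patency; displacement is kinematic, with the distal
(jugular-bulb level) sinus less compliant than the IAC level, and the
lumen narrowing by a configurable fraction per wedge to give the patency
constraint a mechanism.  TL-C models a deskeletonized, collapsed sinus
whose walls lie completely flat along the posterior dura: each
cross-section becomes a zero-thickness structure at its own posterior
border, so the anterior sinus border recedes by the full lumen diameter
(vessel-wall thickness is deliberately ignored, overestimating TL-C
exposure by that thickness).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

from .errors import PresigmoidError, SchemaError
from .landmarks import Disc3, SpecimenLandmarks
from .metrics import anatomical_frame

__all__ = ["RetractionConfig", "ProcedureState", "stationary", "apply_retraction",
           "max_patent_retraction", "apply_collapse"]


@dataclass(frozen=True)
class RetractionConfig:
    """Tunable wedge-retraction model.

    wedge_thickness: posterior displacement per wedge at the IAC level (mm).
    max_wedges: wedge budget; the default exhausts the 20 mm of removable
        retrosigmoid bone (floor(20 / 1.5) = 13).
    patency_min_diameter_fraction: lumen-diameter fraction of the original
        below which patency is considered violated.
    distal_compliance: displacement fraction transmitted to the
        jugular-bulb level (the distal sinus is the least compliant).
    lumen_shrink_per_wedge: fractional lumen-diameter loss per wedge.
    """

    wedge_thickness: float = 1.5
    max_wedges: int = 13
    patency_min_diameter_fraction: float = 0.5
    distal_compliance: float = 0.6
    lumen_shrink_per_wedge: float = 0.10

    def __post_init__(self):
        if self.wedge_thickness <= 0:
            raise PresigmoidError("wedge_thickness must be > 0")
        if not (0.0 < self.patency_min_diameter_fraction <= 1.0):
            raise PresigmoidError("patency_min_diameter_fraction must be in (0, 1]")
        if not (0.0 <= self.lumen_shrink_per_wedge < 1.0):
            raise PresigmoidError("lumen_shrink_per_wedge must be in [0, 1)")
        if self.max_wedges < 0:
            raise PresigmoidError("max_wedges must be >= 0")


@dataclass(frozen=True)
class ProcedureState:
    """Which procedure produced a landmark state, and whether the sinus
    lumen remained patent."""

    procedure: str  # TL-S | TL-R | TL-C
    wedge_count: int
    patent: bool

    def __post_init__(self):
        if self.procedure == "TL-S" and (self.wedge_count != 0 or not self.patent):
            raise PresigmoidError("TL-S implies wedge_count == 0 and a patent sinus")
        if self.procedure == "TL-C" and self.patent:
            raise PresigmoidError("TL-C implies a collapsed (non-patent) lumen")
        if self.wedge_count < 0:
            raise PresigmoidError("wedge_count must be >= 0")


def stationary(lm: SpecimenLandmarks) -> tuple[SpecimenLandmarks, ProcedureState]:
    """TL-S: the identity state."""
    return lm, ProcedureState("TL-S", 0, True)


def _shrink_factor(cfg: RetractionConfig, wedge_count: int) -> float:
    return (1.0 - cfg.lumen_shrink_per_wedge) ** wedge_count


def apply_retraction(lm: SpecimenLandmarks, cfg: RetractionConfig,
                     wedge_count: int) -> tuple[SpecimenLandmarks, ProcedureState]:
    """TL-R with a given wedge count.

    Sinus landmarks at the IAC level (cross-section, anterior border,
    medial border) translate posteriorly by wedge_count x wedge_thickness;
    the bulb-level cross-section moves by the distal compliance fraction
    of that; lumen diameters shrink multiplicatively per wedge.  All
    non-sinus landmarks are untouched.
    """
    if wedge_count < 0:
        raise PresigmoidError(f"wedge_count must be >= 0, got {wedge_count}")
    if wedge_count == 0:
        return lm, ProcedureState("TL-R", 0, True)
    frame = anatomical_frame(lm)
    posterior = -frame.anterior
    delta = wedge_count * cfg.wedge_thickness * posterior
    shrink = _shrink_factor(cfg, wedge_count)
    out = dataclasses.replace(
        lm,
        ss_anterior_above_iac=lm.ss_anterior_above_iac + delta,
        ss_medial_border=lm.ss_medial_border + delta,
        ss_cross_iac=Disc3(lm.ss_cross_iac.center + delta,
                           lm.ss_cross_iac.radius * shrink),
        ss_cross_bulb=Disc3(lm.ss_cross_bulb.center + cfg.distal_compliance * delta,
                            lm.ss_cross_bulb.radius * shrink),
    )
    patent = shrink >= cfg.patency_min_diameter_fraction - 1e-12
    return out, ProcedureState("TL-R", wedge_count, bool(patent))


def max_patent_retraction(lm: SpecimenLandmarks, cfg: RetractionConfig) -> int:
    """Largest wedge count that keeps the lumen patent (0 if even one
    wedge violates), capped at the bone-removal budget."""
    if cfg.lumen_shrink_per_wedge == 0.0:
        return cfg.max_wedges
    k = math.floor(math.log(cfg.patency_min_diameter_fraction)
                   / math.log(1.0 - cfg.lumen_shrink_per_wedge) + 1e-12)
    return int(min(max(k, 0), cfg.max_wedges))


def apply_collapse(lm: SpecimenLandmarks) -> tuple[SpecimenLandmarks, ProcedureState]:
    """TL-C: the collapsed sinus lies flat along the posterior dura.

    Each cross-section collapses onto its own posterior border (radius 0),
    i.e. the line through the posterior SS/dura intersection, and the
    anterior sinus border above the IAC recedes by the full lumen
    diameter.  Idempotent; all non-sinus landmarks are untouched.
    """
    if lm.dura_posterior_ss is None:
        raise SchemaError("dura_posterior_ss: required for the collapse model")
    frame = anatomical_frame(lm)
    posterior = -frame.anterior
    r_iac = lm.ss_cross_iac.radius
    r_bulb = lm.ss_cross_bulb.radius
    out = dataclasses.replace(
        lm,
        ss_cross_iac=Disc3(lm.ss_cross_iac.center + r_iac * posterior, 0.0),
        ss_cross_bulb=Disc3(lm.ss_cross_bulb.center + r_bulb * posterior, 0.0),
        ss_anterior_above_iac=lm.ss_anterior_above_iac + 2.0 * r_iac * posterior,
    )
    return out, ProcedureState("TL-C", 0, False)
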