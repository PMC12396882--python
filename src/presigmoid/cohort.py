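"""Seeded synthetic cohorts of temporal-bone specimens.

The generator is landmark-level: it samples the latent anatomy
(presigmoid depth, sinus radius and inclination, facial-nerve offset,
tegmen tilt, craniotomy size) and places every landmark consistently,
because the exposure metrics consume landmarks only.  Defaults are
calibrated so that the presigmoid depth follows a truncated normal with
mean 25 mm, SD 5.8 mm on [15, 38] mm, presigmoid areas fall in
[283, 776] mm^2, a high-riding jugular bulb occurs in 1 of 6 specimens,
and baseline surgical freedom lands in the 250-650 mm^2 band.  Geometric
validity (a castable corridor, feasible tangent constructions, positive
baseline surgical freedom) is enforced by rejection sampling with a
bounded retry count; every draw is reproducible from the seed.

``simulate_study`` measures each specimen in the TL-S state, after the
maximal patent retraction (TL-R), and after collapse of the TL-S model
(TL-C), adding small per-scan landmark re-measurement noise; the TL-C
state shares the TL-S scan (it is refitted inside the same model), the
TL-R state is an independent re-scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .errors import PresigmoidError
from .io import CohortRecord, records_to_table
from .landmarks import Disc3, SpecimenLandmarks, read_specimen, write_specimen
from .metrics import compute_exposure, surgical_freedom
from .procedures import (ProcedureState, RetractionConfig, apply_collapse,
                         apply_retraction, max_patent_retraction)

__all__ = ["CohortConfig", "GeneratedSpecimen", "sample_specimen", "generate_cohort",
           "measure_cohort", "simulate_study", "write_cohort_dir", "read_cohort_dir"]

_MAX_RETRIES = 1000


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort (all lengths mm)."""

    n_specimens: int = 12
    seed: int = 0
    depth_mean: float = 25.0
    depth_sd: float = 5.8
    depth_range: tuple = (15.0, 38.0)
    presigmoid_area_range: tuple = (283.0, 776.0)
    sinus_radius_mean: float = 6.5
    sinus_radius_sd: float = 0.8
    fn_offset_mean: float = 4.0
    fn_offset_sd: float = 1.0
    craniotomy_scale_mean: float = 1.0
    craniotomy_scale_sd: float = 0.08
    medial_base_mean: float = 17.5
    medial_base_sd: float = 2.5
    high_riding_base_mean: float = 12.5
    high_riding_base_sd: float = 1.0
    lateral_base_mean: float = 16.0
    lateral_base_sd: float = 3.0
    high_riding_prob: float = 1.0 / 6.0
    measurement_noise_sd: float = 0.15
    retraction: RetractionConfig = field(default_factory=RetractionConfig)

    def __post_init__(self):
        if self.n_specimens < 1:
            raise PresigmoidError("n_specimens must be >= 1")
        lo, hi = self.depth_range
        if not lo < hi:
            raise PresigmoidError("depth_range bounds must be ordered")
        for name in ("depth_sd", "sinus_radius_sd", "fn_offset_sd",
                     "craniotomy_scale_sd", "medial_base_sd", "lateral_base_sd",
                     "measurement_noise_sd"):
            if getattr(self, name) < 0:
                raise PresigmoidError(f"{name} must be >= 0")


@dataclass(frozen=True)
class GeneratedSpecimen:
    """A generated specimen plus the sampled latent truth, for
    parameter-recovery checks."""

    landmarks: SpecimenLandmarks
    truth: dict


def _tnorm(rng, mean, sd, lo, hi) -> float:
    if sd <= 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _draw_specimen(cfg: CohortConfig, rng: np.random.Generator,
                   specimen_id: str, side: str):
    """One unvalidated draw of a specimen in the canonical frame (P at
    the origin, +x anterior, +y superior, +z lateral)."""
    P = np.zeros(3)

    # tegmen: a gently tilted plane ~12 mm superior to P
    n_t = np.array([rng.normal(0.0, 0.05), 1.0, rng.normal(0.0, 0.05)])
    n_t /= np.linalg.norm(n_t)
    anchor = np.array([-8.0, 12.0 + rng.normal(0.0, 0.8), 14.0])

    def teg_point(x, z):
        y = anchor[1] - (n_t[0] * (x - anchor[0]) + n_t[2] * (z - anchor[2])) / n_t[1]
        return np.array([x, y, z])

    tegmen_points = np.vstack([
        teg_point(x + rng.normal(0, 0.5), z + rng.normal(0, 0.5))
        for x, z in ((-22.0, 6.0), (6.0, 6.0), (-22.0, 22.0), (6.0, 22.0))
    ])

    # sigmoid sinus at the IAC level
    depth = _tnorm(rng, cfg.depth_mean, cfg.depth_sd, *cfg.depth_range)
    phi = np.radians(_tnorm(rng, 35.0, 7.0, 20.0, 52.0))
    r_s = _tnorm(rng, cfg.sinus_radius_mean, cfg.sinus_radius_sd, 3.5, 9.0)
    u_dir = np.array([-np.cos(phi), 0.0, np.sin(phi)])
    c_iac = (depth + r_s) * u_dir
    ss_cross_iac = Disc3(c_iac, r_s)
    ss_medial_border = c_iac - r_s * u_dir
    ss_anterior_above_iac = c_iac + np.array([r_s, 0.0, 0.0])
    dura_posterior_ss = c_iac - np.array([r_s, 0.0, 0.0])

    # jugular bulb: placed an exact medial-base distance below the tegmen
    high_riding = bool(rng.random() < cfg.high_riding_prob)
    if high_riding:
        mb = rng.normal(cfg.high_riding_base_mean, cfg.high_riding_base_sd)
    else:
        mb = rng.normal(cfg.medial_base_mean, cfg.medial_base_sd)
    x_b = c_iac[0] - 2.0 + rng.normal(0, 1.0)
    z_b = c_iac[2] - 1.0 + rng.normal(0, 1.0)
    top = teg_point(x_b, z_b)
    mb = max(mb, (top[1] + 0.75) / n_t[1])  # keep the bulb inferior to P
    jugular_bulb_top = top - mb * n_t

    # presigmoid dural trapezoid: lateral base conditioned so the implied
    # area lands inside the configured range
    lo_a, hi_a = cfg.presigmoid_area_range
    lo_lb = max(3.0, 2.0 * lo_a / depth - mb)
    hi_lb = 2.0 * hi_a / depth - mb
    if hi_lb <= lo_lb:
        raise PresigmoidError("infeasible trapezoid bases")  # triggers a retry
    lb = _tnorm(rng, cfg.lateral_base_mean, cfg.lateral_base_sd, lo_lb, hi_lb)
    presigmoid_dura_sup = ss_medial_border + np.array([0.0, lb / 2.0, 0.0])
    presigmoid_dura_inf = ss_medial_border - np.array([0.0, lb / 2.0, 0.0])

    # distal sinus cross-section at the bulb level
    ss_cross_bulb = Disc3(
        np.array([c_iac[0] - 1.0 + rng.normal(0, 1.0), jugular_bulb_top[1],
                  c_iac[2] + 1.0 + rng.normal(0, 1.0)]),
        r_s * rng.uniform(0.95, 1.15))

    # facial nerve: a near-vertical tube anterior and lateral of P
    x_f = rng.normal(cfg.fn_offset_mean, cfg.fn_offset_sd)
    z_f = rng.normal(9.0, 1.2)
    r_f = _tnorm(rng, 1.0, 0.12, 0.6, 1.5)
    fn_cross_iac = Disc3(np.array([x_f, 0.0, z_f]), r_f)
    fn_cross_bulb = Disc3(
        np.array([x_f + rng.normal(0, 0.5), jugular_bulb_top[1],
                  z_f + rng.normal(0, 0.5)]),
        r_f * rng.uniform(0.9, 1.1))

    # IAC axis: from the porus antero-laterally toward the fundus
    alpha = np.radians(rng.normal(20.0, 4.0))
    d_iac = np.array([np.sin(alpha), 0.0, np.cos(alpha)])
    iac_mid = 5.0 * d_iac
    iac_anterolateral = 10.5 * d_iac + np.array([rng.normal(0.5, 0.2), 0.0, 0.0])

    # sinodural angle: just below the tegmen at the sinus's
    # anterior-superior junction with the middle-fossa dura
    sda = teg_point(c_iac[0] + r_s + rng.normal(1.0, 0.5),
                    c_iac[2] + 1.0 + rng.normal(0, 1.0)) - 1.5 * n_t

    # craniotomy rim: a jittered ellipse on a near-lateral oblique plane.
    # The mastoidectomy exposes the sinus, so the rim reaches a few mm
    # behind its posterior border and spans tegmen to below the bulb; the
    # plane sits just lateral to the sinus surface (mastoid cortex).
    scale = _tnorm(rng, cfg.craniotomy_scale_mean, cfg.craniotomy_scale_sd, 0.75, 1.3)
    n_r = np.array([rng.normal(0, 0.08), rng.normal(0, 0.08), 1.0])
    n_r /= np.linalg.norm(n_r)
    e1 = np.array([1.0, 0.0, 0.0]) - n_r[0] * n_r
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n_r, e1)
    z_r = max(16.0, c_iac[2] + r_s + 1.5 + abs(rng.normal(0, 0.75)))
    ant_edge = 9.0 * scale + rng.normal(0, 1.0)
    post_edge = c_iac[0] - r_s - (3.0 + abs(rng.normal(0, 0.7))) * scale
    sup_edge = anchor[1] - 1.2
    inf_edge = jugular_bulb_top[1] - 2.5 * scale
    C0 = np.array([(ant_edge + post_edge) / 2.0, (sup_edge + inf_edge) / 2.0, z_r])
    semi_a = (ant_edge - post_edge) / 2.0
    semi_b = (sup_edge - inf_edge) / 2.0
    thetas = np.linspace(0.0, 2.0 * np.pi, 16, endpoint=False) + rng.normal(0, 0.03, 16)
    radial = 1.0 + rng.normal(0, 0.015, 16)
    rim = np.vstack([
        C0 + radial[j] * (semi_a * np.cos(t) * e1 + semi_b * np.sin(t) * e2)
        for j, t in enumerate(thetas)
    ])
    anterior_rim_point = C0 + semi_a * e1

    lm = SpecimenLandmarks(
        specimen_id=specimen_id, side=side,
        P=P, iac_mid=iac_mid, iac_anterolateral=iac_anterolateral,
        ss_anterior_above_iac=ss_anterior_above_iac,
        ss_cross_iac=ss_cross_iac, ss_cross_bulb=ss_cross_bulb,
        ss_medial_border=ss_medial_border,
        fn_cross_iac=fn_cross_iac, fn_cross_bulb=fn_cross_bulb,
        sinodural_angle=sda, tegmen_points=tegmen_points,
        jugular_bulb_top=jugular_bulb_top, craniotomy_rim=rim,
        anterior_rim_point=anterior_rim_point,
        dura_posterior_ss=dura_posterior_ss,
        presigmoid_dura_sup=presigmoid_dura_sup,
        presigmoid_dura_inf=presigmoid_dura_inf,
    )
    truth = {
        "depth": depth, "sinus_radius": r_s, "sinus_inclination_deg": np.degrees(phi),
        "fn_offset": x_f, "rim_scale": scale, "high_riding_bulb": high_riding,
        "medial_base": mb, "lateral_base": lb,
    }
    return lm, truth


def sample_specimen(cfg: CohortConfig, rng: np.random.Generator,
                    specimen_id: str = "S001", side: str = "right") -> GeneratedSpecimen:
    """Draw one geometrically valid specimen (rejection sampling, bounded
    retries).  Validity means: all landmark invariants hold, the six
    lines of sight cast successfully, the baseline surgical freedom is
    positive, and every angular measure is well inside (0, 180); a
    non-convex hexagon is a flagged but legitimate configuration."""
    for _ in range(_MAX_RETRIES):
        try:
            lm, truth = _draw_specimen(cfg, rng, specimen_id, side)
            lm.validate()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sf = surgical_freedom(lm)
                if sf.degenerate:
                    continue
                em = compute_exposure(lm)
            if not all(3.0 < v < 177.0 for v in (em.ea_iac, em.ea_bulb, em.aa)):
                continue
            return GeneratedSpecimen(landmarks=lm, truth=truth)
        except PresigmoidError:
            continue
    raise PresigmoidError(
        f"could not generate a valid specimen in {_MAX_RETRIES} attempts")


def generate_cohort(cfg: CohortConfig) -> list[GeneratedSpecimen]:
    """A reproducible cohort with sides alternating (balanced within 1)."""
    rng = np.random.default_rng(cfg.seed)
    first_right = bool(rng.integers(2))
    out = []
    for i in range(cfg.n_specimens):
        side = "right" if (i % 2 == 0) == first_right else "left"
        out.append(sample_specimen(cfg, rng, specimen_id=f"S{i + 1:03d}", side=side))
    return out


# ---------------------------------------------------------------------------
# the simulated study
# ---------------------------------------------------------------------------

def _jitter(lm: SpecimenLandmarks, rng: np.random.Generator,
            sd: float) -> SpecimenLandmarks:
    """Per-scan re-measurement noise on every landmark coordinate."""
    if sd <= 0:
        return lm
    return lm._mapped(lambda p: p + rng.normal(0.0, sd, 3))


def _measure(lm: SpecimenLandmarks, state: ProcedureState) -> CohortRecord:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sf = surgical_freedom(lm)
        em = compute_exposure(lm)
    return CohortRecord(
        specimen_id=lm.specimen_id, side=lm.side, procedure=state.procedure,
        wedge_count=state.wedge_count, sf_total=sf.total,
        tri_a=sf.tri_a, tri_b=sf.tri_b, tri_c=sf.tri_c, tri_d=sf.tri_d,
        ea_iac=em.ea_iac, ea_bulb=em.ea_bulb, aa=em.aa,
        presigmoid_depth=em.presigmoid_depth, presigmoid_area=em.presigmoid_area,
        patent=state.patent,
    )


def measure_cohort(landmarks_list, retraction: RetractionConfig | None = None,
                   noise_sd: float = 0.15, seed=0,
                   null_effect: bool = False) -> pd.DataFrame:
    """Measure every specimen under TL-S, TL-R (maximal patent
    retraction) and TL-C (collapse of the TL-S scan), returning the
    cohort table.

    With ``null_effect=True`` the TL-R and TL-C rows are independent
    re-scans of the unmodified anatomy (zero procedure effect), which is
    the configuration used for type-I-error calibration.
    """
    retraction = retraction or RetractionConfig()
    rng = np.random.default_rng(seed)
    records = []
    for lm in landmarks_list:
        scan_s = _jitter(lm, rng, noise_sd)
        records.append(_measure(scan_s, ProcedureState("TL-S", 0, True)))
        if null_effect:
            records.append(_measure(_jitter(lm, rng, noise_sd),
                                    ProcedureState("TL-R", 0, True)))
            records.append(_measure(_jitter(lm, rng, noise_sd),
                                    ProcedureState("TL-C", 0, False)))
        else:
            k = max_patent_retraction(lm, retraction)
            geo_r, st_r = apply_retraction(lm, retraction, k)
            records.append(_measure(_jitter(geo_r, rng, noise_sd), st_r))
            # TL-C is refitted inside the TL-S model: same scan noise
            lm_c, st_c = apply_collapse(scan_s)
            records.append(_measure(lm_c, st_c))
    return records_to_table(records)


def simulate_study(cfg: CohortConfig, null_effect: bool = False) -> pd.DataFrame:
    """Generate a cohort and run the full three-procedure study."""
    specimens = generate_cohort(cfg)
    return measure_cohort([sp.landmarks for sp in specimens],
                          retraction=cfg.retraction,
                          noise_sd=cfg.measurement_noise_sd,
                          seed=[cfg.seed, 2],
                          null_effect=null_effect)


# ---------------------------------------------------------------------------
# directory interchange (landmark files + latent truth)
# ---------------------------------------------------------------------------

def write_cohort_dir(specimens, directory) -> Path:
    """Write one landmark JSON per specimen plus a truth.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for sp in specimens:
        write_specimen(sp.landmarks, directory / f"{sp.landmarks.specimen_id}.json")
        rows.append({"specimen_id": sp.landmarks.specimen_id,
                     "side": sp.landmarks.side, **sp.truth})
    pd.DataFrame(rows).to_csv(directory / "truth.csv", index=False)
    return directory


def read_cohort_dir(directory) -> list[SpecimenLandmarks]:
    """Read all landmark files of a cohort directory, sorted by id."""
    directory = Path(directory)
    paths = sorted(p for p in directory.glob("*.json"))
    if not paths:
        raise PresigmoidError(f"no landmark files found in {directory}")
    return [read_specimen(p) for p in paths]
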