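"""Shared fixtures: a hand-built reference specimen with unambiguous
line-of-sight winners, and session-scoped generated cohorts."""

import numpy as np
import pytest

from presigmoid import CohortConfig, generate_cohort
from presigmoid.landmarks import Disc3, SpecimenLandmarks

# IAC axis: 25 degrees anterior of lateral, in the transverse plane
_IAC_DIR = np.array([np.sin(np.radians(25.0)), 0.0, np.cos(np.radians(25.0))])


def make_reference_specimen() -> SpecimenLandmarks:
    """A specimen with exact axis-aligned anatomy.

    The tegmen is the plane y = 12, the craniotomy plane is z = 24, the
    intrinsic frame is exactly the canonical axes, and each line-of-sight
    rule has a single unambiguous winner:
    L1 sinus anterior border, L2 sinodural angle, L3 rim, L4 facial
    nerve, L5 rim, L6 sinus.
    """
    c_iac = np.array([-22.0, 0.0, 16.0])
    r_s = 6.0
    u_dir = c_iac / np.linalg.norm(c_iac)
    thetas = 2.0 * np.pi * np.arange(16) / 16.0
    rim = np.column_stack([
        -9.0 + 23.0 * np.cos(thetas),
        1.0 + 10.5 * np.sin(thetas),
        np.full(16, 24.0),
    ])
    return SpecimenLandmarks(
        specimen_id="REF", side="right",
        P=np.zeros(3),
        iac_mid=5.0 * _IAC_DIR,
        iac_anterolateral=10.5 * _IAC_DIR + np.array([0.5, 0.0, 0.0]),
        ss_anterior_above_iac=c_iac + np.array([r_s, 0.0, 0.0]),
        ss_cross_iac=Disc3(c_iac, r_s),
        ss_cross_bulb=Disc3(np.array([-23.0, -7.0, 17.0]), 6.5),
        ss_medial_border=c_iac - r_s * u_dir,
        fn_cross_iac=Disc3(np.array([5.0, 0.0, 9.0]), 1.0),
        fn_cross_bulb=Disc3(np.array([5.0, -7.0, 9.0]), 1.0),
        sinodural_angle=np.array([-15.0, 10.5, 17.0]),
        tegmen_points=np.array([[-20.0, 12.0, 8.0], [5.0, 12.0, 8.0],
                                [-20.0, 12.0, 22.0], [5.0, 12.0, 22.0]]),
        jugular_bulb_top=np.array([-20.0, -7.0, 14.0]),
        craniotomy_rim=rim,
        anterior_rim_point=np.array([14.0, 1.0, 16.0]),
        dura_posterior_ss=c_iac - np.array([r_s, 0.0, 0.0]),
        presigmoid_dura_sup=c_iac - r_s * u_dir + np.array([0.0, 8.0, 0.0]),
        presigmoid_dura_inf=c_iac - r_s * u_dir + np.array([0.0, -8.0, 0.0]),
    )


@pytest.fixture
def reference_specimen() -> SpecimenLandmarks:
    return make_reference_specimen()


@pytest.fixture(scope="session")
def small_cohort():
    """12 generated specimens, shared across tests."""
    return generate_cohort(CohortConfig(n_specimens=12, seed=101))


@pytest.fixture(scope="session")
def property_cohort():
    """A larger cohort for model-property sweeps."""
    return generate_cohort(CohortConfig(n_specimens=100, seed=202))
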