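import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import torsomorph as tm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def quartet_landmarks() -> tm.LandmarkSet:
    """The hand-computable landmark configuration: xiphoid anterior and T9
    posterior at z=1200, ASIS pair at z=900."""
    return tm.LandmarkSet({
        "xiphoid_process": [0.0, 100.0, 1200.0],
        "t9_vertebra": [0.0, -100.0, 1200.0],
        "asis_left": [-120.0, 60.0, 900.0],
        "asis_right": [120.0, 60.0, 900.0],
    })


@pytest.fixture(scope="session")
def small_spec() -> tm.CohortSpec:
    """Light synthetic spec for geometry tests (fewer points, still dense
    enough for every slice band)."""
    return tm.CohortSpec(n_participants=3, seed=7, point_density=0.25)


@pytest.fixture(scope="session")
def canonical_torso(small_spec):
    """One synthetic torso in canonical pose (no rigid jitter), with its
    ground-truth amplitudes."""
    import dataclasses
    spec = dataclasses.replace(small_spec, rigid_jitter=False)
    amps = np.array([0.03, -0.02, 0.015])
    cloud, landmarks = tm.generate_torso(spec, 0, amplitudes=amps)
    return spec, cloud, landmarks, amps


@pytest.fixture(scope="session")
def descriptor_cohort_43():
    """Descriptor matrix + anthro table for a 43-participant cohort via the
    fast analytic-profile route (shared across statistics tests)."""
    spec = tm.CohortSpec(n_participants=43, seed=17)
    matrix, anthro, truth = tm.generate_descriptor_cohort(spec)
    return spec, matrix, anthro, truth
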