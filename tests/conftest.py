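import numpy as np
import pytest

from scapkin.synthetic_cohort import ParticipantSpec, TrialPlan, simulate_trial


@pytest.fixture
def physiological_participant() -> ParticipantSpec:
    """Unimpaired mover: physiological scapulohumeral rhythm, no noise."""
    return ParticipantSpec(
        id="P1",
        scala_ratio=0.5,
        compensation_slope=0.15,
        marker_noise_sd=0.0,
        peak_sd=0.0,
    )


@pytest.fixture
def flexion_plan() -> TrialPlan:
    return TrialPlan(
        participant="P1", condition="none", direction="flexion", repetition=1, seed=7
    )


@pytest.fixture
def clean_trial(physiological_participant, flexion_plan):
    """One noise-free flexion elevation with ground-truth angles."""
    return simulate_trial(physiological_participant, flexion_plan)


def random_pose(rng: np.random.Generator) -> dict[str, float]:
    """A random, non-degenerate arm/trunk/scapula pose (degrees)."""
    theta_g = rng.uniform(10.0, 150.0)
    rho = rng.uniform(-30.0, 40.0)
    return {
        "theta_gh": theta_g - rho,
        "rho": rho,
        "kappa": rng.uniform(-15.0, 30.0),
        "alpha": rng.uniform(5.0, 175.0),
    }
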