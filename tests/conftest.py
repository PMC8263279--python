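import numpy as np
import pytest

from fnirsdbn.pipeline import RunConfig, run_study
from fnirsdbn.simulate import SimulationConfig, SubjectProfile


@pytest.fixture
def uniform_profile():
    """A subject with no idiosyncrasy: unit gains, uniform lateralization."""
    return SubjectProfile(
        subject_id="U1",
        channel_gains=np.ones(16),
        lateral_exponents=np.ones(16),
        amplitude_scale=1.0,
        hrf_jitter_s=0.0,
        seed_offset=0,
    )


@pytest.fixture
def small_config():
    return SimulationConfig(
        n_subjects=2, trials_per_task_per_session=3, seed=11
    )


def _study_conditions(seed: int) -> RunConfig:
    """The reduced-scale study the end-to-end checks run under: 10 subjects,
    10 trials per task per session, fixed (10, 10) architecture."""
    return RunConfig(
        simulation=SimulationConfig(
            n_subjects=10, trials_per_task_per_session=10
        ),
        fixed_arch=(10, 10),
        seed=seed,
    )


@pytest.fixture(scope="session")
def study_results():
    """Full study runs for five seeds (shared across end-to-end tests)."""
    return {seed: run_study(_study_conditions(seed)) for seed in range(1, 6)}
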