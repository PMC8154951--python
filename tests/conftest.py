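import numpy as np
import pytest

import lexigaze as lg
from lexigaze.simulate import CohortSpec, InfantProfile


@pytest.fixture(scope="session")
def design():
    return lg.default_design("vowel", "action", rng_seed=0)


@pytest.fixture(scope="session")
def object_design():
    return lg.default_design("consonant", "object", rng_seed=1)


@pytest.fixture(scope="session")
def aois():
    return lg.default_test_aois()


@pytest.fixture(scope="session")
def fam_aois():
    return lg.default_familiarization_aois()


@pytest.fixture(scope="session")
def schedule(design):
    return lg.build_test_trials(design, rng_seed=5)


def make_samples(times, xs, ys, valid=None):
    """Build a sample table from parallel coordinate lists."""
    t = np.asarray(times, dtype=float)
    return {
        "time_ms": t,
        "x_px": np.asarray(xs, dtype=float),
        "y_px": np.asarray(ys, dtype=float),
        "valid": np.ones_like(t, dtype=int) if valid is None else np.asarray(valid, int),
    }


@pytest.fixture
def samples_factory():
    return make_samples


def ceiling_cohort(latency_ms: float) -> CohortSpec:
    """Cohort whose gaze is fully lateralized after a near-deterministic latency."""
    base = InfantProfile(
        preference_theta=1.0,
        refixation_rate=0.0,
        p_missing_sample=0.0,
        p_invalid_trial=0.0,
        center_latency_mean_ms=latency_ms,
        center_latency_sd_ms=5.0,
        saccade_gap_ms=0.0,
    )
    return CohortSpec(
        base=base,
        theta_mean=1.0,
        theta_sd=0.0,
        latency_mean_sd_ms=0.0,
        p_invalid_mean=0.0,
        p_invalid_concentration=0.0,
    )
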