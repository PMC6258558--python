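import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ornplume as op

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params8():
    return op.PlumeParams(d=8)


@pytest.fixture(scope="session")
def bounds8(params8):
    return op.derive_timescales(params8)


@pytest.fixture(scope="session")
def logistic_encoder():
    """Saturating Poisson encoder used throughout the recovery tests."""
    return op.make_saturating_encoder(
        r_max=100.0, s_half=0.2, slope=4.0, r0=5.0, theta=0.026
    )


@pytest.fixture(scope="session")
def logistic_samples(params8, logistic_encoder):
    """~4000 pooled responses from the logistic encoder at 8 m.

    Twice the minimal pooled size, so Monte-Carlo noise stays clear of the
    recovery tolerances asserted against it.
    """
    recordings = op.simulate_population(logistic_encoder, params8, 64, 500.0, seed=0)
    return op.extract_group_responses(recordings, logistic_encoder.theta)


@pytest.fixture(scope="session")
def logistic_fit(logistic_samples):
    return op.fit_encoding_model(logistic_samples)


def make_periodic_sequence(blank_s, whiff_s, n_pairs, params=None):
    """Deterministic alternating sequence with fixed blank/whiff durations."""
    onsets, durations, kinds = [], [], []
    t = 0.0
    for _ in range(n_pairs):
        onsets.append(t); durations.append(blank_s); kinds.append(op.BLANK)
        t += blank_s
        onsets.append(t); durations.append(whiff_s); kinds.append(op.WHIFF)
        t += whiff_s
    return op.StimulusSequence(
        onsets=np.array(onsets),
        durations=np.array(durations),
        kinds=np.array(kinds),
        total_duration=t,
        params=params,
    )
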