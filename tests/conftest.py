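import numpy as np
import pytest

from anihrv import SynthConfig, gen_cohort


@pytest.fixture(scope="session")
def clean_cohort():
    """Small noiseless cohort: no RR noise, no artifacts, no rater noise."""
    return gen_cohort(
        SynthConfig(
            n_patients=4,
            duration_s=900,
            seed=7,
            rr_noise_sd_ms=0.0,
            artifact_rate=0.0,
            rater_noise_sd=0.0,
        )
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the default (noisy) generator settings."""
    return gen_cohort(SynthConfig(n_patients=3, duration_s=600, seed=3))


@pytest.fixture
def constant_rr():
    from anihrv import RRSeries

    rr = np.full(20, 800.0)
    t = np.cumsum(rr) / 1000.0
    return RRSeries(beat_time_s=t, rr_ms=rr)
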