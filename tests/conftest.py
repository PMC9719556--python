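import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from iseseg import IseKaryotype, SegParams, SimConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def four_ise_karyotype() -> IseKaryotype:
    """A clone resembling the four-ISE configuration (female 2C 506 Mb)."""
    return IseKaryotype(
        n_ise=4, female_2c_mb=506.0, core_1c_mb=180.0, clone_id="sim4"
    )


@pytest.fixture
def one_ise_karyotype() -> IseKaryotype:
    """A single-ISE clone (two male GS classes, female 2C 444 Mb)."""
    return IseKaryotype(
        n_ise=1, female_2c_mb=444.0, core_1c_mb=190.0, clone_id="sim1"
    )


@pytest.fixture
def biased_params() -> SegParams:
    """Drive plus repulsion, the pattern typical of the inbred line."""
    return SegParams(tb=0.15, cb=-0.35)


def make_sim_config(karyotype, params, seed, **overrides) -> SimConfig:
    defaults = dict(
        n_males=2000,
        n_events_per_male=5,
        female_events=2000,
        cv_percent=2.5,
        background_fraction=0.05,
    )
    defaults.update(overrides)
    return SimConfig(karyotype=karyotype, params=params, seed=seed, **defaults)
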