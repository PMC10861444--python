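import math

import numpy as np
import pytest

from opmsim.config import SystemConfig
from opmsim.fixtures import generate_fixture_transmission


@pytest.fixture(scope="session")
def table_config():
    """Published main configuration with synthetic transmission fixtures."""
    from opmsim.sweep import default_table_config

    return default_table_config(seed=1)


@pytest.fixture()
def small_config():
    """Fast configuration for pipeline-level unit tests (seconds, not minutes)."""
    return SystemConfig(
        na1=1.35, n1=1.404, na2=0.95, n2=1.0, na3=1.0, n3=1.52,
        alpha=math.radians(30.0),
        o3_coupling="ar_coated",
        transmission={
            "o2": generate_fixture_transmission("dry_like"),
            "o3": generate_fixture_transmission("agy_like"),
        },
        n_dipoles=20,
        n_noise_realizations=3,
        seed=7,
        grid_shape=(65, 49, 49),
        pitch_xy=110.0,
        pitch_z=240.0,
        pupil_samples=65,
    )


@pytest.fixture()
def lossless_config():
    """Index-matched, untilted-equivalent lossless relay for energy checks."""
    return SystemConfig(
        na1=0.9, n1=1.0, na2=0.95, n2=1.0, na3=1.0, n3=1.0,
        alpha=math.radians(30.0), o3_coupling="matched",
        grid_shape=(33, 33, 33), pupil_samples=33,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
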