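import numpy as np
import pytest

from poaf_twin.synth_cohort import GroundTruthConfig, generate_cohort
from poaf_twin.twin_builder import (
    ApdCache,
    CalibrationConfig,
    FiberCache,
    build_twins,
)
from poaf_twin.risk_models import score_panel


@pytest.fixture(scope="session")
def gt_config() -> GroundTruthConfig:
    return GroundTruthConfig()


@pytest.fixture(scope="session")
def calib_config() -> CalibrationConfig:
    return CalibrationConfig()


@pytest.fixture(scope="session")
def apd_cache(calib_config) -> ApdCache:
    """APD90-vs-s_Kr forward map (17 full ODE runs, shared session-wide)."""
    return ApdCache(config=calib_config)


@pytest.fixture(scope="session")
def fiber_cache() -> FiberCache:
    return FiberCache()


@pytest.fixture(scope="session")
def cohort_small(gt_config):
    return generate_cohort(gt_config, n=500, seed=7)


@pytest.fixture(scope="session")
def cohort_10k(gt_config):
    """The acceptance-scale cohort (untreated outcomes drawn in-generator)."""
    return generate_cohort(gt_config, n=10_000, seed=11)


@pytest.fixture(scope="session")
def twins_10k(cohort_10k, calib_config, apd_cache, fiber_cache):
    return build_twins(cohort_10k, calib_config,
                       apd_cache=apd_cache, fiber_cache=fiber_cache)


@pytest.fixture(scope="session")
def panel_10k(cohort_10k, twins_10k):
    return score_panel(cohort_10k, twins_10k)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
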