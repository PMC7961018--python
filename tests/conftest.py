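import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def small_cohort():
    """A modest synthetic cohort shared across tests (null scenario)."""
    from mixge import scenario, simulate_cohort

    cfg = scenario("null", n_subjects=120, n_snps=10, seed=7)
    cohort, gm, truth = simulate_cohort(cfg)
    return cohort, gm, truth


@pytest.fixture()
def fitted_design(small_cohort):
    from mixge.core import build_design, fit_null_model

    cohort, gm, _ = small_cohort
    d = build_design(cohort, gm, "volume")
    return d, fit_null_model(d)
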