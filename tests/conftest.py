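import numpy as np
import pytest

from voxelsurv import PipelineConfig, SyntheticSpec, generate_cohort
from voxelsurv.ensembles import EnsembleSpec


def small_spec(**kw):
    """Small, fast cohort spec used across unit tests."""
    base = dict(n_subjects=60, n_sites=2, grid_shape=(8, 8, 8), seed=0)
    base.update(kw)
    return SyntheticSpec(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_spec(seed=5))


@pytest.fixture(scope="session")
def small_config():
    """Cheap pipeline config matched to the small cohort."""
    return PipelineConfig(
        sigma_mm=4.0,
        subsample_mm=6.0,
        ensemble=EnsembleSpec("none", 1),
        k_folds=5,
        n_inner_folds=4,
        seed=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def tie_free_survival(rng, n, beta_x=0.8, censor_q=0.75):
    """Continuous (tie-free) two-group exponential survival data; with no
    ties Breslow and Efron likelihoods coincide, so lifelines is a valid
    cross-check for our Breslow fits."""
    x = (rng.random(n) < 0.5).astype(float)
    t = rng.exponential(np.exp(-beta_x * x))
    cut = np.quantile(t, censor_q)
    e = t < cut
    t = np.minimum(t, cut) + rng.uniform(0, 1e-9, n)
    return x, t, e
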