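import dataclasses

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", max_examples=50, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from foldpool.store import ParameterSet, SamplingPlan
from foldpool.synthetic import DEFAULT_PROFILES, GeneratorConfig, generate_benchmark


def small_plan() -> SamplingPlan:
    """A 3-set, 108-record plan covering the weak 3-recycle set."""
    return SamplingPlan("small", (
        ParameterSet("afm_basic", templates=True, n_nn_models=3, samples_per_model=12),
        ParameterSet("afm_dropout_noSM_woTemplates", dropout_evoformer=True,
                     n_nn_models=3, samples_per_model=12),
        ParameterSet("afm_dropout_full_woTemplates_r3", dropout_evoformer=True,
                     dropout_structure_module=True, recycles=3,
                     n_nn_models=3, samples_per_model=12),
    ))


def small_profiles():
    """Default effect sizes with outlier counts scaled to the small pool.

    With 108-record pools the default 10-40 outliers would dominate the top
    quartile; 2-4 keeps the outliers outliers.
    """
    profs = dict(DEFAULT_PROFILES)
    profs["hard"] = dataclasses.replace(profs["hard"], n_outliers=(2, 4))
    return profs


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_easy=5, n_hard=3, n_extreme=2, plan=small_plan(),
                           seed=11, profiles=small_profiles())


@pytest.fixture(scope="session")
def small_benchmark(small_config):
    return generate_benchmark(small_config)


@pytest.fixture(scope="session")
def full_hard_benchmark():
    """One hard interface sampled with the full 8040-record production plan."""
    return generate_benchmark(GeneratorConfig(n_easy=0, n_hard=1, n_extreme=0, seed=5))
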