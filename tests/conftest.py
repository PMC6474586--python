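import numpy as np
import pytest
from hypothesis import settings

import sigreverse as sr

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-gene disease/normal cohort with a quarter of genes affected."""
    return sr.generate_disease_cohort(
        600, n_disease=6, n_normal=11, effect_sd=1.0, affected_fraction=0.25,
        noise_sd=0.3, seed=42, cohort_id="uc",
    )


@pytest.fixture(scope="session")
def small_signature(small_cohort):
    return sr.build_signature(small_cohort.matrix, small_cohort.design, signature_id="uc")


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Noise-free cohort: group-mean differences equal the truth vector exactly."""
    return sr.generate_disease_cohort(
        600, n_disease=3, n_normal=3, effect_sd=1.0, affected_fraction=0.5,
        noise_sd=0.0, seed=7, cohort_id="clean",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
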