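import dataclasses

import pytest

from bracenorms import CohortSpec, generate_cohort
from bracenorms.published import load_published_model


@pytest.fixture(scope="session")
def published():
    return load_published_model()


@pytest.fixture(scope="session")
def reference_spec():
    """Study-condition reference cohort: n=1063, no target group."""
    return CohortSpec(n_reference=1063, n_target=0, seed=20260921)


@pytest.fixture(scope="session")
def reference_cohort(reference_spec):
    return generate_cohort(reference_spec)


@pytest.fixture()
def small_spec():
    """A fast cohort for pipeline-level tests."""
    return CohortSpec(n_reference=150, n_target=80, seed=7)


@pytest.fixture()
def make_spec():
    def _make(**overrides):
        return dataclasses.replace(CohortSpec(), **overrides)

    return _make
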