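"""Shared fixtures: small simulated cohorts reused across test modules."""

import pytest

from ampliscreen import simulate_cohort, small_config


@pytest.fixture(scope="session")
def small_cohort():
    """A scaled-down clean cohort (no injected lesions), seed 42."""
    return simulate_cohort(small_config(42))


@pytest.fixture(scope="session")
def small_sample(small_cohort):
    return small_cohort.samples[0]
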