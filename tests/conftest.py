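import numpy as np
import pytest

from cutscan import BinaryTrait, CohortTrait, SurvivalOutcome


def ids(n, prefix="S"):
    return np.array([f"{prefix}{i:03d}" for i in range(n)], dtype=object)


@pytest.fixture
def toy_trait():
    """Ten samples with values 1..10 in order."""
    return CohortTrait(ids(10), np.arange(1.0, 11.0), name="toy")


@pytest.fixture
def toy_outcome():
    """Ten samples, times 1..10, all events."""
    return SurvivalOutcome(ids(10), np.arange(1.0, 11.0), np.ones(10, dtype=int))


@pytest.fixture
def planted_cohort():
    """A cohort with a hazard jump planted at the 75th expression percentile."""
    from cutscan import SyntheticSpec, gen_survival_cohort
    return gen_survival_cohort(SyntheticSpec(n=300, seed=2024))


def make_trait(values, name="t"):
    values = np.asarray(values, dtype=float)
    return CohortTrait(ids(values.size), values, name=name)


def make_outcome(times, events):
    times = np.asarray(times, dtype=float)
    return SurvivalOutcome(ids(times.size), times, np.asarray(events))


def make_binary(groups):
    groups = np.asarray(groups)
    return BinaryTrait(ids(groups.size), groups)
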