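import numpy as np
import pytest

from inhalerdce.cohort import (
    CohortConfig,
    cohort_to_frame,
    default_cohort_config,
    generate_respondents,
)
from inhalerdce.design import search_design
from inhalerdce.model import ModelSpec
from inhalerdce.schema import AttributeSpec, inhaler_schema
from inhalerdce.simulate import TrueModel, simulate_study_frame


@pytest.fixture(scope="session")
def attrs():
    return inhaler_schema()


@pytest.fixture(scope="session")
def tiny_attrs():
    """A two-attribute schema small enough for brute-force oracles."""
    return [
        AttributeSpec("color", "categorical", ("red", "blue"), reference_level="blue"),
        AttributeSpec("price", "continuous", (0.0, 1.0, 2.0)),
    ]


@pytest.fixture(scope="session")
def design36(attrs):
    """The study-sized design: 36 sets in 3 blocks of 12."""
    return search_design(attrs, 36, 3, seed=11, n_restarts=10)


@pytest.fixture(scope="session")
def cohort():
    return generate_respondents(default_cohort_config(), seed=2)


@pytest.fixture(scope="session")
def cohort_df(cohort):
    return cohort_to_frame(cohort)


@pytest.fixture(scope="session")
def asthma_frame(cohort, design36):
    """Simulated rankings for the asthma group at published utilities."""
    asthma = [r for r in cohort if r.disease == "asthma"]
    model = TrueModel.asthma_defaults(sigma_re=0.5)
    return simulate_study_frame(asthma, design36, model, seed=3)


@pytest.fixture(scope="session")
def spec(attrs):
    return ModelSpec(attributes=attrs, quadrature_nodes=15)
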