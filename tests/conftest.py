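import hypothesis
import numpy as np
import pandas as pd
import pytest

from milkmr import CohortConfig, OutcomeSpec, simulate_cohort
from milkmr.datasets import phecode_map_mini

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def mini_map():
    return phecode_map_mini()


@pytest.fixture(scope="session")
def cataract_spec():
    return OutcomeSpec(
        phecode="366",
        baseline_prevalence=0.10,
        log_or_per_50g=-0.12,
        icd_codes=(("H25.1", "ICD10"), ("3669", "ICD9")),
    )


@pytest.fixture(scope="session")
def small_cohort(mini_map, cataract_spec):
    """One 20k-person cohort with a single cataract-like outcome."""
    config = CohortConfig(n_individuals=20_000, seed=7, outcome_specs=(cataract_spec,))
    return simulate_cohort(config, mini_map)
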