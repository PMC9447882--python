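import numpy as np
import pandas as pd
import pytest

from ohca_interact import CohortConfig, EffectModel, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 3000-record pre-filter cohort with default settings."""
    return generate_cohort(CohortConfig(n_records=3000, seed=123))


@pytest.fixture(scope="session")
def included_cohort() -> pd.DataFrame:
    """A 2500-record cohort with no filter-eligible exclusions."""
    cfg = CohortConfig(
        n_records=2500, exclusion_under18=0.0, exclusion_noncardiogenic=0.0, seed=7
    )
    return generate_cohort(cfg)


def logistic_stub(effects: EffectModel):
    """Deterministic predictor stub: the generative model itself."""
    from ohca_interact import true_outcome_probability

    def predict(records: pd.DataFrame) -> np.ndarray:
        return np.asarray(true_outcome_probability(records, effects), dtype=float)

    return predict
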