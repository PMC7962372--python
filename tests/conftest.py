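import numpy as np
import pandas as pd
import pytest

from dietfrail.simulate import SimulationConfig, generate_cohort, simulate_study


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """500-participant synthetic cohort without follow-up."""
    return generate_cohort(SimulationConfig(n=500, seed=42))


@pytest.fixture(scope="session")
def study_cohort() -> pd.DataFrame:
    """4000-participant cohort with frailty, NI and follow-up attached."""
    cfg = SimulationConfig(
        n=4000, seed=7, diet_beta=float(np.log(1.15)), baseline_hazard=0.008
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def scored_cohort(study_cohort) -> pd.DataFrame:
    """The study cohort with all eight score columns appended."""
    from dietfrail.scoring import score_all

    return score_all(study_cohort)
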