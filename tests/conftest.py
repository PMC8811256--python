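import numpy as np
import pandas as pd
import pytest

from trlim import quantgen as qg
from trlim import synthetic_data as sd


@pytest.fixture(scope="session")
def small_map() -> qg.GeneticMap:
    return sd.default_map(n_chromosomes=2, n_markers=20, spacing_cm=5.0)


@pytest.fixture(scope="session")
def small_pop(small_map) -> qg.RILPopulation:
    return sd.simulate_ril(80, small_map, selfing_generations=2, seed=11)


@pytest.fixture(scope="session")
def study_pop() -> qg.RILPopulation:
    """Population at the study scale: 120 lines, 5 chromosomes x 50 markers."""
    return sd.simulate_ril(120, sd.default_map(), selfing_generations=2, seed=42)


@pytest.fixture()
def balanced_weighing() -> pd.DataFrame:
    """Noise-free weighing records for three genotypes incl. both parents."""
    truth = pd.DataFrame(
        {
            "genotype": ["Jackson", "KS4895", "RIL001"],
            "tr_h2o": [1.40, 1.23, 1.10],
            "sensitivity": [0.33, 0.35, 0.10],
            "leaf_temp_c": [33.3, 32.0, 32.5],
        }
    )
    df, _ = sd.simulate_weighing(truth, n_sets=2, n_reps=2, noise=0.0, set_sd=0.0, seed=0)
    return df
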