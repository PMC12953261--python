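import numpy as np
import pandas as pd
import pytest

from depcascade.cohort import CohortTable, GeneratorSpec, sample_cohort


@pytest.fixture(scope="session")
def clean_cohort() -> CohortTable:
    """Reference synthetic cohort, no missingness."""
    return sample_cohort(GeneratorSpec(n_total=581, n_depressed=90, seed=1))


@pytest.fixture(scope="session")
def missing_cohort() -> CohortTable:
    """Reference cohort with 5% MCAR missingness."""
    return sample_cohort(GeneratorSpec(n_total=581, n_depressed=90, seed=1,
                                       missing_rate=0.05))


def make_separable_table(
    n: int = 600,
    shift: float = 3.0,
    n_informative: int = 3,
    n_noise: int = 20,
    seed: int = 0,
    pos_fraction: float = 0.3,
) -> CohortTable:
    """Two-group continuous table with a mean shift on the informative
    features, wrapped as a CohortTable so the model pipelines accept it."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < pos_fraction).astype(int)
    cols = {}
    dictionary = {}
    for j in range(n_informative):
        cols[f"inf{j}"] = rng.standard_normal(n) + shift * y
        dictionary[f"inf{j}"] = {"modality": "lab", "vtype": "continuous", "units": ""}
    for j in range(n_noise):
        cols[f"noise{j}"] = rng.standard_normal(n)
        dictionary[f"noise{j}"] = {"modality": "lab", "vtype": "continuous", "units": ""}
    df = pd.DataFrame({"participant_id": [f"S{i}" for i in range(n)],
                       "diagnosis": y, "subtype": None, **cols})
    return CohortTable(df=df, dictionary=dictionary)


def make_xor_frame(n: int = 500, n_noise: int = 8, seed: int = 0):
    """Complementary pair: f0 carries a weak marginal signal, f1 is informative
    only jointly with f0 (soft XOR); the rest is pure noise."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    f0 = 0.8 * y + rng.standard_normal(n)
    z = y ^ (f0 > np.median(f0)).astype(int)
    f1 = (2 * z - 1) + 0.5 * rng.standard_normal(n)
    cols = {"f0": f0, "f1": f1}
    for j in range(n_noise):
        cols[f"noise{j}"] = rng.standard_normal(n)
    return pd.DataFrame(cols), y
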