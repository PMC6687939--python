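import numpy as np
import pandas as pd
import pytest

from sipsyn import thermo
from sipsyn.enrichment import CountMatrix

CONDITION_MAP = {"12C_rep1": "12C", "12C_rep2": "12C", "13C_rep1": "13C", "13C_rep2": "13C"}


@pytest.fixture(scope="session")
def species_table():
    return thermo.default_species_table()


@pytest.fixture(scope="session")
def butyrate_reaction():
    return thermo.BUTYRATE_OXIDATION


@pytest.fixture
def bioreactor_conditions():
    """pH 7, 1 mM butyrate and acetate, 1 Pa H2, 298.15 K."""
    return thermo.EnvironmentalConditions(
        temperature=298.15,
        pH=7.0,
        activities={"butyrate": 1e-3, "acetate": 1e-3, "H2": 1e-5},
    )


def make_count_matrix(arr, features=None):
    """2-vs-2 CountMatrix from an array of shape (n_features, 4)."""
    arr = np.asarray(arr)
    features = features or [f"f{i + 1}" for i in range(arr.shape[0])]
    counts = pd.DataFrame(arr, index=features, columns=list(CONDITION_MAP))
    return CountMatrix(counts=counts, conditions=dict(CONDITION_MAP),
                       replicates={s: s[-1] for s in CONDITION_MAP})


def simulate_null_counts(n_features, depth, dispersion, seed, fold_change=None):
    """NB counts with identical expectations in both conditions.

    ``fold_change`` (per-feature array) multiplies the 13C expectation.
    """
    rng = np.random.default_rng(seed)
    shares = rng.lognormal(0.0, 1.0, n_features)
    shares /= shares.sum()
    mu = depth * shares
    fc = np.ones(n_features) if fold_change is None else np.asarray(fold_change, float)
    size = 1.0 / dispersion
    cols = []
    for cond_mu in (mu, mu, mu * fc, mu * fc):
        cols.append(rng.negative_binomial(size, size / (size + cond_mu)))
    return make_count_matrix(np.column_stack(cols))
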