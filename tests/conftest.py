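import numpy as np
import pandas as pd
import pytest

from skinqspr import (
    CompoundDescriptors,
    Dataset,
    GeneratorConfig,
    PermeabilityRecord,
    generate,
    load_registry,
)


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_rows(beta, X, noise=None):
    """Labelled regression rows from coefficients and a descriptor matrix."""
    X = np.asarray(X, dtype=float)
    y = beta[0] + X @ np.asarray(beta[1:], dtype=float)
    if noise is not None:
        y = y + noise
    return pd.DataFrame(
        {
            "compound_id": [f"c{i}" for i in range(len(X))],
            "log_p": X[:, 0],
            "tpsa": X[:, 1],
            "mv": X[:, 2],
            "log_kp": y,
        }
    )


def random_design(rng, n):
    """Descriptor matrix on realistic scales."""
    return np.column_stack(
        [
            rng.uniform(-4, 5, n),
            rng.uniform(0, 160, n),
            rng.uniform(50, 500, n),
        ]
    )


@pytest.fixture
def small_dataset():
    """Five records over three compounds, with one incomplete record."""
    records = [
        PermeabilityRecord("c1", -5.0, skin_source="abdomen", skin_layer="epidermis",
                           donor_concentration="diluted", donor_temperature_c=22.0, donor_ph=7.2),
        PermeabilityRecord("c1", -5.5, skin_source="breast", skin_layer="dermis",
                           donor_concentration="concentrated", donor_temperature_c=37.0, donor_ph=5.0),
        PermeabilityRecord("c2", -6.0, skin_source="abdomen", skin_layer="epidermis+dermis",
                           donor_concentration="concentrated", donor_temperature_c=32.0, donor_ph=7.4),
        PermeabilityRecord("c2", -6.2, skin_source="thigh", skin_layer="epidermis",
                           donor_concentration="diluted", donor_temperature_c=None, donor_ph=None),
        PermeabilityRecord("c3", -4.5, skin_source="abdomen", skin_layer="epidermis",
                           donor_concentration="diluted", donor_temperature_c=24.0, donor_ph=7.0),
    ]
    descriptors = {
        "c1": CompoundDescriptors("c1", 2.0, 30.0, 150.0),
        "c2": CompoundDescriptors("c2", -1.0, 90.0, 80.0),
        "c3": CompoundDescriptors("c3", 0.5, 60.0, 200.0),
    }
    return Dataset(records=records, descriptors=descriptors)


@pytest.fixture
def noisy_single_scenario():
    cfg = GeneratorConfig(
        n_compounds=200, records_per_compound=(1, 1), noise_sd=0.3, seed=11
    )
    return generate(cfg)
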