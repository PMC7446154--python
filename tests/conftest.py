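import pytest

from varboost import SimulationConfig, simulate_dataset
from varboost.preprocessing import attach_labels, encode_features, fit_feature_schema


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small well-separated simulated dataset shared across tests."""
    config = SimulationConfig(
        n_pathogenic=80, n_neutral=80, informative_shift=3.0, seed=11
    )
    return config, simulate_dataset(config)


@pytest.fixture(scope="session")
def tiny_matrix(tiny_dataset):
    config, ds = tiny_dataset
    schema = fit_feature_schema(ds.annotations, config.manifest)
    matrix = attach_labels(
        encode_features(ds.annotations, ds.af_lookup, schema), ds.variants
    )
    return schema, matrix
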