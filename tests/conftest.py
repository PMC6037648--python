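import pytest
from hypothesis import settings

import gh57
from gh57.pipeline import PipelineConfig, detect_records, train_profile_sets

settings.register_profile("suite", deadline=None, derandomize=True, database=None)
settings.load_profile("suite")

# A reduced study: every group present, ~130 sequences, quick to generate.
SMALL_COUNTS = {
    "AAMY": 20, "AAMY-like": 10, "4AGT": 12, "4AGT-like": 6,
    "APU": 15, "APU-CMD": 6, "APU-CMD-like": 2, "MGA": 6,
    "AGAL-related": 5, "AGAL": 5, "MGA-like": 1, "NSA": 12,
    "GBE-like": 6, "GBE": 25,
}


@pytest.fixture(scope="session")
def schema():
    return gh57.default_schema()


@pytest.fixture(scope="session")
def catalogue():
    return gh57.default_catalogue()


@pytest.fixture(scope="session")
def rules():
    return gh57.default_rules()


@pytest.fixture(scope="session")
def small_dataset():
    return gh57.generate_dataset(
        gh57.SyntheticConfig(seed=7, counts=SMALL_COUNTS, dropout_fraction=0.0)
    )


@pytest.fixture(scope="session")
def small_profiles(small_dataset):
    return train_profile_sets(small_dataset)


@pytest.fixture(scope="session")
def consensus():
    return gh57.build_group_consensus(seed=1602)


@pytest.fixture(scope="session")
def default_dataset():
    """The full default study conditions: 1602 sequences plus decoys."""
    return gh57.generate_dataset(gh57.SyntheticConfig(seed=1602))


@pytest.fixture(scope="session")
def default_profiles(default_dataset):
    return train_profile_sets(default_dataset)


@pytest.fixture(scope="session")
def default_detection(default_dataset, default_profiles):
    """Detection table for the full default dataset (shared across tests)."""
    records = [(s.id, s.sequence) for s in default_dataset.sequences]
    return detect_records(records, default_profiles, PipelineConfig())
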