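from importlib.resources import files

import pytest

from operonpp.pipeline import run_pipeline
from operonpp.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study (noise-free profiles, fixed seed)."""
    return simulate_dataset(SimConfig(seed=7))


@pytest.fixture(scope="session")
def default_result(default_dataset):
    ds = default_dataset
    return run_pipeline(
        ds.features, ds.counts, ds.og_profiles, ds.gene_to_og,
        ds.coverage_plus, ds.coverage_minus, categories=ds.categories,
    )


@pytest.fixture(scope="session")
def fold_change_table_path():
    """The published TNFa response fold-change table shipped with the package."""
    return files("operonpp") / "data" / "tnfa_fold_changes.tsv"
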