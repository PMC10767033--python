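import numpy as np
import pytest

from wsbbo.enrichment import label, read_filter, split_negatives, load_count_table
from wsbbo.ensemble import PredictorConfig, train_ensemble
from wsbbo.synthetic import default_landscape, simulate_panning


@pytest.fixture(scope="session")
def landscape():
    return default_landscape(seed=1)


@pytest.fixture(scope="session")
def count_table(landscape):
    return simulate_panning(landscape, n_variants=2000, reads_per_pool=200_000, seed=1)


@pytest.fixture(scope="session")
def count_records(count_table, tmp_path_factory):
    path = tmp_path_factory.mktemp("counts") / "counts.csv"
    count_table[["sequence", "count_eluted", "count_ns"]].to_csv(path, index=False)
    return load_count_table(path)


@pytest.fixture(scope="session")
def labeled_dataset(count_records):
    return split_negatives(label(read_filter(count_records)), k=5, seed=2)


@pytest.fixture(scope="session")
def toy_ensemble(labeled_dataset):
    config = PredictorConfig(
        architecture="logistic", epochs=200, learning_rate=0.05,
        seed=3, alphabet="ACDE", l2=0.05,
    )
    return train_ensemble(labeled_dataset, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
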