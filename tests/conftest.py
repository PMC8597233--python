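import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import promforest as pf
from promforest.dataset import split_train_test
from promforest.model import GRID_FAST

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def benchmark():
    """Canonical synthetic benchmark: 1 Mbp, 500 planted promoters."""
    return pf.default_benchmark()


@pytest.fixture(scope="session")
def benchmark_split(benchmark):
    """75/25 stratified split of the 1:10 training set."""
    return split_train_test(benchmark.train_set, 0.25, seed=0)


@pytest.fixture(scope="session")
def hot_model(benchmark_split):
    """Fast-profile RF-HOT trained on the benchmark's 75% split."""
    train, _ = benchmark_split
    model, report = pf.train_rf(
        pf.encode_set(train, "HOT"), grid=GRID_FAST, folds=3, seed=0
    )
    return model, report


@pytest.fixture(scope="session")
def tetra_model(benchmark_split):
    """Fast-profile RF-TETRA trained on the benchmark's 75% split."""
    train, _ = benchmark_split
    model, report = pf.train_rf(
        pf.encode_set(train, "TETRA"), grid=GRID_FAST, folds=3, seed=0
    )
    return model, report


@pytest.fixture(scope="session")
def small_fixture():
    """A small planted-motif genome for scan/evaluation tests."""
    spec = pf.SyntheticSpec(genome_length=100_000, n_promoters=60, seed=3)
    genome, tss, truth = pf.generate_genome(spec)
    return spec, genome, tss, truth


@pytest.fixture(scope="session")
def small_model(small_fixture):
    """A quick single-cell RF-HOT on the small fixture's 1:10 dataset."""
    _, genome, tss, _ = small_fixture
    ds = pf.build_dataset(genome, tss, neg_per_pos=10, seed=1)
    model, _ = pf.train_rf(
        pf.encode_set(ds, "HOT"),
        grid={"max_features": ["log2"], "n_estimators": [50]},
        folds=3,
        seed=0,
    )
    return model


@pytest.fixture(scope="session")
def small_scan(small_model, small_fixture):
    """Step-20 scan of the small fixture genome."""
    _, genome, _, _ = small_fixture
    return pf.scan_genome(small_model, genome, step=20)
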