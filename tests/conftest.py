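import numpy as np
import pytest

from atacspace import (
    CellEmbeddingModel,
    FeatureSpec,
    SimConfig,
    TrainingConfig,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated dataset shared by unit tests (not the benchmark)."""
    return simulate_dataset(
        SimConfig(
            n_cells=60, n_events=120, event_len=200, genome_size=8000,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def tiny_results(small_sim):
    """A quickly trained model for downstream / io unit tests."""
    ds, truth = small_sim
    cfg = TrainingConfig(
        epochs=3, spec=FeatureSpec(k=8, N=3, bucket=20_000)
    )
    return CellEmbeddingModel(ds, cfg).fit(seed=5)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
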