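import numpy as np
import pandas as pd
import pytest

from indelmark.simulate import (
    GenomeModel,
    SimulationConfig,
    simulate_reference,
    simulate_variant_calls,
)


@pytest.fixture(scope="session")
def small_genome() -> GenomeModel:
    return GenomeModel.demo(n_chromosomes=2, length=400_000)


@pytest.fixture(scope="session")
def reference(small_genome):
    return simulate_reference(small_genome, seed=11)


@pytest.fixture(scope="session")
def dense_config() -> SimulationConfig:
    # elevated rates so small test genomes still carry a useful number of calls
    return SimulationConfig(
        indel_rate=5e-4, snp_rate=1e-3,
        het_fraction=0.05, unanchored_fraction=0.05, seed=11,
    )


@pytest.fixture(scope="session")
def sim_variants(reference, dense_config):
    return simulate_variant_calls(reference, dense_config)


@pytest.fixture(scope="session")
def marker_table() -> pd.DataFrame:
    rng = np.random.default_rng(7)
    n = 40
    ref_sizes = rng.integers(100, 400, n)
    shifts = rng.integers(5, 51, n) * rng.choice([-1, 1], n)
    return pd.DataFrame(
        {
            "marker_id": [f"M{i:03d}" for i in range(n)],
            "chrom": "chr01",
            "pos": np.sort(rng.choice(np.arange(10_000, 390_000), n, replace=False)),
            "product_size_ref": ref_sizes,
            "product_size_alt": ref_sizes + shifts,
        }
    )
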