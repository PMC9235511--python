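import numpy as np
import pandas as pd
import pytest

from methsev.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_samples=80, n_sites=600, n_islands=40, n_genes=200, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One small planted-signal cohort shared across the suite."""
    return simulate_dataset(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_manifest() -> pd.DataFrame:
    """Hand-written 9-site manifest: one island, one promoter, one body."""
    rows = [
        ("cg01", "1", 100, "isl_A", "GENE1", "Island"),
        ("cg02", "1", 150, "isl_A", "GENE1", "Island"),
        ("cg03", "1", 200, "isl_A", "GENE1", "Island"),
        ("cg04", "1", 260, "isl_A", "GENE1", "Island"),
        ("cg05", "1", 5000, "", "GENE2", "TSS200"),
        ("cg06", "1", 5100, "", "GENE2", "TSS1500"),
        ("cg07", "1", 5200, "", "GENE2", "TSS200"),
        ("cg08", "1", 9000, "", "GENE3", "Body"),
        ("cg09", "1", 9400, "", "GENE3", "5'UTR"),
    ]
    return pd.DataFrame(
        rows, columns=["probe_id", "chr", "pos", "island_id", "gene", "location_class"]
    )
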