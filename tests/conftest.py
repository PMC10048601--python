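import numpy as np
import pytest

from introprio.synthetic_data import SimulationConfig, simulate_dataset


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A compact simulation: 2 x 4 Mb chromosomes, one 2 Mb introgression."""
    kw = dict(
        n_chromosomes=2,
        chrom_length_bp=4_000_000,
        n_genes_per_chrom=8,
        introgression_segments=(("chr1", 1_000_001, 3_000_000),),
        background_rate=50.0,
        introgression_rate=1000.0,
        n_species=3,
        n_accessions_per_species=3,
        n_panel_sites_per_chrom=200,
        seed=seed,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """One simulated dataset shared by read-only tests."""
    cfg = small_config()
    return simulate_dataset(cfg, tmp_path_factory.mktemp("sim"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
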