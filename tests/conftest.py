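import numpy as np
import pytest

from peako.simulate import SimulationConfig, generate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_experiment(tmp_path_factory):
    """A compact synthetic WT/KO experiment shared by pipeline-level tests:
    80 signal peaks in a 300 kb genome, 5 decoys, tight planting (sigma 10).
    Large enough that the differential (Fisher) arm is decisively significant
    for the planted motif."""
    outdir = tmp_path_factory.mktemp("small_exp")
    cfg = SimulationConfig(
        genome_length=300_000,
        n_wt=80,
        n_ko=20,
        n_shared_noise=10,
        decoy_count=5,
        center_sigma=10.0,
        seed=7,
    )
    return cfg, generate_experiment(cfg, outdir)
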