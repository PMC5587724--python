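import numpy as np
import pytest

from ribolife import ribo, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small two-condition simulation shared across test modules."""
    cfg = simulate.SimulationConfig(
        seed=7,
        n_genes=30,
        n_replicates=2,
        footprint_reads=60_000,
        library_size=100_000,
        n_uorfs_range=(1, 3),
    )
    genome, transcripts, truth = simulate.generate_genome_annotation(cfg)
    return cfg, genome, transcripts, truth


@pytest.fixture(scope="session")
def small_footprints(small_sim):
    cfg, genome, transcripts, truth = small_sim
    return simulate.simulate_footprints(transcripts, truth, cfg, "wild_type", 1)


@pytest.fixture(scope="session")
def small_calibration(small_sim, small_footprints):
    cfg, genome, transcripts, truth = small_sim
    return ribo.infer_psite_offsets(small_footprints, transcripts)
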