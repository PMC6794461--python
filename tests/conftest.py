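import pytest

from abrep import numbering, sim


@pytest.fixture(scope="session")
def toy_germline():
    genes = sim.make_toy_germline(1)
    numbering.register_toy_tables(genes)
    return genes


@pytest.fixture(scope="session")
def noise_free_sim(toy_germline):
    """A small repertoire with every error process switched off."""
    cfg = sim.SimulationConfig(
        seed=11, n_cells=30, germline=toy_germline, shm_rate=0.0,
        pcr_error_rate=0.0, seq_miscall_scale=0.0,
        mrna_per_cell_mean=2, pcr_duplicates_mean=2, fixed_counts=True,
    )
    return sim.simulate_repertoire(cfg)


@pytest.fixture(scope="session")
def shm_sim(toy_germline):
    """A mutated but sequencing-error-free repertoire (SHM only)."""
    cfg = sim.SimulationConfig(
        seed=13, n_cells=60, germline=toy_germline, shm_rate=0.03,
        hotspot_multiplier=1.0, pcr_error_rate=0.0, seq_miscall_scale=0.0,
        mrna_per_cell_mean=1, pcr_duplicates_mean=1, fixed_counts=True,
    )
    return sim.simulate_repertoire(cfg)
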