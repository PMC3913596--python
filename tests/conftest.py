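import numpy as np
import pytest

from crocmhc.seq_model import SpeciesMeta


@pytest.fixture
def species_a():
    return SpeciesMeta(common_name="Saltwater crocodile",
                       scientific_name="Crocodylus porosus",
                       genus="Crocodylus", gene_prefix="Crpo")


@pytest.fixture
def species_b():
    return SpeciesMeta(common_name="Spectacled caiman",
                       scientific_name="Caiman crocodylus",
                       genus="Caiman", gene_prefix="Cacr")


@pytest.fixture
def taxonomy(species_a, species_b):
    return {m.gene_prefix: m for m in (species_a, species_b)}


def make_read(species, seq, read_id="r1", individual="i1", pcr="p1",
              direction="forward", exon="IIb_ex3"):
    from crocmhc.seq_model import CloneRead

    return CloneRead(read_id=read_id, species=species, individual_id=individual,
                     pcr_id=pcr, direction=direction, seq=seq, exon_target=exon)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset reused by several read-only tests."""
    from crocmhc.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(n_species=6, seed=7, retention_rate=0.4,
                    chimera_rate=0.0, pcr_error_rate=0.0)
    reads, truth, taxonomy = simulate_dataset(cfg)
    return cfg, reads, truth, taxonomy
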