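import numpy as np
import pytest

from barcode_gauge import distances as dist
from barcode_gauge import synthetic as syn
from barcode_gauge.align import MultipleAlignment, progressive_msa
from barcode_gauge.dataset_io import LocusDataset, SequenceRecord


def make_dataset(entries, locus="other"):
    """entries: list of (accession_id, species, sequence)."""
    return LocusDataset(
        locus=locus,
        records=[SequenceRecord(accession_id=a, species=s, locus=locus,
                                sequence=q) for a, s, q in entries],
    )


@pytest.fixture(scope="session")
def sim_small():
    """A small simulated genus with a clean barcoding gap (ratio ~6)."""
    cfg = syn.SimulationConfig(n_species=6, accessions_per_species=3,
                               root_length=300, target_intra=0.006,
                               target_inter=0.035, seed=11)
    return syn.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def sim_small_msa(sim_small):
    return progressive_msa(sim_small.dataset)


@pytest.fixture(scope="session")
def sim_small_dm(sim_small, sim_small_msa):
    return dist.distance_matrix(sim_small_msa, sim_small.dataset.species)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
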