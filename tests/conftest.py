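import logging

import numpy as np
import pytest

from trnaremold.core import TRNAGene
from trnaremold.synthetic_data import SimulationConfig, simulate

logging.getLogger("trnaremold").setLevel(logging.ERROR)


def make_gene(gene_id="g1", species="sp1", family="A", anticodon="UGC",
              sequence="ACGUACGU", structure=None, start=0, end=None,
              strand="+", genome_length=16000):
    return TRNAGene(
        gene_id=gene_id, species=species, family=family, anticodon=anticodon,
        sequence=sequence, structure=structure, start=start,
        end=end if end is not None else start + len(sequence),
        strand=strand, genome_length=genome_length,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One default simulated clade with an implanted W~>G remolding."""
    return simulate(SimulationConfig(seed=5))


@pytest.fixture(scope="session")
def null_dataset():
    """A simulated clade without any remolding event."""
    return simulate(SimulationConfig(seed=7, event=None))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
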