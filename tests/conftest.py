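import pytest
from hypothesis import settings

from araliome.simulate import (make_toy_plastome, simulate_alignment,
                               two_clade_config)

# property tests are derandomized; skip the on-disk example database
settings.register_profile("no_db", database=None)
settings.load_profile("no_db")


@pytest.fixture(scope="session")
def toy_plastome():
    """A 10 kb annotated circular toy plastome with planted ground truth."""
    record, truth = make_toy_plastome(n_genes=6, ir_length=1500, seed=0)
    return record, truth


@pytest.fixture(scope="session")
def small_sim():
    """A small two-clade simulation for unit tests (4 genes x 120 codons)."""
    cfg = two_clade_config(seed=3, n_genes=4, codons_per_gene=120)
    return simulate_alignment(cfg)


@pytest.fixture(scope="session")
def study_sim():
    """The canonical two-clade dataset (20 genes x 300 codons, seed 1)."""
    return simulate_alignment(two_clade_config(seed=1))
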