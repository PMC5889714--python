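import numpy as np
import pytest

from contigprophet.synthetic import (
    HomopolymerSpec,
    RepeatFamilySpec,
    SimGenomeConfig,
    TelomereSpec,
    simulate_genome,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20180129)


@pytest.fixture(scope="session")
def small_genome():
    """200-kb two-chromosome genome with a repeat family, a gap and homopolymers."""
    cfg = SimGenomeConfig(
        genome_size=200_000,
        n_chromosomes=2,
        repeat_families=[RepeatFamilySpec(5_000, 4, 98.0)],
        gap_runs=[2_000],
        homopolymer_runs=[HomopolymerSpec("A", 10, 4), HomopolymerSpec("T", 8, 4)],
        telomere_arrays=[TelomereSpec("TTAGGG", 3_000)],
        seed=101,
    )
    return simulate_genome(cfg)
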