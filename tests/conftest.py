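import numpy as np
import pytest

from ssrkit.io import SequenceRecord
from ssrkit.simulate import (SimulationParams, simulate_genome_pair,
                             simulate_genotype_matrix)


@pytest.fixture(scope="session")
def sim_pair():
    """Default-condition genome pair: 50 planted loci, 20 polymorphic."""
    return simulate_genome_pair(SimulationParams(seed=7))


@pytest.fixture(scope="session")
def genotype_panel():
    """Moderate panel (40 markers x 46 individuals) with truth freqs."""
    return simulate_genotype_matrix(40, 46, seed=11)


def random_sequences(n, rng, min_len=200, max_len=5000):
    """Random ACGT sequences at mixed GC content."""
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        gc = rng.uniform(0.2, 0.8)
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        bases = rng.choice(list("ACGT"), size=length, p=p)
        yield SequenceRecord(f"rand{i}", "".join(bases))
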