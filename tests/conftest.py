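import warnings

import numpy as np
import pytest

from crmscan.motifs import MarkovBackground, train_markov
from crmscan.seqio import SequenceRecord

warnings.filterwarnings("ignore", message="Objective did not converge")


@pytest.fixture(scope="session")
def random_genome() -> SequenceRecord:
    """A 50 kb uniform-composition reference for background training."""
    rng = np.random.default_rng(20240117)
    return SequenceRecord("ref", "".join(rng.choice(list("ACGT"), 50_000)))


@pytest.fixture(scope="session")
def bg2(random_genome) -> MarkovBackground:
    return train_markov([random_genome], 2)


@pytest.fixture(scope="session")
def bg0(random_genome) -> MarkovBackground:
    return train_markov([random_genome], 0)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), length))
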