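import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from offsieve import Genome, GuideRNA


BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def toy_genome(rng) -> Genome:
    return Genome({"chr1": random_seq(rng, 2000), "chr2": random_seq(rng, 1500)})


@pytest.fixture
def toy_guide(rng) -> GuideRNA:
    return GuideRNA("g", random_seq(rng, 12))
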