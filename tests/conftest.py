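from __future__ import annotations

import numpy as np
import pytest

from epvkit.annotate import Genome, reverse_complement


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.4, n_frac: float = 0.0) -> str:
    bases = np.array(list("ACGTN"))
    p_acgt = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]) * (1 - n_frac)
    p = np.append(p_acgt, n_frac)
    return "".join(rng.choice(bases, size=n, p=p))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture
def itr_genome(rng) -> tuple[Genome, int]:
    """A genome with a planted 1 kb terminal repeat around a dissimilar core."""
    itr = random_dna(rng, 1000)
    # force a mismatch right at the boundary so the planted repeat has no
    # chance terminal extension ("no other terminal similarity")
    core = "A" + random_dna(rng, 7998) + "A"
    genome = Genome(id="planted_itr", sequence=itr + core + reverse_complement(itr))
    return genome, 1000
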