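import numpy as np
import pytest

from bandpop.matrix import BandMatrix


def make_matrix(values, pops, locus_primer=None, taxon_of=None,
                prefix="S"):
    """Build a BandMatrix from a 2-D array and a population label per row."""
    values = np.asarray(values)
    acc = [f"{prefix}{i + 1}" for i in range(values.shape[0])]
    loci = [f"L{j + 1:03d}" for j in range(values.shape[1])]
    return BandMatrix(acc, loci, values, dict(zip(acc, pops)),
                      locus_primer=locus_primer, taxon_of=taxon_of)


def random_matrix(rng, n, m, n_pops=2, prefix="S"):
    values = rng.integers(0, 2, size=(n, m))
    pops = [f"pop{k % n_pops}" for k in range(n)]
    return make_matrix(values, sorted(pops), prefix=prefix)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_two_pop():
    """Two populations {00, 00} vs {11, 11}: maximal differentiation."""
    return make_matrix([[0, 0], [0, 0], [1, 1], [1, 1]],
                       ["popA", "popA", "popB", "popB"])


@pytest.fixture
def small_matrix():
    """4 individuals x 3 loci, 2 populations of 2, primer and taxon maps."""
    return make_matrix(
        [[1, 0, 1], [1, 1, 0], [0, 0, 1], [0, 1, 1]],
        ["popA", "popA", "popB", "popB"],
        locus_primer={"L001": "2076", "L002": "2076", "L003": "2277"},
        taxon_of={"popA": "cultivated", "popB": "wild"})
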