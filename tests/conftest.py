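import numpy as np
import pytest

from msatpop import GenotypeTable


def random_table(
    rng: np.random.Generator,
    n: int = 12,
    loci: int = 6,
    n_alleles: int = 5,
    missing_rate: float = 0.1,
    n_pops: int = 2,
) -> GenotypeTable:
    """Random valid genotype table with contiguous population blocks."""
    sizes = 100 + 4 * np.arange(n_alleles)
    geno = sizes[rng.integers(0, n_alleles, size=(n, loci, 2))]
    miss = rng.random((n, loci)) < missing_rate
    geno[miss] = 0
    labels = [f"pop_{1 + (i * n_pops) // n}" for i in range(n)]
    return GenotypeTable(
        [f"S{i + 1}" for i in range(n)],
        [f"Loc{j + 1}" for j in range(loci)],
        geno,
        labels,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def two_cluster_table(
    rng: np.random.Generator, n_per: int = 25, loci: int = 8, bases=(100, 200)
) -> tuple[GenotypeTable, list[int]]:
    """Strongly diverged clusters with disjoint allele sets."""
    geno, truth = [], []
    for c, base in enumerate(bases):
        for _ in range(n_per):
            geno.append(base + 4 * rng.integers(0, 4, size=(loci, 2)))
            truth.append(c)
    n = len(geno)
    table = GenotypeTable(
        [f"s{i}" for i in range(n)],
        [f"L{j}" for j in range(loci)],
        np.array(geno),
    )
    return table, truth
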