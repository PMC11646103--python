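import numpy as np
import pytest

from matefreq import AlleleFrequencies, GenotypeTable


def make_table(entries, queen=None, loci=None):
    """Build a small colony table from worker entries (list of rows of allele
    pairs / None) plus an optional queen row."""
    n_loci = len(entries[0]) if entries else len(queen)
    loci = loci or [f"L{l + 1}" for l in range(n_loci)]
    ids, roles, rows = [], [], []
    if queen is not None:
        ids.append("queen")
        roles.append("queen")
        rows.append(queen)
    for i, row in enumerate(entries):
        ids.append(f"w{i + 1}")
        roles.append("worker")
        rows.append(row)
    return GenotypeTable(ids, loci, rows, roles)


@pytest.fixture
def uniform3():
    """Two-locus frequency table, 3 equal alleles per locus."""
    return AlleleFrequencies.uniform(["L1", "L2"], 3)


@pytest.fixture
def rng():
    return np.random.default_rng(20240813)
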