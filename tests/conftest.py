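"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest


def brute_canonical_kmers(seqs, k):
    """Independent canonical k-mer set: plain set comprehension with Biopython
    reverse complements, no sharing with the package's scanner."""
    from Bio.Seq import Seq

    out = set()
    for seq in seqs:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if set(km) <= set("ACGT"):
                rc = str(Seq(km).reverse_complement())
                out.add(min(km, rc))
    return out


@pytest.fixture
def kmer_oracle():
    return brute_canonical_kmers


@pytest.fixture
def rng():
    return np.random.default_rng(20250922)


def random_panel(rng, max_genomes=5, max_len=10_000):
    n = int(rng.integers(2, max_genomes + 1))
    return {
        f"g{i}": "".join(rng.choice(list("ACGT"), size=int(rng.integers(50, max_len + 1))))
        for i in range(n)
    }


@pytest.fixture
def make_random_panel():
    return random_panel
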