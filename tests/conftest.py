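"""Shared fixtures and independent reference implementations (oracles).

The oracles here deliberately re-derive quantities by brute force or exact
arithmetic, independently of the package's vectorized implementations.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest

import motifindexer as mi


@pytest.fixture()
def rng():
    """Fresh, identically seeded generator per test (order-independent runs)."""
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def random_promoters():
    """20 random 30-bp promoters (reduced scale for exhaustive oracles)."""
    local = np.random.default_rng(7121)
    seqs = [
        "".join(local.choice(list("ACGT"), size=30)) for _ in range(20)
    ]
    ids = [f"p{i:02d}" for i in range(20)]
    return mi.PromoterSet(ids, seqs, window_length=30)


def brute_force_presence_counts(promoters, alphabet, word_length):
    """Oracle: per-oligo promoter-presence counts by direct window matching."""
    size = alphabet.size**word_length
    counts = np.zeros(size, dtype=np.int64)
    for code in range(size):
        word = mi.decode(code, word_length, alphabet)
        for _gene, seq in promoters:
            if any(
                mi.matches(word, seq[i : i + word_length], alphabet)
                for i in range(len(seq) - word_length + 1)
            ):
                counts[code] += 1
    return counts


def exact_hypergeom_upper_tail(m, M, k, K) -> Fraction:
    """Oracle: P(X >= m) by exact rational enumeration."""
    total = Fraction(0)
    for i in range(m, min(k, M) + 1):
        if M - i > K - k:
            continue
        total += Fraction(comb(k, i) * comb(K - k, M - i), comb(K, M))
    return total


def random_word(rng, alphabet, word_length) -> str:
    return "".join(rng.choice(list(alphabet.letters), size=word_length))
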