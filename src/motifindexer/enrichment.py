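"""Hypergeometric over-representation statistics for cataloged oligos.

For an oligo present in ``m`` of the ``M`` promoters of a selected cluster
and in ``k`` of the ``K`` promoters of the whole genome, over-representation
is scored by the hypergeometric upper tail

    pValue = P(X >= m),   X ~ Hypergeometric(population K, successes k, draws M),

computed in log space (log-gamma + logsumexp) because tails of interest reach
1e-40 and beyond.  Only oligos that are *tested* get a p-value:

* genome-frequency restriction: the oligo exists in fewer than 50% of all
  promoters (k < K/2), and
* over-representation: m exceeds its expectation, m > k*M/K.

After p-values are sorted, one member of every reverse-complement pair is
dropped (single-strand scanning makes RC pairs redundant), and q-values are
Benjamini-Hochberg adjusted over the tested, RC-deduplicated family.  Under
a null of randomly drawn promoter groups the expected number of oligos with
p-value below a cutoff is ``n_restricted * p / 4`` (one factor of ~2 for the
over-representation gate and discreteness of the tail, one for RC dedup).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln, logsumexp

from .alphabet import MotifAlphabet, encode, reverse_complement

__all__ = [
    "EnrichmentRecord",
    "hypergeom_pvalue",
    "hypergeom_logsf",
    "pair_pvalues",
    "is_tested",
    "fold_enrichment",
    "dedupe_reverse_complements",
    "qvalues",
    "expected_false_positives",
    "n_restricted",
]


@dataclass
class EnrichmentRecord:
    """Per-oligo enrichment statistics (one row of the report tables)."""

    oligo: str
    m: int  # promoters in cluster containing the oligo
    M: int  # cluster size
    k: int  # promoters in genome containing the oligo
    K: int  # genome promoter count
    pvalue: float
    tested: bool
    qvalue: Optional[float] = None
    fold: Optional[float] = None


def _validate_counts(m: int, M: int, k: int, K: int) -> None:
    if not (0 <= m <= M <= K and 0 <= k <= K and m <= k):
        raise ValueError(f"inconsistent counts m={m} M={M} k={k} K={K}")


def is_tested(m: int, M: int, k: int, K: int) -> bool:
    """Gate for p-value computation: k < K/2 and m above expectation."""
    _validate_counts(m, M, k, K)
    return 2 * k < K and m * K > k * M


def _log_binom(n, r):
    return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)


def hypergeom_logsf(m: int, M: int, k: int, K: int) -> float:
    """log of P(X >= m) for X ~ Hypergeometric(K, k, M), exact summation."""
    _validate_counts(m, M, k, K)
    hi = min(k, M)
    lo = max(m, M + k - K)
    if lo > hi:
        return -np.inf
    if m <= max(0, M + k - K):
        return 0.0
    i = np.arange(lo, hi + 1)
    log_terms = (
        _log_binom(k, i) + _log_binom(K - k, M - i) - _log_binom(K, M)
    )
    return float(logsumexp(log_terms))


def hypergeom_pvalue(m: int, M: int, k: int, K: int) -> float:
    """Upper-tail probability of observing >= m cluster promoters with the oligo."""
    return float(np.exp(hypergeom_logsf(m, M, k, K)))


def pair_pvalues(pairs: Iterable[Tuple[int, int]], M: int, K: int) -> Dict[Tuple[int, int], float]:
    """p-values for a collection of distinct (m, k) pairs at fixed M, K."""
    return {(m, k): hypergeom_pvalue(m, M, k, K) for m, k in pairs}


def fold_enrichment(m: int, M: int, k: int, K: int) -> float:
    """Cluster-over-genome frequency ratio (m/M) / (k/K)."""
    _validate_counts(m, M, k, K)
    if k == 0:
        raise ValueError("fold enrichment undefined for k = 0")
    return (m / M) / (k / K)


def dedupe_reverse_complements(
    records: Sequence[EnrichmentRecord], alphabet: MotifAlphabet
) -> List[EnrichmentRecord]:
    """Keep one member of each reverse-complement pair.

    ``records`` must be sorted ascending by p-value; the first-encountered
    (better-ranked) member of every RC pair is kept.  Palindromic oligos
    (rc(o) == o) are kept unconditionally.
    """
    pvals = [r.pvalue for r in records]
    if pvals != sorted(pvals):
        raise ValueError("records must be sorted ascending by pvalue")
    kept: List[EnrichmentRecord] = []
    seen = set()
    for rec in records:
        code = encode(rec.oligo, alphabet)
        rc = encode(reverse_complement(rec.oligo, alphabet), alphabet)
        if rc in seen and rc != code:
            continue
        if code in seen:
            continue
        seen.add(code)
        kept.append(rec)
    return kept


def dedupe_rc_codes(codes: np.ndarray, rc: np.ndarray) -> np.ndarray:
    """Vectorized-order RC dedup: boolean keep-mask over rank-sorted codes."""
    keep = np.ones(codes.size, dtype=bool)
    seen = set()
    for i, (c, r) in enumerate(zip(codes.tolist(), rc.tolist())):
        if (r in seen and r != c) or c in seen:
            keep[i] = False
            continue
        seen.add(c)
    return keep


def qvalues(pvalues: np.ndarray, family_size: Optional[int] = None) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values.

    ``family_size`` is the size of the tested family the p-values were drawn
    from (defaults to ``len(pvalues)``); passing it allows adjusting only the
    retained sub-cutoff records while ranks stay correct, because every
    unlisted member of the family has a larger p-value.
    """
    p = np.asarray(pvalues, dtype=float)
    n = family_size if family_size is not None else p.size
    if n < p.size:
        raise ValueError("family_size smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, p.size + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(ranked)
    out[order] = np.minimum(ranked, 1.0)
    return out


def expected_false_positives(n_restricted: int, p_cutoff: float) -> float:
    """Expected null oligos below a p cutoff: n_restricted * p / 4."""
    return n_restricted * p_cutoff / 4.0


def n_restricted(genome_counts: np.ndarray, n_promoters: int) -> int:
    """Number of oligos in fewer than 50% of the genome's promoters."""
    return int(np.count_nonzero(genome_counts.astype(np.int64) * 2 < n_promoters))
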