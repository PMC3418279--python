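"""End-to-end cluster analysis: catalog, test, score position bias, filter.

This orchestrates the per-module pieces into the standard workflow for one
co-expressed gene cluster against a genome-wide promoter index:

1.  catalog presence counts ``m`` of every oligo in the cluster promoters;
2.  gate oligos on the genome-frequency restriction (k < K/2) and the
    over-representation condition (m > k*M/K) and compute hypergeometric
    upper-tail p-values (grouped by distinct (m, k) pairs -- the p-value
    depends on counts only, which keeps the full 214M-oligo scan cheap);
3.  compute occurrence counts, mean positions and TSS z-scores of candidate
    oligos within the cluster promoters;
4.  apply the two qualification criteria (p < 1e-7, or 1e-7 <= p <= 1e-5
    with z > 3), drop reverse-complement duplicates, attach BH q-values and
    fold enrichment;
5.  run the 10% position-overlap filter to extract major motifs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .alphabet import MotifAlphabet, decode, digits_of_codes, rc_codes
from .enrichment import (
    dedupe_rc_codes,
    expected_false_positives,
    hypergeom_pvalue,
    qvalues,
)
from .indexing import (
    OligoCountIndex,
    index_promoters,
    match_windows,
    occurrence_index,
    window_digits,
)
from .position_bias import zscores_from_moments
from .promoters import PromoterSet
from .selection import MajorMotifReport, select_major_motifs

__all__ = ["ClusterAnalysis", "cluster_candidates", "analyze_cluster", "candidate_positions"]

_CHUNK = 1 << 22


@dataclass
class ClusterAnalysis:
    """Result of one cluster-vs-genome motif analysis."""

    candidates: pd.DataFrame  # qualified, RC-deduplicated, sorted by pValue
    majors: Optional[MajorMotifReport]
    M: int
    K: int
    n_tested: int
    n_restricted: int
    family_size: int  # tested family size after RC dedup (basis of q-values)

    @property
    def major_table(self) -> pd.DataFrame:
        if self.majors is None:
            return self.candidates.iloc[0:0]
        rows = self.candidates.set_index("motif")
        return rows.loc[self.majors.words].reset_index()

    def expected_fp(self, p_cutoff: float) -> float:
        return expected_false_positives(self.n_restricted, p_cutoff)


def _pair_histogram(
    m: np.ndarray, k: np.ndarray, M: int, K: int
) -> np.ndarray:
    """Histogram over (m, k) pairs, shape (M+1, K+1)."""
    hist = np.zeros((M + 1) * (K + 1), dtype=np.int64)
    for lo in range(0, m.size, _CHUNK):
        sl = slice(lo, min(lo + _CHUNK, m.size))
        pair = m[sl].astype(np.int64) * (K + 1) + k[sl]
        hist += np.bincount(pair, minlength=hist.size)
    return hist.reshape(M + 1, K + 1)


def _tested_pair_mask(M: int, K: int) -> np.ndarray:
    """Boolean (M+1, K+1) grid of the tested gate: 2k < K and m*K > k*M, m >= 1."""
    mm, kk = np.meshgrid(
        np.arange(M + 1, dtype=np.int64),
        np.arange(K + 1, dtype=np.int64),
        indexing="ij",
    )
    return (2 * kk < K) & (mm * K > kk * M) & (mm >= 1) & (mm <= kk)


def cluster_candidates(
    cluster: PromoterSet,
    genome_index: OligoCountIndex,
    p_cutoff: float = 1e-5,
    cluster_index: Optional[OligoCountIndex] = None,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Tested oligos with p-value at or below a cutoff, plus family accounting.

    Returns an (unsorted-by-rank but p-filtered) DataFrame with columns
    ``code, m, k, pvalue`` and a dict with ``n_tested``, ``n_restricted``,
    ``family_size`` (RC-deduplicated tested-family size used for q-values;
    exact when the tested family is small enough to enumerate, otherwise the
    half-count approximation, palindromes being a negligible fraction).
    """
    alphabet, L = genome_index.alphabet, genome_index.word_length
    if cluster_index is None:
        cluster_index = index_promoters(cluster, alphabet, L)
    if cluster_index.alphabet is not alphabet or cluster_index.word_length != L:
        raise ValueError("cluster and genome indexes use different codecs")
    m_arr, k_arr = cluster_index.counts, genome_index.counts
    M, K = cluster_index.n_promoters, genome_index.n_promoters

    hist = _pair_histogram(m_arr, k_arr, M, K)
    tested = _tested_pair_mask(M, K)
    n_tested = int(hist[tested].sum())
    n_restr = int(
        np.count_nonzero(k_arr <= (K - 1) // 2)
        if K % 2
        else np.count_nonzero(k_arr < K // 2)
    )

    # p-values on the occupied, tested (m, k) grid cells
    pgrid = np.ones((M + 1, K + 1), dtype=np.float64)
    occupied = np.argwhere(tested & (hist > 0))
    for mm, kk in occupied:
        pgrid[mm, kk] = hypergeom_pvalue(int(mm), M, int(kk), K)
    keep_pair = tested & (pgrid <= p_cutoff)

    keep_flat = keep_pair.ravel()
    codes = []
    for lo in range(0, m_arr.size, _CHUNK):
        sl = slice(lo, min(lo + _CHUNK, m_arr.size))
        pair = m_arr[sl].astype(np.int64) * (K + 1) + k_arr[sl]
        hits = np.flatnonzero(keep_flat[pair])
        if hits.size:
            codes.append(hits + lo)
    codes = (
        np.concatenate(codes) if codes else np.empty(0, dtype=np.int64)
    )

    # RC-deduplicated tested family size (exact when enumerable)
    family_size = _family_size(m_arr, k_arr, tested, n_tested, alphabet, L, M, K)

    m_sel = m_arr[codes].astype(np.int64)
    k_sel = k_arr[codes].astype(np.int64)
    df = pd.DataFrame(
        {
            "code": codes,
            "m": m_sel,
            "k": k_sel,
            "pvalue": pgrid[m_sel, k_sel],
        }
    )
    meta = {
        "n_tested": n_tested,
        "n_restricted": n_restr,
        "family_size": family_size,
        "M": M,
        "K": K,
    }
    return df, meta


_FAMILY_ENUM_LIMIT = 2_000_000


def _family_size(
    m_arr, k_arr, tested_grid, n_tested, alphabet, L, M, K
) -> int:
    if n_tested == 0:
        return 0
    if n_tested > _FAMILY_ENUM_LIMIT:
        return max(1, (n_tested + 1) // 2)
    flat = tested_grid.ravel()
    codes = []
    for lo in range(0, m_arr.size, _CHUNK):
        sl = slice(lo, min(lo + _CHUNK, m_arr.size))
        pair = m_arr[sl].astype(np.int64) * (K + 1) + k_arr[sl]
        hits = np.flatnonzero(flat[pair])
        if hits.size:
            codes.append(hits + lo)
    tested_codes = np.concatenate(codes)
    rc = rc_codes(tested_codes, L, alphabet)
    in_tested = np.isin(rc, tested_codes, assume_unique=False)
    both = int(np.count_nonzero(in_tested & (rc != tested_codes)))
    return int(tested_codes.size - both // 2)


def candidate_positions(
    cluster: PromoterSet,
    words_digits: np.ndarray,
    alphabet: MotifAlphabet,
    chunk: int = 512,
) -> List[Set[Tuple[str, int]]]:
    """Occurrence position sets (gene, 1-based start) for many oligos at once."""
    wins, gene_idx, starts = [], [], []
    for gi, (gene, seq) in enumerate(cluster):
        w, s = window_digits(seq, words_digits.shape[1])
        if w.size:
            wins.append(w)
            gene_idx.append(np.full(s.size, gi, dtype=np.int64))
            starts.append(s)
    if not wins:
        return [set() for _ in range(len(words_digits))]
    win = np.concatenate(wins)
    gene_idx = np.concatenate(gene_idx)
    starts = np.concatenate(starts)
    tab = alphabet.match_table
    out: List[Set[Tuple[str, int]]] = []
    for lo in range(0, len(words_digits), chunk):
        cd = words_digits[lo : lo + chunk]
        ok = tab[cd[:, 0][:, None], win[None, :, 0]]
        for pos in range(1, cd.shape[1]):
            ok &= tab[cd[:, pos][:, None], win[None, :, pos]]
        for row in ok:
            hits = np.flatnonzero(row)
            out.append(
                {
                    (cluster.gene_ids[gene_idx[h]], int(starts[h]))
                    for h in hits
                }
            )
    return out


def analyze_cluster(
    cluster: PromoterSet,
    genome_index: OligoCountIndex,
    p_strict: float = 1e-7,
    p_relaxed: float = 1e-5,
    z_cutoff: float = 3.0,
    overlap_fraction: float = 0.10,
    stop_below: int = 10,
    select_majors: bool = True,
    max_candidates: Optional[int] = None,
    slack: int = 0,
) -> ClusterAnalysis:
    """Full single-cluster motif discovery against a genome index."""
    alphabet, L = genome_index.alphabet, genome_index.word_length
    cand, meta = cluster_candidates(cluster, genome_index, p_relaxed)

    occ = occurrence_index(cluster, alphabet, L)
    codes = cand["code"].to_numpy()
    n_occ = occ.occurrences[codes].astype(np.int64)
    pos_sum = occ.pos_sum[codes].astype(np.int64)
    del occ
    z = zscores_from_moments(n_occ, pos_sum, cluster.window_length, L)
    mean_pos = np.divide(
        pos_sum, n_occ, out=np.full(len(cand), np.nan), where=n_occ > 0
    )
    cand = cand.assign(n=n_occ, mean_position=mean_pos, z=z)

    p = cand["pvalue"].to_numpy()
    qualified = (p < p_strict) | (
        (p >= p_strict) & (p <= p_relaxed) & (cand["z"].to_numpy() > z_cutoff)
    )
    cand = cand[qualified]

    # rank, RC dedup, q-values
    cand = cand.sort_values(["pvalue", "code"], kind="stable").reset_index(drop=True)
    if max_candidates is not None:
        cand = cand.iloc[:max_candidates]
    rc = rc_codes(cand["code"].to_numpy(), L, alphabet)
    keep = dedupe_rc_codes(cand["code"].to_numpy(), rc)
    cand = cand[keep].reset_index(drop=True)
    cand = cand.assign(
        qvalue=qvalues(
            cand["pvalue"].to_numpy(), max(meta["family_size"], len(cand))
        ),
        fold=(cand["m"] / meta["M"]) / (cand["k"] / meta["K"]),
        motif=[decode(int(c), L, alphabet) for c in cand["code"]],
    )
    order = [
        "motif", "m", "k", "pvalue", "qvalue", "fold", "n",
        "mean_position", "z", "code",
    ]
    cand = cand[order]
    cand.attrs.update(meta)

    majors = None
    if select_majors and len(cand):
        digits = digits_of_codes(cand["code"].to_numpy(), L, alphabet)
        possets = candidate_positions(cluster, digits, alphabet)
        ranked = list(zip(cand["motif"], cand["pvalue"]))
        positions = {w: ps for (w, _), ps in zip(ranked, possets)}
        majors = select_major_motifs(
            ranked, positions, overlap_fraction, stop_below, slack=slack
        )
    return ClusterAnalysis(
        candidates=cand,
        majors=majors,
        M=meta["M"],
        K=meta["K"],
        n_tested=meta["n_tested"],
        n_restricted=meta["n_restricted"],
        family_size=meta["family_size"],
    )
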