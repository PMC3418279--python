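"""False-discovery calibration on randomly sampled promoter groups.

Groups of promoters drawn at random from the genome contain no shared
regulatory signal, so every oligo that clears a p-value cutoff in such a
group is a false positive.  Sampling many groups and counting sub-cutoff
oligos (after reverse-complement dedup) measures the method's false-discovery
behavior and is compared against the analytic expectation
``n_restricted * p / 4``.  The TSS z-scores of tested oligos in random groups
also calibrate the position-bias score: their distribution should be
standard-normal-like, so the fraction with z > 3 stays near P(Z > 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .enrichment import expected_false_positives
from .indexing import OligoCountIndex, index_promoters, occurrence_index
from .alphabet import rc_codes
from .enrichment import hypergeom_pvalue
from .pipeline import _pair_histogram, _tested_pair_mask
from .position_bias import zscores_from_moments
from .promoters import PromoterSet, subset_by_ids

__all__ = ["CalibrationResult", "calibrate"]


@dataclass
class CalibrationResult:
    """Outcome of the random-group false-discovery experiment."""

    group_size: int
    n_groups: int
    cutoffs: List[float]
    counts: np.ndarray  # (n_groups, n_cutoffs) sub-cutoff oligo counts
    mean_counts: np.ndarray  # per-cutoff mean over groups
    mean_z_gt3: float  # mean count of sub-(loosest-cutoff) oligos with z > 3
    expected: np.ndarray  # analytic expectation n_restricted * p / 4
    n_restricted: int
    seed: int
    z_mean: float = field(default=np.nan)  # pooled z moments of tested oligos
    z_sd: float = field(default=np.nan)


def calibrate(
    universe: PromoterSet,
    genome_index: OligoCountIndex,
    group_size: int,
    n_groups: int,
    cutoffs: Sequence[float],
    seed: int,
    z_cutoff: float = 3.0,
) -> CalibrationResult:
    """Run the random-group experiment and report per-cutoff mean counts.

    Each replicate samples ``group_size`` promoters without replacement,
    scores all tested oligos against the genome index, RC-deduplicates the
    sub-cutoff oligos, and counts them below each cutoff.  Fully reproducible
    from ``seed`` (a master seed spawns one independent stream per group).
    """
    if group_size >= len(universe):
        raise ValueError("group_size must be smaller than the universe")
    cutoffs = sorted(float(c) for c in cutoffs)  # ascending: tightest first
    alphabet, L = genome_index.alphabet, genome_index.word_length
    k_arr = genome_index.counts
    K = genome_index.n_promoters
    n_restr = int(
        np.count_nonzero(k_arr.astype(np.int64) * 2 < K)
    )
    loosest = cutoffs[-1]
    M = group_size
    tested_grid = _tested_pair_mask(M, K)

    streams = np.random.SeedSequence(seed).spawn(n_groups)
    counts = np.zeros((n_groups, len(cutoffs)), dtype=np.int64)
    z_gt3 = np.zeros(n_groups, dtype=np.int64)
    z_pool: List[np.ndarray] = []

    for g, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        pick = rng.choice(len(universe), size=group_size, replace=False)
        ids = [universe.gene_ids[i] for i in sorted(pick)]
        group = subset_by_ids(universe, ids)
        gi = index_promoters(group, alphabet, L)
        m_arr = gi.counts

        hist = _pair_histogram(m_arr, k_arr, M, K)
        pgrid = np.ones((M + 1, K + 1))
        for mm, kk in np.argwhere(tested_grid & (hist > 0)):
            pgrid[mm, kk] = hypergeom_pvalue(int(mm), M, int(kk), K)

        keep_flat = (tested_grid & (pgrid <= loosest)).ravel()
        pair = m_arr.astype(np.int64) * (K + 1) + k_arr
        codes = np.flatnonzero(keep_flat[pair])
        pv = pgrid.ravel()[pair[codes]]

        # RC dedup among sub-cutoff oligos, better-ranked member kept
        order = np.lexsort((codes, pv))
        codes, pv = codes[order], pv[order]
        rc = rc_codes(codes, L, alphabet)
        keep = np.ones(codes.size, dtype=bool)
        seen = set()
        for i, (c, r) in enumerate(zip(codes.tolist(), rc.tolist())):
            if (r in seen and r != c) or c in seen:
                keep[i] = False
                continue
            seen.add(c)
        codes, pv = codes[keep], pv[keep]

        for j, cut in enumerate(cutoffs):
            counts[g, j] = int(np.count_nonzero(pv <= cut))

        # z-scores of tested oligos within the group's promoters
        occ = occurrence_index(group, alphabet, L)
        tested_flat = tested_grid.ravel()
        tested_codes = np.flatnonzero(tested_flat[pair])
        zs = zscores_from_moments(
            occ.occurrences[tested_codes],
            occ.pos_sum[tested_codes],
            universe.window_length,
            L,
        )
        z_pool.append(zs[np.isfinite(zs)])
        sub_z = zscores_from_moments(
            occ.occurrences[codes], occ.pos_sum[codes], universe.window_length, L
        )
        z_gt3[g] = int(np.count_nonzero(sub_z > z_cutoff))

    pooled = np.concatenate(z_pool) if z_pool else np.empty(0)
    return CalibrationResult(
        group_size=group_size,
        n_groups=n_groups,
        cutoffs=list(cutoffs),
        counts=counts,
        mean_counts=counts.mean(axis=0),
        mean_z_gt3=float(z_gt3.mean()),
        expected=np.array(
            [expected_false_positives(n_restr, c) for c in cutoffs]
        ),
        n_restricted=n_restr,
        seed=seed,
        z_mean=float(pooled.mean()) if pooled.size else np.nan,
        z_sd=float(pooled.std(ddof=1)) if pooled.size > 1 else np.nan,
    )
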