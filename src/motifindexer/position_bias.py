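"""Position bias of oligos toward the transcription start site.

Bona fide promoter motifs tend to sit close to the TSS.  With fixed windows
of W bp, an L-mer has S = W - L + 1 valid 1-based starts (S = 993 for 8-mers
in 1000-bp promoters; position S is immediately adjacent to the TSS).  Under
the null of no positional selection, occurrence starts are uniform on
{1, ..., S}, so

    mu      = (1 + S) / 2            (497 for 8-mers in 1000-bp windows)
    sigma^2 = (S^2 - 1) / 12         (discrete-uniform variance)

and the mean position p_bar of an oligo with n occurrence instances has
standard error sqrt(sigma^2 / n).  The bias score is

    z = (p_bar - mu) / sqrt(sigma^2 / n),

positive when occurrences crowd toward the TSS.  Instances are counted per
occurrence (several per promoter allowed), distinct from the presence counts
used by the enrichment test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .promoters import last_start

__all__ = [
    "BiasStatistics",
    "uniform_mean",
    "uniform_variance",
    "zscore",
    "zscores_from_moments",
    "position_profile",
    "qualify_motif",
]


def uniform_mean(window_length: int, word_length: int) -> float:
    """Null mean start position, (1 + S)/2 with S = W - L + 1."""
    return (1 + last_start(window_length, word_length)) / 2.0


def uniform_variance(window_length: int, word_length: int) -> float:
    """Null per-instance variance of the start position, (S^2 - 1)/12."""
    s = last_start(window_length, word_length)
    return (s * s - 1) / 12.0


@dataclass
class BiasStatistics:
    """Positional statistics of one oligo within a set of promoters."""

    oligo: str
    n: int  # occurrence instances (all positions, all promoters)
    mean_position: float
    z: float


PositionsLike = Union[Sequence[int], Mapping[str, Sequence[int]]]


def _flatten(positions: PositionsLike) -> np.ndarray:
    if isinstance(positions, Mapping):
        chunks = [np.asarray(v, dtype=np.int64) for v in positions.values()]
        return np.concatenate(chunks) if chunks else np.empty(0, np.int64)
    return np.asarray(list(positions), dtype=np.int64)


def zscore(
    positions: PositionsLike,
    window_length: int,
    word_length: int,
    oligo: str = "",
) -> BiasStatistics:
    """TSS-bias z-score of an oligo from its occurrence start positions.

    ``positions`` is either a flat sequence of 1-based starts or a
    per-gene mapping as returned by
    :func:`motifindexer.indexing.collect_positions`.
    """
    pos = _flatten(positions)
    if pos.size == 0:
        raise ValueError("z-score undefined for an oligo with no occurrences")
    s = last_start(window_length, word_length)
    if pos.min() < 1 or pos.max() > s:
        raise ValueError(f"positions must lie in [1, {s}]")
    mu = uniform_mean(window_length, word_length)
    var = uniform_variance(window_length, word_length)
    p_bar = float(pos.mean())
    z = (p_bar - mu) / np.sqrt(var / pos.size)
    return BiasStatistics(oligo, int(pos.size), p_bar, float(z))


def zscores_from_moments(
    n: np.ndarray, pos_sum: np.ndarray, window_length: int, word_length: int
) -> np.ndarray:
    """Vectorized z-scores from occurrence counts and position sums.

    Entries with ``n == 0`` yield NaN.
    """
    n = np.asarray(n, dtype=np.float64)
    mu = uniform_mean(window_length, word_length)
    var = uniform_variance(window_length, word_length)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_bar = np.asarray(pos_sum, dtype=np.float64) / n
        return (p_bar - mu) * np.sqrt(n / var)


def position_profile(
    positions: PositionsLike,
    window_length: int,
    word_length: int,
    bin_width: int = 50,
) -> pd.DataFrame:
    """Binned occurrence density along the promoter (TSS-distance profile).

    Bins run from position 1 (at -window_length relative to the TSS) toward
    the TSS; the last bin is truncated if ``bin_width`` does not divide the
    valid-start range.  Columns: ``bin_start``, ``bin_end`` (1-based,
    inclusive), ``count``, ``density``; counts sum to the instance count n.
    """
    pos = _flatten(positions)
    s = last_start(window_length, word_length)
    edges = np.arange(1, s + bin_width + 1, bin_width)
    edges[-1] = max(edges[-1], s + 1)
    counts, _ = np.histogram(pos, bins=edges)
    widths = np.diff(edges)
    total = max(pos.size, 1)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": np.minimum(edges[1:] - 1, s),
            "count": counts,
            "density": counts / (total * widths),
        }
    )


def qualify_motif(
    pvalue: float,
    z: Optional[float],
    p_strict: float = 1e-7,
    p_relaxed: float = 1e-5,
    z_cutoff: float = 3.0,
) -> bool:
    """Two-criteria motif qualification.

    An oligo qualifies as a potential motif if its enrichment p-value is
    below ``p_strict`` (1e-7), or if the p-value lies between ``p_strict``
    and ``p_relaxed`` (1e-5) *and* the TSS z-score exceeds ``z_cutoff`` (3).
    """
    if pvalue < p_strict:
        return True
    if pvalue <= p_relaxed and z is not None and z > z_cutoff:
        return True
    return False
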