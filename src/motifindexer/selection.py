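"""Position-overlap filtering of ranked oligos into non-redundant major motifs.

Highly significant oligo lists are dominated by degenerate variants of a few
underlying motifs: variants match largely the same genomic windows.  The
filter walks the p-value ranking; each selected *major motif* claims its
occurrence positions (``(gene_id, start)`` pairs), and any remaining oligo
sharing at least ``overlap_fraction`` (10%) of *its own* positions with the
claimed set is removed.  Iteration stops when fewer than ``stop_below`` (10)
oligos remain.

A position is the exact pair (gene, 1-based start): oligos covering the same
genomic window at shifted starts do not share a position (a ``slack`` of
+/- w bp can relax this).  The overlap denominator is the candidate's own
position count, which guarantees progress and reads the 10%-of-its-positions
rule per candidate.  Ties in p-value break by word order for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

__all__ = ["MajorMotif", "MajorMotifReport", "position_overlap", "select_major_motifs"]

Position = Tuple[str, int]


def position_overlap(oligo_positions: Set[Position], claimed: Set[Position]) -> float:
    """Fraction of an oligo's own positions already claimed by major motifs."""
    if not oligo_positions:
        raise ValueError("overlap undefined for an oligo with no positions")
    return len(oligo_positions & claimed) / len(oligo_positions)


@dataclass
class MajorMotif:
    """One selected major motif with the positions it claimed."""

    oligo: str
    pvalue: float
    positions: Set[Position]
    rank: int  # 0-based rank in the input ordering


@dataclass
class MajorMotifReport:
    """Ordered non-redundant motif list from the position-overlap filter."""

    majors: List[MajorMotif] = field(default_factory=list)
    claimed_positions: Set[Position] = field(default_factory=set)
    survivors_at_stop: int = 0

    @property
    def words(self) -> List[str]:
        return [m.oligo for m in self.majors]


def _expand_slack(positions: Iterable[Position], slack: int) -> Set[Position]:
    if slack == 0:
        return set(positions)
    return {
        (gene, start + d)
        for gene, start in positions
        for d in range(-slack, slack + 1)
    }


def select_major_motifs(
    ranked: Sequence[Tuple[str, float]],
    positions: Mapping[str, Mapping[str, Sequence[int]] | Iterable[Position]],
    overlap_fraction: float = 0.10,
    stop_below: int = 10,
    slack: int = 0,
) -> MajorMotifReport:
    """Extract major motifs from a p-value-ranked, RC-deduplicated oligo list.

    Parameters
    ----------
    ranked:
        ``(word, pvalue)`` pairs sorted ascending by p-value.
    positions:
        Per-oligo occurrence positions: either ``{gene: [starts]}`` mappings
        (as from :func:`~motifindexer.indexing.collect_positions`) or
        iterables of ``(gene, start)`` pairs.
    overlap_fraction:
        Remove a candidate once this fraction of its own positions is claimed.
    stop_below:
        Halt when fewer than this many candidates remain.
    slack:
        Treat starts within +/- ``slack`` bp as the same position (default:
        exact-start identity).
    """
    pvals = [p for _, p in ranked]
    if pvals != sorted(pvals):
        raise ValueError("ranked oligos must be sorted ascending by pvalue")

    def posset(word: str) -> Set[Position]:
        raw = positions[word]
        if isinstance(raw, Mapping):
            return {(g, int(s)) for g, starts in raw.items() for s in starts}
        return {(g, int(s)) for g, s in raw}

    remaining: List[Tuple[str, float, Set[Position]]] = [
        (word, p, posset(word)) for word, p in ranked
    ]
    report = MajorMotifReport()
    while remaining and len(remaining) >= stop_below:
        word, p, pos = remaining.pop(0)
        rank = len(report.majors)
        report.majors.append(MajorMotif(word, p, pos, rank))
        report.claimed_positions |= _expand_slack(pos, slack)
        remaining = [
            cand
            for cand in remaining
            if position_overlap(cand[2], report.claimed_positions)
            < overlap_fraction
        ]
    report.survivors_at_stop = len(remaining)
    return report
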