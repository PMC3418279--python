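"""Fixed-length promoter sequence sets and the coordinate convention.

Promoters are fixed-length upstream windows (canonically 1000 bp, 5'->3'),
with the window's last base immediately adjacent to the transcription start
site (or translation start, depending on how the input was extracted).
Occurrence coordinates everywhere in the package are the 1-based start index
of an L-mer window: position 1 lies at -window_length relative to the TSS and
the last valid start of an L-mer is ``window_length - L + 1`` (993 for 8-mers
in 1000-bp promoters).

Sequences are stored uppercase over {A,C,G,T,N}.  ``N`` marks sequence
ambiguity (assembly gaps): no oligo occurrence may span an ``N`` -- it is not
a motif-side wildcard.  Scanning is on the given (forward) strand only;
reverse-complement symmetry is handled at the reporting stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

from Bio import SeqIO

__all__ = [
    "PromoterSet",
    "PromoterValidationError",
    "FIRST_POSITION",
    "last_start",
    "read_promoters",
    "write_promoters",
    "read_gene_list",
    "subset_by_ids",
]

#: 1-based coordinate of the window base furthest from the TSS
FIRST_POSITION = 1

_VALID_CHARS = frozenset("ACGTN")


def last_start(window_length: int, word_length: int) -> int:
    """Largest valid 1-based start of an L-mer in a fixed window (W - L + 1)."""
    return window_length - word_length + 1


class PromoterValidationError(ValueError):
    """Raised when promoter records violate the fixed-window contract."""

    def __init__(self, message: str, gene_ids: Sequence[str] = ()):
        super().__init__(message)
        self.gene_ids = list(gene_ids)


@dataclass
class PromoterSet:
    """An ordered set of named fixed-length promoter sequences.

    Invariants enforced at construction: every sequence has length exactly
    ``window_length``, gene ids are unique, sequences are uppercase over
    {A,C,G,T,N}.
    """

    gene_ids: List[str]
    sequences: List[str]
    window_length: int
    species: str = ""
    _index: Dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.sequences):
            raise PromoterValidationError("ids and sequences differ in length")
        self.sequences = [s.upper() for s in self.sequences]
        bad_len = [
            g
            for g, s in zip(self.gene_ids, self.sequences)
            if len(s) != self.window_length
        ]
        if bad_len:
            raise PromoterValidationError(
                f"{len(bad_len)} sequence(s) do not have length "
                f"{self.window_length}: {', '.join(bad_len[:10])}",
                bad_len,
            )
        bad_chars = [
            g
            for g, s in zip(self.gene_ids, self.sequences)
            if not _VALID_CHARS.issuperset(s)
        ]
        if bad_chars:
            raise PromoterValidationError(
                "sequence(s) contain characters outside A/C/G/T/N: "
                + ", ".join(bad_chars[:10]),
                bad_chars,
            )
        self._index = {}
        for g in self.gene_ids:
            if g in self._index:
                raise PromoterValidationError(f"duplicate gene id {g!r}", [g])
            self._index[g] = len(self._index)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self) -> Iterable[Tuple[str, str]]:
        return iter(zip(self.gene_ids, self.sequences))

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def sequence_of(self, gene_id: str) -> str:
        return self.sequences[self._index[gene_id]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PromoterSet):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sequences == other.sequences
            and self.window_length == other.window_length
        )


def read_promoters(path, window_length: int, species: str = "") -> PromoterSet:
    """Read and validate a promoter FASTA of fixed-length upstream windows.

    Records whose length differs from ``window_length`` are rejected with an
    error naming the offending ids -- there is no silent trimming or padding.
    Lowercase input is normalized to uppercase.
    """
    if window_length < 20:
        raise ValueError("window_length must be at least 20 bp")
    ids: List[str] = []
    seqs: List[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if not ids:
        raise PromoterValidationError(f"no FASTA records found in {path}")
    return PromoterSet(ids, seqs, window_length=window_length, species=species)


def write_promoters(promoters: PromoterSet, path) -> None:
    """Write a promoter set as FASTA (round-trips byte-identically)."""
    with open(path, "w") as fh:
        for gene_id, seq in promoters:
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_gene_list(path) -> List[str]:
    """Read a gene-id list: one id per line, ``#`` comments and blanks allowed."""
    ids: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.append(line)
    return ids


def subset_by_ids(
    universe: PromoterSet, ids: Sequence[str], on_missing: str = "warn"
) -> PromoterSet:
    """Subset a promoter universe to a gene-id list, preserving universe order.

    Ids absent from the universe are reported (``on_missing='warn'``, default)
    or rejected (``'error'``).  An empty intersection is always an error.
    """
    if not ids:
        raise ValueError("ids must be non-empty")
    wanted = set(ids)
    missing = sorted(wanted.difference(universe.gene_ids))
    if missing:
        msg = f"{len(missing)} id(s) not in universe: {', '.join(missing[:10])}"
        if on_missing == "error":
            raise PromoterValidationError(msg, missing)
        warnings.warn(msg, stacklevel=2)
    kept = [(g, s) for g, s in universe if g in wanted]
    if not kept:
        raise PromoterValidationError("no requested ids found in the universe")
    return PromoterSet(
        [g for g, _ in kept],
        [s for _, s in kept],
        window_length=universe.window_length,
        species=universe.species,
    )
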