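"""Per-oligo promoter-presence and occurrence cataloging.

The cataloging loop conceptually runs, for every promoter: extract all clean
(N-free) L-mer windows; list every degenerate expansion of every window;
increment each distinct expansion's counter once for the promoter.  Done
literally, an 8-mer window has ``5**8 = 390,625`` expansions, so this module
computes the identical result with a separable superset transform over the
dense code-indexed array instead:

1.  Mark the concrete window codes of up to 64 promoters as bits in a packed
    ``uint64`` array of length ``|alphabet|**L``.
2.  For each word position, derive every degenerate digit's slice as the
    bitwise OR of the slices of the concrete digits it covers (r = A|G, ...,
    n = r|y).  After all positions, bit *j* of entry ``code`` is set iff
    promoter *j* contains a window matched by ``decode(code)``.
3.  Popcount into the per-oligo promoter counts.

The same transform with ``+`` in place of ``|`` (valid because each wobble's
match set is a disjoint union of bases) turns per-code *occurrence* counts and
position sums of concrete windows into occurrence counts and position sums of
every degenerate oligo, which is what the position-bias statistics need.

The low-significance word positions make the per-axis slices cache-hostile,
so the innermost two axes are handled by small numba block kernels when numba
is available; a pure-numpy path computes the same thing otherwise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .alphabet import ALPHA11, MotifAlphabet, alphabet_by_name
from .promoters import PromoterSet

__all__ = [
    "OligoCountIndex",
    "OccurrenceIndex",
    "index_promoters",
    "occurrence_index",
    "collect_positions",
    "save_index",
    "load_index",
    "window_digits",
    "concrete_window_codes",
    "match_windows",
]

_BASE_LUT = np.full(256, 127, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_LUT[ord(_b)] = _i
_BASE_LUT[ord("N")] = 4

try:  # compiled kernels for the cache-hostile inner axes
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap


@njit(cache=False)
def _derive_axis_or(arr, size, left, right, triples):  # pragma: no cover - numba
    nt = triples.shape[0]
    vals = np.zeros(size, dtype=arr.dtype)
    for l in range(left):
        base_l = l * size * right
        for r in range(right):
            base = base_l + r
            for d in range(4):
                vals[d] = arr[base + d * right]
            for t in range(nt):
                vals[triples[t, 0]] = vals[triples[t, 1]] | vals[triples[t, 2]]
            for t in range(nt):
                d = triples[t, 0]
                arr[base + d * right] = vals[d]


@njit(cache=False)
def _derive_axis_add(arr, size, left, right, triples):  # pragma: no cover - numba
    nt = triples.shape[0]
    vals = np.zeros(size, dtype=arr.dtype)
    for l in range(left):
        base_l = l * size * right
        for r in range(right):
            base = base_l + r
            for d in range(4):
                vals[d] = arr[base + d * right]
            for t in range(nt):
                vals[triples[t, 0]] = vals[triples[t, 1]] + vals[triples[t, 2]]
            for t in range(nt):
                d = triples[t, 0]
                arr[base + d * right] = vals[d]


@njit(cache=False)
def _derive_block_or(arr2, size, triples):  # pragma: no cover - numba
    nt = triples.shape[0]
    for blk in range(arr2.shape[0]):
        block = arr2[blk]
        for t in range(nt):  # second-to-last axis
            d = triples[t, 0] * size
            c1 = triples[t, 1] * size
            c2 = triples[t, 2] * size
            for j in range(size):
                block[d + j] = block[c1 + j] | block[c2 + j]
        for t in range(nt):  # last axis
            d = triples[t, 0]
            c1 = triples[t, 1]
            c2 = triples[t, 2]
            for i in range(0, size * size, size):
                block[i + d] = block[i + c1] | block[i + c2]


@njit(cache=False)
def _derive_block_add(arr2, size, triples):  # pragma: no cover - numba
    nt = triples.shape[0]
    for blk in range(arr2.shape[0]):
        block = arr2[blk]
        for t in range(nt):
            d = triples[t, 0] * size
            c1 = triples[t, 1] * size
            c2 = triples[t, 2] * size
            for j in range(size):
                block[d + j] = block[c1 + j] + block[c2 + j]
        for t in range(nt):
            d = triples[t, 0]
            c1 = triples[t, 1]
            c2 = triples[t, 2]
            for i in range(0, size * size, size):
                block[i + d] = block[i + c1] + block[i + c2]


@njit(cache=False)
def _popcount_accumulate(packed, counts):  # pragma: no cover - numba
    one = np.uint64(1)
    for i in range(packed.size):
        x = packed[i]
        n = 0
        while x:
            x &= x - one
            n += 1
        counts[i] += n


def _numpy_derive_axis(arr, size, left, right, triples, op):
    view = arr.reshape(left, size, right)
    for d, c1, c2 in triples:
        op(view[:, c1, :], view[:, c2, :], out=view[:, d, :])


def superset_transform(
    arr: np.ndarray, alphabet: MotifAlphabet, word_length: int, op: str = "or"
) -> None:
    """In-place separable transform deriving every degenerate code's value.

    With ``op='or'`` the result at ``code`` is the OR over all concrete words
    the oligo matches; with ``op='add'`` it is the sum (exact because wobble
    match sets partition into disjoint base sets).
    """
    size = alphabet.size
    triples = np.asarray(alphabet.derivations, dtype=np.int64)
    ufunc = np.bitwise_or if op == "or" else np.add
    use_blocks = _HAVE_NUMBA and word_length >= 2 and arr.size >= size * size
    outer_axes = word_length - 2 if use_blocks else word_length
    for pos in range(outer_axes):
        left = size**pos
        right = size ** (word_length - 1 - pos)
        if _HAVE_NUMBA and right >= size * size:
            kern = _derive_axis_or if op == "or" else _derive_axis_add
            kern(arr, size, left, right, triples)
        else:
            _numpy_derive_axis(arr, size, left, right, triples, ufunc)
    if use_blocks:
        kern2 = _derive_block_or if op == "or" else _derive_block_add
        kern2(arr.reshape(-1, size * size), size, triples)


# -- window extraction -----------------------------------------------------


def window_digits(seq: str, word_length: int) -> Tuple[np.ndarray, np.ndarray]:
    """Digit rows of all clean L-mer windows and their 1-based starts.

    Windows overlapping an ``N`` are skipped entirely.
    """
    raw = _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if raw.size < word_length:
        return np.empty((0, word_length), np.uint8), np.empty(0, np.int64)
    win = np.lib.stride_tricks.sliding_window_view(raw, word_length)
    valid = (win < 4).all(axis=1)
    starts = np.flatnonzero(valid).astype(np.int64) + 1
    return np.ascontiguousarray(win[valid]), starts


def concrete_window_codes(
    seq: str, word_length: int, alphabet: MotifAlphabet
) -> Tuple[np.ndarray, np.ndarray]:
    """Concrete positional-notation codes of clean windows, with 1-based starts."""
    win, starts = window_digits(seq, word_length)
    powers = alphabet.size ** np.arange(word_length - 1, -1, -1, dtype=np.int64)
    return win.astype(np.int64) @ powers, starts


def match_windows(
    oligo_digits: np.ndarray, win: np.ndarray, alphabet: MotifAlphabet
) -> np.ndarray:
    """Boolean mask over window rows matched by one oligo (digit vector)."""
    tab = alphabet.match_table
    ok = tab[oligo_digits[0], win[:, 0]]
    for pos in range(1, len(oligo_digits)):
        ok &= tab[oligo_digits[pos], win[:, pos]]
    return ok


# -- indexes ---------------------------------------------------------------


@dataclass
class OligoCountIndex:
    """Dense per-oligo promoter-presence counts over a promoter set.

    ``counts[code]`` is the number of promoters harboring at least one window
    matched by ``decode(code)``; each promoter contributes at most 1 per oligo
    regardless of occurrence multiplicity.
    """

    counts: np.ndarray
    n_promoters: int
    alphabet: MotifAlphabet
    word_length: int

    def __post_init__(self) -> None:
        if self.counts.size != self.alphabet.size**self.word_length:
            raise ValueError("counts length does not match alphabet**L")


@dataclass
class OccurrenceIndex:
    """Per-oligo occurrence counts and position sums over a promoter set.

    Occurrences are counted per window (several per promoter allowed), the
    quantity the position-bias z-score's *n* refers to.  ``mean position`` of
    an oligo is ``pos_sum[code] / occurrences[code]``.
    """

    occurrences: np.ndarray
    pos_sum: np.ndarray
    n_promoters: int
    total_windows: int
    window_length: int
    alphabet: MotifAlphabet
    word_length: int


def index_promoters(
    promoters: PromoterSet,
    alphabet: MotifAlphabet = ALPHA11,
    word_length: int = 8,
    counts_dtype: Optional[np.dtype] = None,
) -> OligoCountIndex:
    """Count, for every oligo, the number of promoters harboring it."""
    if promoters.window_length < word_length:
        raise ValueError("window_length shorter than the word length")
    size = alphabet.size**word_length
    n = len(promoters)
    if counts_dtype is None:
        counts_dtype = np.uint16 if n < 2**16 else np.uint32
    if np.iinfo(counts_dtype).max < n:
        raise ValueError("counts dtype cannot hold the promoter count")
    counts = np.zeros(size, dtype=counts_dtype)
    packed = np.zeros(size, dtype=np.uint64)
    for batch_start in range(0, n, 64):
        if batch_start:
            packed[:] = 0
        stop = min(batch_start + 64, n)
        for j in range(batch_start, stop):
            codes, _ = concrete_window_codes(
                promoters.sequences[j], word_length, alphabet
            )
            if codes.size:
                packed[codes] |= np.uint64(1 << (j - batch_start))
        superset_transform(packed, alphabet, word_length, op="or")
        if _HAVE_NUMBA:
            _popcount_accumulate(packed, counts)
        else:
            np.add(counts, np.bitwise_count(packed), out=counts, casting="unsafe")
    return OligoCountIndex(counts, n, alphabet, word_length)


def occurrence_index(
    promoters: PromoterSet,
    alphabet: MotifAlphabet = ALPHA11,
    word_length: int = 8,
) -> OccurrenceIndex:
    """Occurrence counts and position sums for every oligo at once."""
    if promoters.window_length < word_length:
        raise ValueError("window_length shorter than the word length")
    size = alphabet.size**word_length
    total_windows = 0
    max_start = promoters.window_length - word_length + 1
    # position sums can exceed int32 only for very large inputs
    pos_bound = len(promoters) * max_start * max_start
    occ = np.zeros(size, dtype=np.int32)
    pos_sum = np.zeros(
        size, dtype=np.int32 if pos_bound < 2**31 else np.int64
    )
    for seq in promoters.sequences:
        codes, starts = concrete_window_codes(seq, word_length, alphabet)
        if codes.size:
            np.add.at(occ, codes, 1)
            np.add.at(pos_sum, codes, starts.astype(pos_sum.dtype))
            total_windows += codes.size
    superset_transform(occ, alphabet, word_length, op="add")
    superset_transform(pos_sum, alphabet, word_length, op="add")
    return OccurrenceIndex(
        occ,
        pos_sum,
        len(promoters),
        total_windows,
        promoters.window_length,
        alphabet,
        word_length,
    )


def collect_positions(
    promoters: PromoterSet, oligo_word: str, alphabet: MotifAlphabet = ALPHA11
) -> Dict[str, List[int]]:
    """All 1-based start positions of windows matched by an oligo, per gene.

    Genes without any occurrence are omitted; a gene appears here iff the
    presence index counted it.
    """
    word = alphabet.canonicalize(oligo_word)
    digits = np.array([alphabet.digit_of[c] for c in word], dtype=np.int64)
    out: Dict[str, List[int]] = {}
    for gene_id, seq in promoters:
        win, starts = window_digits(seq, len(word))
        if not win.size:
            continue
        hits = starts[match_windows(digits, win, alphabet)]
        if hits.size:
            out[gene_id] = [int(s) for s in hits]
    return out


# -- serialization ---------------------------------------------------------


def save_index(index: OligoCountIndex, prefix) -> None:
    """Write a raw little-endian counter array plus a JSON sidecar."""
    prefix = Path(prefix)
    raw = index.counts.astype(index.counts.dtype.newbyteorder("<"), copy=False)
    data_path = prefix.with_suffix(".counts")
    raw.tofile(data_path)
    meta = {
        "alphabet": index.alphabet.name,
        "word_length": index.word_length,
        "n_promoters": index.n_promoters,
        "dtype": index.counts.dtype.str.replace(">", "<"),
        "sha256": hashlib.sha256(raw.tobytes()).hexdigest(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_index(prefix) -> OligoCountIndex:
    """Load an index written by :func:`save_index`, verifying the checksum."""
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    counts = np.fromfile(prefix.with_suffix(".counts"), dtype=meta["dtype"])
    if hashlib.sha256(counts.tobytes()).hexdigest() != meta["sha256"]:
        raise IOError(f"checksum mismatch for {prefix}")
    return OligoCountIndex(
        counts,
        int(meta["n_promoters"]),
        alphabet_by_name(meta["alphabet"]),
        int(meta["word_length"]),
    )
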