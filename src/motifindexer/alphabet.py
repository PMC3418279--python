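"""Degenerate motif alphabets and the positional-notation oligo codec.

Motifs are words over a small alphabet of concrete bases (A, C, G, T) plus
degenerate "wobble" letters, each of which stands for a set of bases:

    r = {A,G}   y = {C,T}   s = {C,G}   w = {A,T}
    m = {A,C}   k = {G,T}   n = {A,C,G,T}

Two alphabets are used throughout the package:

* :data:`ALPHA11` -- the full 11-letter alphabet (all two-fold wobbles plus
  ``n``), used for 8-mer motifs.  There are ``11**8 = 214,358,881`` possible
  8-mers in this alphabet.
* :data:`ALPHA5` -- A, C, G, T, ``n`` only, used for 12-mer motifs
  (``5**12 = 244,140,625`` words).

Every word maps bijectively onto an integer *code* by reading its letters as
digits of a base-``|alphabet|`` number, leftmost letter most significant
(A, C, G, T, r, y, s, w, m, k, n -> 0..10).  Dense per-oligo arrays are
indexed by this code.

Three-fold wobbles (IUPAC b, d, h, v) are deliberately not representable.
Motif strings are written with uppercase concrete bases and lowercase wobble
letters (e.g. ``rGTCAAmn``); parsing is case-insensitive apart from the
inherent A/w-style collisions handled by :meth:`MotifAlphabet.canonicalize`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Tuple

import numpy as np

__all__ = [
    "MotifAlphabet",
    "ALPHA11",
    "ALPHA5",
    "encode",
    "decode",
    "degenerate_expansions",
    "expansion_count",
    "matches",
    "reverse_complement",
    "canonical_word",
    "n_words",
]

BASES = "ACGT"
_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: match sets of the degenerate letters (concrete bases map to themselves)
WOBBLE_SETS: Dict[str, FrozenSet[str]] = {
    "r": frozenset("AG"),
    "y": frozenset("CT"),
    "s": frozenset("CG"),
    "w": frozenset("AT"),
    "m": frozenset("AC"),
    "k": frozenset("GT"),
    "n": frozenset("ACGT"),
}


class InvalidLetterError(ValueError):
    """A word contains a letter outside its motif alphabet."""


@dataclass(frozen=True)
class MotifAlphabet:
    """An ordered motif alphabet with its digit assignment.

    Parameters
    ----------
    name:
        Short identifier ("alpha11" / "alpha5").
    letters:
        Canonical letter string; the digit of a letter is its index here.
    derivations:
        Binary derivation triples ``(target, src1, src2)`` (digits) such that
        applying them in order, per word position, builds every degenerate
        letter's value from values of previously available letters.  Used by
        the array transforms in :mod:`motifindexer.indexing`; validated at
        construction against the letters' match sets.
    """

    name: str
    letters: str
    derivations: Tuple[Tuple[int, int, int], ...]
    digit_of: Dict[str, int] = field(init=False, repr=False)
    matches_of: Dict[str, FrozenSet[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "digit_of", {c: i for i, c in enumerate(self.letters)}
        )
        matches_of = {}
        for c in self.letters:
            matches_of[c] = (
                frozenset(c) if c in BASES else WOBBLE_SETS[c]
            )
        object.__setattr__(self, "matches_of", matches_of)
        self._validate_derivations()

    def _validate_derivations(self) -> None:
        # Replay the derivation triples on match sets: each step must combine
        # two already-built, *disjoint* sets (disjointness is what makes the
        # same triples valid for both the OR and the occurrence-sum transform),
        # and every degenerate letter must end up with its declared match set.
        acc: Dict[int, FrozenSet[str]] = {
            self.digit_of[b]: frozenset(b) for b in BASES if b in self.digit_of
        }
        for target, s1, s2 in self.derivations:
            if s1 not in acc or s2 not in acc:
                raise ValueError(f"derivation of digit {target} uses un-built source")
            if acc[s1] & acc[s2]:
                raise ValueError(
                    f"derivation of digit {target} combines overlapping sets; "
                    "the additive transform would double-count"
                )
            acc[target] = acc[s1] | acc[s2]
        for c in self.letters:
            d = self.digit_of[c]
            if c not in BASES and acc.get(d) != self.matches_of[c]:
                raise ValueError(f"derivations do not reproduce letter {c!r}")

    # -- basic properties -------------------------------------------------

    @property
    def size(self) -> int:
        return len(self.letters)

    def __len__(self) -> int:
        return len(self.letters)

    def __contains__(self, letter: str) -> bool:
        return letter in self.digit_of

    @property
    def complement_digits(self) -> np.ndarray:
        """Digit permutation mapping each letter to its complement letter."""
        out = np.empty(self.size, dtype=np.int64)
        for c, d in self.digit_of.items():
            comp_set = frozenset(_COMPLEMENT_BASE[b] for b in self.matches_of[c])
            comp_letter = next(
                l for l, s in self.matches_of.items() if s == comp_set
            )
            out[d] = self.digit_of[comp_letter]
        return out

    @property
    def match_table(self) -> np.ndarray:
        """Boolean table ``(size, 4)``: letter digit x base digit -> matches."""
        tab = np.zeros((self.size, 4), dtype=bool)
        for c, d in self.digit_of.items():
            for b in self.matches_of[c]:
                tab[d, BASES.index(b)] = True
        return tab

    def canonicalize(self, word: str) -> str:
        """Normalize case to the canonical dialect (ACGT upper, wobbles lower)."""
        out = []
        for i, c in enumerate(word):
            if c.upper() in BASES:
                out.append(c.upper())
            elif c.lower() in WOBBLE_SETS and c.lower() in self.digit_of:
                out.append(c.lower())
            else:
                raise InvalidLetterError(
                    f"invalid letter {c!r} at position {i + 1} for alphabet "
                    f"{self.name}"
                )
        return "".join(out)

    def letters_matching(self, base: str) -> Tuple[str, ...]:
        """All alphabet letters whose match set contains ``base``."""
        return tuple(c for c in self.letters if base in self.matches_of[c])


#: 11-letter alphabet for 8-mer motifs; digits A..n -> 0..10.
ALPHA11 = MotifAlphabet(
    name="alpha11",
    letters="ACGTryswmkn",
    derivations=(
        (4, 0, 2),   # r = A|G
        (5, 1, 3),   # y = C|T
        (6, 1, 2),   # s = C|G
        (7, 0, 3),   # w = A|T
        (8, 0, 1),   # m = A|C
        (9, 2, 3),   # k = G|T
        (10, 4, 5),  # n = r|y
    ),
)

#: 5-letter alphabet for 12-mer motifs; digits A..n -> 0..4.
ALPHA5 = MotifAlphabet(
    name="alpha5",
    letters="ACGTn",
    derivations=(
        (4, 0, 1),
        (4, 4, 2),
        (4, 4, 3),
    ),
)

_ALPHABETS = {"alpha11": ALPHA11, "alpha5": ALPHA5}


def alphabet_by_name(name: str) -> MotifAlphabet:
    try:
        return _ALPHABETS[name]
    except KeyError:
        raise KeyError(f"unknown alphabet {name!r}") from None


# sanity: search-space cardinalities stated throughout the docs
assert len(ALPHA11) ** 8 == 214_358_881
assert len(ALPHA5) ** 12 == 244_140_625
# each concrete base belongs to exactly 3 two-fold wobbles of ALPHA11
assert all(
    sum(1 for w, s in WOBBLE_SETS.items() if w != "n" and b in s) == 3
    for b in BASES
)


def n_words(alphabet: MotifAlphabet, word_length: int) -> int:
    """Number of possible words of ``word_length`` over ``alphabet``."""
    return alphabet.size ** word_length


def encode(word: str, alphabet: MotifAlphabet) -> int:
    """Positional-notation integer code of a degenerate word.

    The leftmost letter is the most significant digit:
    ``code = sum(digit(word[i]) * size**(L-1-i))``.
    """
    word = alphabet.canonicalize(word)
    code = 0
    for c in word:
        code = code * alphabet.size + alphabet.digit_of[c]
    return code


def decode(code: int, word_length: int, alphabet: MotifAlphabet) -> str:
    """Inverse of :func:`encode`."""
    if not 0 <= code < alphabet.size ** word_length:
        raise ValueError(
            f"code {code} out of range for {alphabet.name}^{word_length}"
        )
    letters = []
    for _ in range(word_length):
        code, d = divmod(code, alphabet.size)
        letters.append(alphabet.letters[d])
    return "".join(reversed(letters))


def expansion_count(concrete_word: str, alphabet: MotifAlphabet) -> int:
    """Size of the degenerate-expansion set of a concrete word (product rule)."""
    total = 1
    for base in concrete_word.upper():
        if base not in BASES:
            raise ValueError(f"non-concrete base {base!r} in word")
        total *= len(alphabet.letters_matching(base))
    return total


def degenerate_expansions(concrete_word: str, alphabet: MotifAlphabet):
    """All degenerate words matching a concrete word (the word included).

    Each position independently takes any alphabet letter whose match set
    contains the base at that position: 5 choices per position for
    :data:`ALPHA11` (the base, its three two-fold wobbles, and ``n``), 2 for
    :data:`ALPHA5`.  Returns a set of canonical word strings; for 8-mers over
    ALPHA11 this is ``5**8 = 390,625`` words, so prefer
    :func:`expansion_count` when only the size is needed.
    """
    word = concrete_word.upper()
    if any(b not in BASES for b in word):
        raise ValueError(
            "degenerate_expansions requires a concrete A/C/G/T word "
            f"(got {concrete_word!r}); windows containing N must be skipped"
        )
    choices = [alphabet.letters_matching(b) for b in word]
    return {"".join(p) for p in itertools.product(*choices)}


def matches(oligo_word: str, window: str, alphabet: MotifAlphabet = ALPHA11) -> bool:
    """True iff every window base is in the match set of the oligo letter.

    Any ``N`` in the *window* matches nothing (sequence-side ambiguity is not
    motif-side degeneracy), so a window containing ``N`` never matches.
    """
    if len(oligo_word) != len(window):
        raise ValueError(
            f"length mismatch: oligo {len(oligo_word)} vs window {len(window)}"
        )
    word = alphabet.canonicalize(oligo_word)
    for c, b in zip(word, window.upper()):
        if b not in BASES or b not in alphabet.matches_of[c]:
            return False
    return True


def reverse_complement(word: str, alphabet: MotifAlphabet = ALPHA11) -> str:
    """Letter-wise complement (A<->T, C<->G, r<->y, m<->k, s/w/n fixed), reversed."""
    word = alphabet.canonicalize(word)
    comp = alphabet.complement_digits
    return "".join(
        alphabet.letters[comp[alphabet.digit_of[c]]] for c in reversed(word)
    )


def canonical_word(word: str, alphabet: MotifAlphabet = ALPHA11) -> str:
    """The member of an RC pair with the smaller code (strand-invariant key)."""
    word = alphabet.canonicalize(word)
    rc = reverse_complement(word, alphabet)
    return word if encode(word, alphabet) <= encode(rc, alphabet) else rc


# -- vectorized helpers on code arrays ------------------------------------


def digits_of_codes(codes: np.ndarray, word_length: int, alphabet: MotifAlphabet) -> np.ndarray:
    """Digit matrix ``(n, L)`` of an integer code array, most significant first."""
    codes = np.asarray(codes, dtype=np.int64)
    out = np.empty((codes.size, word_length), dtype=np.int8)
    rem = codes.copy()
    for pos in range(word_length - 1, -1, -1):
        rem, d = np.divmod(rem, alphabet.size)
        out[:, pos] = d
    return out


def codes_of_digits(digits: np.ndarray, alphabet: MotifAlphabet) -> np.ndarray:
    """Inverse of :func:`digits_of_codes`."""
    digits = np.asarray(digits, dtype=np.int64)
    powers = alphabet.size ** np.arange(digits.shape[1] - 1, -1, -1, dtype=np.int64)
    return digits @ powers


def rc_codes(codes: np.ndarray, word_length: int, alphabet: MotifAlphabet) -> np.ndarray:
    """Reverse-complement codes of an integer code array (vectorized)."""
    digits = digits_of_codes(codes, word_length, alphabet)
    comp = alphabet.complement_digits[digits][:, ::-1]
    return codes_of_digits(comp, alphabet)
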