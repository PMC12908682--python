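"""Overlapping k-mer tokenization of enhancer and promoter sequences.

DNA sequences are turned into integer token sequences over a fixed
``4^k + 1`` vocabulary: every k-mer made of unambiguous bases gets a
base-4 positional code (A=0, C=1, G=2, T=3, most-significant base
first), and any k-mer touching an ambiguous base (N, IUPAC codes, gaps)
maps to a single special token.  With the default k=6 this gives 4096
regular codes plus the special index 4096.

Canonical element lengths are 3000 bp for enhancers and 2000 bp for
promoters, i.e. 2995 / 1995 overlapping 6-mer tokens.  Inputs that
deviate are center-padded with N or center-trimmed by
:func:`canonicalize_length`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical element widths in bp (fixed by the 2995/1995 token counts).
ENHANCER_LENGTH_BP = 3000
PROMOTER_LENGTH_BP = 2000

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"


class InvalidKmerError(ValueError):
    """Raised when a string of the wrong length is offered as a k-mer."""


@dataclass(frozen=True)
class KmerVocabulary:
    """The fixed k-mer vocabulary: ``4^k`` positional codes + 1 special token.

    The code assignment is lexicographic base-4 with A<C<G<T; it is a
    bijection between ``{A,C,G,T}^k`` and ``[0, 4^k)``.
    """

    k: int = 6
    size: int = field(init=False)
    special_index: int = field(init=False)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be positive, got {self.k}")
        object.__setattr__(self, "size", 4 ** self.k + 1)
        object.__setattr__(self, "special_index", 4 ** self.k)

    def encode(self, kmer: str) -> int:
        return encode_kmer(kmer, k=self.k)

    def decode(self, index: int) -> str:
        return decode_kmer(index, k=self.k)

    def kmers(self):
        """All 4^k regular k-mers in code order."""
        return (self.decode(i) for i in range(self.size - 1))


DEFAULT_VOCAB = KmerVocabulary(k=6)


def encode_kmer(kmer: str, k: int = 6) -> int:
    """Encode one k-mer as its base-4 positional code.

    Case-insensitive; any character outside {A,C,G,T} sends the whole
    k-mer to the special index ``4^k``.

    Raises
    ------
    InvalidKmerError
        If ``len(kmer) != k``.
    """
    if len(kmer) != k:
        raise InvalidKmerError(f"expected a {k}-mer, got {len(kmer)} characters: {kmer!r}")
    code = 0
    for ch in kmer.upper():
        b = _BASE_CODE.get(ch)
        if b is None:
            return 4 ** k
        code = code * 4 + b
    return code


def decode_kmer(index: int, k: int = 6) -> str:
    """Inverse of :func:`encode_kmer` on the regular codes ``[0, 4^k)``."""
    if not 0 <= index < 4 ** k:
        raise ValueError(f"index {index} outside regular code range [0, {4 ** k})")
    out = []
    for _ in range(k):
        index, r = divmod(index, 4)
        out.append(_CODE_BASE[r])
    return "".join(reversed(out))


def tokenize(sequence: str, k: int = 6) -> np.ndarray:
    """Tokenize a DNA sequence into overlapping k-mers, stride 1.

    Returns an int32 array of length ``len(sequence) - k + 1``.  A
    sequence of 3000 bp yields 2995 tokens; 2000 bp yields 1995.

    Raises
    ------
    ValueError
        If the sequence is shorter than ``k``.
    """
    n = len(sequence)
    if n < k:
        raise ValueError(f"sequence of length {n} is shorter than k={k}")
    seq = sequence.upper()
    # Vectorized positional encoding: per-base codes, 4^k on ambiguity.
    codes = np.full(n, -1, dtype=np.int64)
    arr = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    for base, c in _BASE_CODE.items():
        codes[arr == ord(base)] = c
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    toks = windows @ powers
    bad = (windows < 0).any(axis=1)
    toks[bad] = 4 ** k
    return toks.astype(np.int32)


def canonicalize_length(sequence: str, target_bp: int) -> str:
    """Force a sequence to the canonical width.

    Shorter sequences are center-padded with N (ambiguous) on both
    sides; longer ones are center-trimmed.  Both events are logged.
    """
    n = len(sequence)
    if n == target_bp:
        return sequence
    if n < target_bp:
        pad = target_bp - n
        left = pad // 2
        logger.info("center-padding sequence from %d to %d bp", n, target_bp)
        return "N" * left + sequence + "N" * (pad - left)
    trim = n - target_bp
    left = trim // 2
    logger.info("center-trimming sequence from %d to %d bp", n, target_bp)
    return sequence[left:left + target_bp]


def token_count(length_bp: int, k: int = 6) -> int:
    """Number of overlapping k-mers in a sequence of ``length_bp`` bases."""
    if length_bp < k:
        raise ValueError(f"length {length_bp} shorter than k={k}")
    return length_bp - k + 1
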