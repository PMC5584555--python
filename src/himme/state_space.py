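"""The k-mer state space and sequence tokenization.

The hidden states of the model are the ``4**k`` k-mers over the nucleotide
alphabet ``N = (A, C, G, T)``.  States are encoded as integers via the
lexicographic (base-4, A=0, C=1, G=2, T=3, first character most significant)
ordering, so ``"AAA" -> 0`` and ``"TTT" -> 63`` for ``k = 3``.

Sequences are broken into *non-overlapping* k-mers starting at position 0:
the chain of hidden states advances one full k-mer per step.  A trailing
partial window is dropped; any window containing an ambiguous base (N or any
IUPAC code outside ACGT) is skipped, and the chain is treated as contiguous
across the gap.  Lowercase input is folded to uppercase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import AmbiguousBaseError

ALPHABET = "ACGT"

#: Largest supported k-mer size.  The transition matrix is dense and its
#: memory footprint grows as 16**k, so the state space is capped explicitly.
MAX_K = 8

# 256-entry byte -> base-code lookup; -1 marks ambiguous characters.
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_BASE_BYTES = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class KmerStateSpace:
    """The hidden-state alphabet E of all ``4**k`` k-mers over ACGT.

    Parameters
    ----------
    k : int
        k-mer size, ``1 <= k <= MAX_K``.
    """

    k: int
    alphabet: str = ALPHABET

    def __post_init__(self) -> None:
        if not isinstance(self.k, (int, np.integer)) or not 1 <= self.k <= MAX_K:
            raise ValueError(f"k must be an integer in [1, {MAX_K}], got {self.k!r}")
        if self.alphabet != ALPHABET:
            raise ValueError("only the nucleotide alphabet ACGT is supported")

    @property
    def cardinality(self) -> int:
        """Number of states, ``|E| = 4**k``."""
        return 4 ** self.k

    @property
    def powers(self) -> np.ndarray:
        """Base-4 place values ``(4**(k-1), ..., 4, 1)`` used for encoding."""
        return 4 ** np.arange(self.k - 1, -1, -1, dtype=np.int64)

    def state_bases(self) -> np.ndarray:
        """(|E|, k) array giving the base code of every state at every position."""
        idx = np.arange(self.cardinality, dtype=np.int64)
        return (idx[:, None] // self.powers[None, :]) % 4

    def encode(self, kmer: str) -> int:
        return encode_kmer(kmer, self)

    def decode(self, index: int) -> str:
        return decode_kmer(index, self)


def encode_bases(seq: str) -> np.ndarray:
    """Map a nucleotide string to an int8 code array; ambiguous bases become -1."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def decode_bases(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_bases` for unambiguous code arrays."""
    return _BASE_BYTES[np.asarray(codes, dtype=np.int64)].tobytes().decode("ascii")


def encode_kmer(kmer: str, space: KmerStateSpace) -> int:
    """Integer index of ``kmer`` in the lexicographic ordering of E."""
    if len(kmer) != space.k:
        raise ValueError(f"expected a k-mer of length {space.k}, got {len(kmer)}")
    codes = encode_bases(kmer)
    if (codes < 0).any():
        bad = kmer[int(np.argmax(codes < 0))]
        raise AmbiguousBaseError(f"ambiguous base {bad!r} in k-mer {kmer!r}")
    return int(codes.astype(np.int64) @ space.powers)


def decode_kmer(index: int, space: KmerStateSpace) -> str:
    """k-mer string at position ``index`` of the state space; inverts encode_kmer."""
    if not 0 <= index < space.cardinality:
        raise ValueError(f"state index {index} outside [0, {space.cardinality})")
    digits = (index // space.powers) % 4
    return decode_bases(digits)


@dataclass(frozen=True)
class KmerSequence:
    """A tokenized nucleotide sequence: the observed k-mer chain.

    Attributes
    ----------
    kmers : numpy.ndarray
        State-space indices of the retained non-overlapping k-mers, in order.
    m : int
        Number of retained k-mers (``len(kmers)``).
    dropped_tail : int
        Trailing bases that did not fill a complete window.
    skipped : int
        Complete windows discarded because they contained an ambiguous base.
    k : int
        k-mer size used for tokenization.

    The accounting identity ``k*m + k*skipped + dropped_tail == len(source)``
    always holds.
    """

    kmers: np.ndarray
    m: int
    dropped_tail: int
    skipped: int
    k: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "kmers", np.asarray(self.kmers, dtype=np.int64))


def tokenize_sequence(seq: str, space: KmerStateSpace) -> KmerSequence:
    """Break ``seq`` into consecutive non-overlapping k-mers from position 0.

    Returns an ``m = 0`` record (not an error) when no complete unambiguous
    window exists.  Raises ``ValueError`` on an empty input string.
    """
    if len(seq) == 0:
        raise ValueError("cannot tokenize an empty sequence")
    k = space.k
    n_windows, dropped_tail = divmod(len(seq), k)
    if n_windows == 0:
        return KmerSequence(np.empty(0, np.int64), 0, dropped_tail, 0, k)
    codes = encode_bases(seq[: n_windows * k]).reshape(n_windows, k)
    valid = (codes >= 0).all(axis=1)
    # Clip ambiguous (-1) codes before the dot product; invalid rows are masked out.
    kmers = (np.maximum(codes, 0).astype(np.int64) @ space.powers)[valid]
    skipped = int(n_windows - valid.sum())
    return KmerSequence(kmers, int(valid.sum()), dropped_tail, skipped, k)
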