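"""Estimating the hidden-state chain: initial distribution and transition matrix.

The hidden k-mer chain is a first-order Markov chain over the ``4**k`` states.
Training parses a set of sequences and counts adjacent k-mer pairs — the
window ``[i, i+k)`` followed by ``[i+k, i+2k)``.  By default every start
offset ``i`` contributes (``mode="sliding"``), pooling all k phase offsets;
``mode="chunked"`` counts a single phase (``i = 0, k, 2k, ...``) matching the
non-overlapping tokenization used at scoring time.  Pooling phases is
phase-invariant and makes fuller use of limited training data.

Counts are additively smoothed: row ``s`` of the transition matrix is
``(count(s, .) + a) / (sum(count(s, .)) + 4**k * a)`` for pseudocount ``a``.
The initial distribution ``pi0`` is the identically smoothed global k-mer
frequency of the training set (all valid sliding windows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import EmptyTrainingError, UntrainedStateError
from .io import iter_sequences
from .state_space import KmerSequence, KmerStateSpace, encode_bases

_ROW_SUM_TOL = 1e-12


@dataclass
class TransitionModel:
    """Initial distribution and row-stochastic k-mer transition matrix.

    Attributes
    ----------
    space : KmerStateSpace
    pi0 : (|E|,) ndarray
        Initial state distribution.
    trans : (|E|, |E|) ndarray
        ``trans[s, i] = P[X_n = i | X_{n-1} = s]``; every row sums to 1.
    pseudocount : float
        Additive smoothing constant used during estimation.
    training_meta : dict
        Provenance: source, sequence count, base count, transition count, mode.
    counts : ndarray or None
        Raw (unsmoothed) transition counts, kept when estimated from data.
    """

    space: KmerStateSpace
    pi0: np.ndarray
    trans: np.ndarray
    pseudocount: float = 0.0
    training_meta: dict = field(default_factory=dict)
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pi0 = np.asarray(self.pi0, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        card = self.space.cardinality
        if self.pi0.shape != (card,) or self.trans.shape != (card, card):
            raise ValueError("pi0/trans shapes do not match the state space")

    def validate(self) -> None:
        """Check stochasticity invariants (row sums 1 within 1e-12, entries >= 0)."""
        if (self.trans < 0).any() or (self.pi0 < 0).any():
            raise ValueError("negative probabilities in transition model")
        if abs(self.pi0.sum() - 1.0) > _ROW_SUM_TOL * self.space.cardinality:
            raise ValueError("pi0 does not sum to 1")
        dev = np.abs(self.trans.sum(axis=1) - 1.0).max()
        if dev > _ROW_SUM_TOL * self.space.cardinality:
            raise ValueError(f"transition rows deviate from stochasticity by {dev:g}")

    @classmethod
    def uniform(cls, space: KmerStateSpace) -> "TransitionModel":
        card = space.cardinality
        return cls(
            space=space,
            pi0=np.full(card, 1.0 / card),
            trans=np.full((card, card), 1.0 / card),
            training_meta={"source": "uniform"},
        )


def _rolling_codes(arr: np.ndarray, space: KmerStateSpace) -> tuple[np.ndarray, np.ndarray]:
    """All length-k window codes of a base-code array, plus a validity mask."""
    k = space.k
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = (windows >= 0).all(axis=1)
    codes = np.maximum(windows, 0).astype(np.int64) @ space.powers
    return codes, valid


def learn_transition_model(
    training,
    space: KmerStateSpace,
    pseudocount: float = 1.0,
    mode: str = "sliding",
    source: str | None = None,
) -> TransitionModel:
    """Estimate a :class:`TransitionModel` from training sequences.

    Parameters
    ----------
    training : FASTA path, handle, string, or iterable of sequences/records
    space : KmerStateSpace
    pseudocount : float
        Additive smoothing constant (>= 0).  With 0, every state must be
        observed as a transition source or :class:`UntrainedStateError` is
        raised.
    mode : {"sliding", "chunked"}
        Whether adjacent-pair counting pools all start offsets or uses the
        single phase starting at 0.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if mode not in ("sliding", "chunked"):
        raise ValueError(f"unknown counting mode {mode!r}")
    card = space.cardinality
    k = space.k
    trans_counts = np.zeros(card * card, dtype=np.int64)
    kmer_counts = np.zeros(card, dtype=np.int64)
    n_seq = 0
    n_bases = 0
    for _sid, seq in iter_sequences(training):
        n_seq += 1
        n_bases += len(seq)
        if len(seq) < k:
            continue
        arr = encode_bases(seq)
        codes, valid = _rolling_codes(arr, space)
        kmer_counts += np.bincount(codes[valid], minlength=card)
        if len(seq) < 2 * k:
            continue
        starts = np.arange(0, len(seq) - 2 * k + 1, 1 if mode == "sliding" else k)
        ok = valid[starts] & valid[starts + k]
        pairs = codes[starts[ok]] * card + codes[starts[ok] + k]
        trans_counts += np.bincount(pairs, minlength=card * card)
    counts = trans_counts.reshape(card, card)
    row_tot = counts.sum(axis=1)
    if pseudocount == 0:
        if counts.sum() == 0:
            raise EmptyTrainingError(
                "no countable k-mer transition in the training input and pseudocount is 0"
            )
        if (row_tot == 0).any():
            missing = int((row_tot == 0).sum())
            raise UntrainedStateError(
                f"{missing} of {card} states never occur as a transition source; "
                "their rows are undefined with pseudocount 0"
            )
        if kmer_counts.sum() == 0:
            raise EmptyTrainingError("no k-mer observed for pi0 and pseudocount is 0")
    trans = (counts + pseudocount) / (row_tot + card * pseudocount)[:, None]
    pi0 = (kmer_counts + pseudocount) / (kmer_counts.sum() + card * pseudocount)
    model = TransitionModel(
        space=space,
        pi0=pi0,
        trans=trans,
        pseudocount=float(pseudocount),
        training_meta={
            "source": source or getattr(training, "name", None) or _describe_source(training),
            "n_sequences": n_seq,
            "n_bases": n_bases,
            "n_transitions": int(counts.sum()),
            "mode": mode,
        },
        counts=counts,
    )
    model.validate()
    return model


def _describe_source(training) -> str:
    if isinstance(training, (str,)) and len(training) < 200:
        return str(training)[:60]
    return type(training).__name__


def mc_sequence_log_probability(seq: KmerSequence, model: TransitionModel) -> float:
    """Log probability of a hidden-state path under the Markov chain.

    Returns ``log pi0(x1) + sum_i log P[x_i | x_{i-1}]``; ``-inf`` (the
    documented sentinel) when any factor is zero.
    """
    if seq.m < 1:
        raise ValueError("sequence has no k-mer (m == 0)")
    x = seq.kmers
    factors = np.empty(seq.m)
    factors[0] = model.pi0[x[0]]
    factors[1:] = model.trans[x[:-1], x[1:]]
    if (factors == 0).any():
        return float("-inf")
    return float(np.sum(np.log(factors)))
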