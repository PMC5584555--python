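"""Seeded sequence simulators.

Four generators cover the study designs the package supports:

* :func:`simulate_random_sequences` — i.i.d. nucleotides with a configurable
  base composition (the "random" cohort; matching the composition to the
  reference is the worst case for a transition-based scorer).
* :func:`synthetic_reference` — a patterned pseudo-genome from a seeded
  higher-order base-level Markov chain, standing in for a real reference: it
  has genuine local dependency structure that a k-mer transition matrix can
  learn, which an i.i.d. string would not.
* :func:`sample_sequences_from_reference` — uniformly positioned,
  ambiguity-free substrings of a reference (the "true" cohort).
* :func:`sample_from_model` — sequences drawn from a trained model itself:
  a hidden k-mer chain from ``pi0``/``trans`` plus per-base emission noise.
"""

from __future__ import annotations

import numpy as np

from .emission import EmissionModel
from .exceptions import InvalidDistributionError
from .io import iter_sequences
from .state_space import decode_bases, encode_bases
from .transition import TransitionModel


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _check_composition(composition) -> np.ndarray:
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1.0) > 1e-9:
        raise InvalidDistributionError("composition must be 4 non-negative values summing to 1")
    return comp


def simulate_random_sequences(
    n: int, length: int, composition=(0.25, 0.25, 0.25, 0.25), seed=None
) -> list[str]:
    """``n`` i.i.d. nucleotide strings of the given length and base composition."""
    if n < 1 or length < 1:
        raise ValueError("n and length must be positive")
    comp = _check_composition(composition)
    rng = _as_rng(seed)
    draws = rng.choice(4, size=(n, length), p=comp)
    return [decode_bases(row) for row in draws]


def synthetic_reference(
    length: int = 100_000, order: int = 3, concentration: float = 0.5, seed=0
) -> str:
    """A patterned pseudo-genome from an order-``order`` base Markov chain.

    Conditional next-base distributions for each of the ``4**order`` contexts
    are drawn once from a Dirichlet with the given concentration; smaller
    concentration gives stronger local structure.  Fully determined by the
    seed.
    """
    if length < order + 1:
        raise ValueError("length must exceed the model order")
    rng = _as_rng(seed)
    n_ctx = 4**order
    cond = rng.dirichlet(np.full(4, concentration), size=n_ctx)
    cum = np.cumsum(cond, axis=1)
    out = np.empty(length, dtype=np.int64)
    out[:order] = rng.integers(0, 4, size=order)
    ctx = 0
    for j in range(order):
        ctx = ctx * 4 + out[j]
    mod = n_ctx // 4
    u = rng.random(length)
    for i in range(order, length):
        out[i] = np.searchsorted(cum[ctx], u[i], side="right")
        ctx = (ctx % mod) * 4 + out[i]
    return decode_bases(out)


def sample_sequences_from_reference(reference, n: int, length: int, seed=None) -> list[str]:
    """``n`` uniformly positioned, ambiguity-free substrings of the reference.

    ``reference`` is a FASTA path, string, or record iterable; windows are
    drawn within records, uniformly over all valid (ambiguity-free) start
    positions across records.
    """
    if n < 1 or length < 1:
        raise ValueError("n and length must be positive")
    rng = _as_rng(seed)
    seqs = []
    starts_per_record = []
    for _rid, seq in iter_sequences(reference):
        if len(seq) < length:
            continue
        arr = encode_bases(seq)
        windows_ok = (
            np.lib.stride_tricks.sliding_window_view(arr >= 0, length).all(axis=1)
            if length > 1
            else (arr >= 0)
        )
        valid = np.flatnonzero(windows_ok)
        if valid.size:
            seqs.append(seq)
            starts_per_record.append(valid)
    total = sum(v.size for v in starts_per_record)
    if total == 0:
        raise ValueError(f"reference contains no ambiguity-free window of length {length}")
    weights = np.array([v.size for v in starts_per_record], dtype=float) / total
    rec_idx = rng.choice(len(seqs), size=n, p=weights)
    out = []
    for r in rec_idx:
        start = int(rng.choice(starts_per_record[r]))
        out.append(seqs[r][start : start + length])
    return out


def sample_from_model(
    tm: TransitionModel,
    em: EmissionModel,
    n: int,
    length: int,
    seed=None,
    return_codes: bool = False,
):
    """Draw ``n`` observed sequences of ``length`` nt from the trained model.

    A hidden chain of ``m = length // k`` k-mers is sampled from ``pi0`` and
    the transition matrix, then per-base emission noise is applied.  With
    ``return_codes=True`` the (n, m) observed k-mer index array is returned
    instead of strings (the fast path for batch scoring).
    """
    k = tm.space.k
    m = length // k
    if m < 1:
        raise ValueError(f"length {length} holds no complete {k}-mer")
    rng = _as_rng(seed)
    card = tm.space.cardinality
    states = np.empty((n, m), dtype=np.int64)
    cum_pi0 = np.cumsum(tm.pi0)
    cum_trans = np.cumsum(tm.trans, axis=1)
    states[:, 0] = np.searchsorted(cum_pi0, rng.random(n) * cum_pi0[-1], side="right")
    for t in range(1, m):
        rows = cum_trans[states[:, t - 1]]
        u = rng.random(n) * rows[:, -1]
        states[:, t] = (rows >= u[:, None]).argmax(axis=1)
    # hidden bases, then per-base emission noise
    hidden = tm.space.state_bases()[states.ravel()].reshape(n, m * k)
    if em.is_identity:
        observed = hidden
    else:
        observed = np.empty_like(hidden)
        cum_em = np.cumsum(em.base_emission, axis=1)
        u = rng.random(hidden.shape)
        for b in range(4):
            mask = hidden == b
            observed[mask] = np.searchsorted(cum_em[b], u[mask] * cum_em[b, -1], side="right")
    observed = np.minimum(observed, 3)
    if return_codes:
        powers = tm.space.powers
        return observed.reshape(n, m, k).astype(np.int64) @ powers
    return [decode_bases(row) for row in observed]
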