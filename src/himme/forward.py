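"""The scaled forward algorithm and the per-frame normalized score.

The probability of an observed k-mer chain under the model is the marginal
over all hidden paths,

    P[Y] = sum_x pi0(x_1) e(y_1|x_1) prod_i e(y_i|x_i) P[x_i|x_{i-1}],

computed by the forward recursion

    alpha(1, i) = pi0(i) e(y_1|i)
    alpha(n, i) = sum_s alpha(n-1, s) p_si e(y_n|i)

in O(m |E|^2) time.  The raw alpha values underflow double precision for
assembly-scale sequences, so at every step the working vector is divided by
its mass ``a_t`` (the scaling factor is ``c_t = 1/a_t``) and the exact
log-likelihood is reconstructed from the accumulated log normalizers:
``log P[Y] = sum_t log a_t = -sum_t log c_t``.

The length-normalized score is the per-frame log-likelihood

    s_hat = -sum_t log(c_t) / (k * m) = log P[Y] / (k * m),

which divides by the number of nucleotides actually modeled and removes the
linear dependence of the raw score on sequence length, making contigs of
different lengths comparable.  Higher (closer to zero) means the sequence is
closer to the training patterns.  A zero-probability observation yields the
documented ``-inf`` sentinel rather than an exception.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emission import EmissionModel
from .exceptions import UndefinedScoreError
from .state_space import KmerSequence
from .transition import TransitionModel


@dataclass(frozen=True)
class ForwardResult:
    """Outcome of one scaled forward pass.

    ``log_scaling[t]`` is ``log a_t = -log c_t``, the log of the step-t
    normalizer; their sum equals ``log_likelihood``.  When the observation
    has probability zero the entry at the failing step is ``-inf`` and the
    remaining entries are zero.
    """

    log_likelihood: float
    log_scaling: np.ndarray
    m: int


def forward_log_likelihood(
    obs: KmerSequence, tm: TransitionModel, em: EmissionModel
) -> ForwardResult:
    """Exact ``log P[Y; Theta]`` of a tokenized observation, with scaling."""
    if obs.m < 1:
        raise UndefinedScoreError("observation has no k-mer (m == 0)")
    k = tm.space.k
    if obs.k != k:
        raise ValueError(f"observation tokenized with k={obs.k}, model has k={k}")
    ek = em.kmer_matrix(k)  # (|E| states, |E| observed k-mers)
    y = obs.kmers
    log_scaling = np.zeros(obs.m)
    alpha = tm.pi0 * ek[:, y[0]]
    a = alpha.sum()
    if a == 0.0:
        log_scaling[0] = -np.inf
        return ForwardResult(float("-inf"), log_scaling, obs.m)
    log_scaling[0] = np.log(a)
    alpha /= a
    trans = tm.trans
    for t in range(1, obs.m):
        alpha = (alpha @ trans) * ek[:, y[t]]
        a = alpha.sum()
        if a == 0.0:
            log_scaling[t] = -np.inf
            return ForwardResult(float("-inf"), log_scaling, obs.m)
        log_scaling[t] = np.log(a)
        alpha /= a
    return ForwardResult(float(np.sum(log_scaling)), log_scaling, obs.m)


def normalized_score(fr: ForwardResult, k: int) -> float:
    """Per-frame log-likelihood ``s_hat = log P[Y] / (k * m)``."""
    if fr.m < 1:
        raise UndefinedScoreError("normalized score undefined for m == 0")
    return fr.log_likelihood / (k * fr.m)


def forward_batch(codes: np.ndarray, tm: TransitionModel, em: EmissionModel) -> np.ndarray:
    """Log-likelihoods of ``n`` equal-length k-mer chains, computed jointly.

    ``codes`` is an (n, m) integer array of observed k-mer indices.  One
    matrix product per step services all sequences at once; this is the fast
    path used for reference-distribution simulation and benchmarks.  Returns
    an (n,) array; impossible observations get ``-inf``.
    """
    codes = np.asarray(codes, dtype=np.int64)
    if codes.ndim != 2 or codes.shape[1] < 1:
        raise ValueError("codes must be an (n, m >= 1) array")
    n, m = codes.shape
    k = tm.space.k
    ek = em.kmer_matrix(k)
    alpha = tm.pi0[None, :] * ek[:, codes[:, 0]].T
    loglik = np.zeros(n)
    for t in range(m):
        if t > 0:
            alpha = (alpha @ tm.trans) * ek[:, codes[:, t]].T
        a = alpha.sum(axis=1)
        dead = a == 0.0
        loglik += np.where(dead, -np.inf, np.log(np.where(dead, 1.0, a)))
        alpha /= np.where(dead, 1.0, a)[:, None]
    return loglik
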