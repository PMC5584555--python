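"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: the HMM likelihood is
computed by explicit summation over every hidden path, the naive-Bayes error
by numerical quadrature, and the Welch test by its textbook formulas.
"""

import itertools
import math

import numpy as np
from scipy import integrate, stats


def brute_force_log_likelihood(obs_codes, pi0, trans, kmer_emission) -> float:
    """log P[Y] by explicit summation over all |E|^m hidden paths.

    ``kmer_emission[x, y]`` is the k-mer emission matrix.  Exponential cost;
    only usable for tiny state spaces and chain lengths.
    """
    card = len(pi0)
    m = len(obs_codes)
    total = 0.0
    for path in itertools.product(range(card), repeat=m):
        p = pi0[path[0]] * kmer_emission[path[0], obs_codes[0]]
        for i in range(1, m):
            p *= trans[path[i - 1], path[i]] * kmer_emission[path[i], obs_codes[i]]
        total += p
    return math.log(total) if total > 0 else float("-inf")


def unscaled_forward_log_likelihood(obs_codes, pi0, trans, kmer_emission) -> float:
    """Forward recursion without scaling (valid only while no underflow)."""
    alpha = pi0 * kmer_emission[:, obs_codes[0]]
    for y in obs_codes[1:]:
        alpha = (alpha @ trans) * kmer_emission[:, y]
    return math.log(alpha.sum())


def numeric_nb_error(mu1, s1, mu2, s2) -> float:
    """0.5 * integral of min of two Gaussian densities, by quadrature."""
    f = lambda t: min(stats.norm.pdf(t, mu1, s1), stats.norm.pdf(t, mu2, s2))
    lo = min(mu1 - 12 * s1, mu2 - 12 * s2)
    hi = max(mu1 + 12 * s1, mu2 + 12 * s2)
    val, _err = integrate.quad(f, lo, hi, limit=500)
    return 0.5 * val


def welch_by_hand(x, y):
    """Welch t statistic, degrees of freedom, two-sided p, 95% CI by formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
    se = math.sqrt(vx + vy)
    t = (x.mean() - y.mean()) / se
    df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
    p = 2 * stats.t.sf(abs(t), df)
    half = stats.t.ppf(0.975, df) * se
    diff = x.mean() - y.mean()
    return diff, diff - half, diff + half, p
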