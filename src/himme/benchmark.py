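"""Simulation benchmark: discriminant power of the scorer.

The study design: draw "true" sequences (substrings of the training
reference) and "random" sequences (i.i.d. bases, by default composition-
matched to the reference — the worst case for a transition-based method),
score both cohorts under models trained at several k-mer sizes, and quantify
how separable the two normalized-score distributions are:

* mean score difference per k (with a Welch two-sample t-test and 95% CI);
* the analytic naive-Bayes classification error after fitting a Gaussian to
  each cohort's scores (equal priors);
* a base-composition audit of reference, drawn, and random sequences.

Discriminant power is expected to grow with k: larger k-mers carry more
information, so the score distributions separate further and the
classification error falls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .emission import EmissionModel
from .exceptions import InsufficientDataError, ZeroVarianceError
from .forward import forward_batch
from .io import iter_sequences
from .simulate import sample_sequences_from_reference, simulate_random_sequences
from .state_space import ALPHABET, KmerStateSpace, encode_bases
from .transition import learn_transition_model


@dataclass(frozen=True)
class BenchmarkConfig:
    """Benchmark study conditions.

    ``pseudocount=None`` selects per-row unit pseudo-mass (``4**-k``), which
    keeps the total smoothing mass per transition row constant across k so
    that large-k models are not washed out by the smoothing prior at
    moderate training sizes.  ``composition=None`` matches the random
    generator to the measured composition of the training reference.
    """

    lengths: tuple[int, ...] = tuple(range(10, 101, 10))
    n_per_length: int = 1000
    k_values: tuple[int, ...] = (1, 3, 5)
    composition: tuple[float, float, float, float] | None = None
    seed: int = 0
    pseudocount: float | None = None
    counting: str = "sliding"

    def __post_init__(self) -> None:
        if self.n_per_length < 2:
            raise ValueError("n_per_length must be >= 2")
        if any(l < 1 for l in self.lengths):
            raise ValueError("lengths must be positive")
        if self.composition is not None:
            comp = np.asarray(self.composition, dtype=float)
            if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1) > 1e-9:
                raise ValueError("composition must be 4 non-negative values summing to 1")


class WelchResult(NamedTuple):
    difference: float
    ci_low: float
    ci_high: float
    pvalue: float


@dataclass
class BenchmarkResult:
    """Scores and derived statistics of one benchmark run."""

    config: BenchmarkConfig
    scores: dict  # (k, length) -> {"true": ndarray, "random": ndarray}
    mean_difference: dict  # k -> mean(true) - mean(random), pooled over lengths
    nb_error: dict  # k -> analytic Gaussian naive-Bayes error (fraction)
    t_test: dict  # k -> WelchResult
    composition: pd.DataFrame  # % per base: reference / drawn / random

    def pooled(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        true = np.concatenate([self.scores[(k, l)]["true"] for l in self.config.lengths])
        rand = np.concatenate([self.scores[(k, l)]["random"] for l in self.config.lengths])
        return true, rand

    def nb_error_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {f"{k}-mers": [100.0 * self.nb_error[k]] for k in self.config.k_values},
            index=["NB classifier error (%)"],
        )

    def t_test_table(self) -> pd.DataFrame:
        rows = []
        for k in self.config.k_values:
            t = self.t_test[k]
            rows.append(
                {
                    "k-mer size": k,
                    "difference in means": t.difference,
                    "CI95 low": t.ci_low,
                    "CI95 high": t.ci_high,
                    "p-value": t.pvalue,
                }
            )
        return pd.DataFrame(rows)

    def write_tables(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.composition.to_csv(out / "base_composition.tsv", sep="\t")
        self.nb_error_table().to_csv(out / "nb_error.tsv", sep="\t")
        self.t_test_table().to_csv(out / "t_test.tsv", sep="\t", index=False)
        rows = []
        for (k, length), sets in self.scores.items():
            for cohort, vals in sets.items():
                rows.append(
                    {
                        "k": k,
                        "length": length,
                        "cohort": cohort,
                        "mean_shat": vals.mean(),
                        "sd_shat": vals.std(ddof=1),
                        "n": vals.size,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "score_summary.tsv", sep="\t", index=False)

    def plot_score_densities(self, path, length: int | None = None) -> None:
        """Kernel-density plot of true vs random scores per k (optional)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        length = length or max(self.config.lengths)
        ks = self.config.k_values
        fig, axes = plt.subplots(1, len(ks), figsize=(4 * len(ks), 3), sharey=False)
        axes = np.atleast_1d(axes)
        for ax, k in zip(axes, ks):
            for cohort, color in (("true", "C0"), ("random", "C1")):
                vals = self.scores[(k, length)][cohort]
                grid = np.linspace(vals.min(), vals.max(), 200)
                ax.plot(grid, stats.gaussian_kde(vals)(grid), color=color, label=cohort)
            ax.set_title(f"k = {k}, length = {length} nt")
            ax.set_xlabel("normalized score")
            ax.legend()
        axes[0].set_ylabel("density")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def base_composition(sequences) -> np.ndarray:
    """Percentage of A, C, G, T among unambiguous bases of the input."""
    counts = np.zeros(4, dtype=np.int64)
    for seq in ([sequences] if isinstance(sequences, str) else sequences):
        arr = encode_bases(seq)
        counts += np.bincount(arr[arr >= 0], minlength=4)
    if counts.sum() == 0:
        raise ValueError("no unambiguous base in input")
    return 100.0 * counts / counts.sum()


def gaussian_nb_error(scores_true, scores_random) -> float:
    """Analytic naive-Bayes error of two fitted Gaussians with equal priors.

    A Gaussian is fitted to each score set (sample mean and sd); the Bayes
    error is ``0.5 * integral of min(f_true, f_random)``, evaluated exactly
    from the decision boundaries (roots of the log-density difference, a
    quadratic) and Gaussian tail masses.  Identical distributions give 0.5;
    the error is at most 0.5.
    """
    x = np.asarray(scores_true, dtype=float)
    y = np.asarray(scores_random, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("each score set needs at least 2 values")
    mu1, s1 = float(x.mean()), float(x.std(ddof=1))
    mu2, s2 = float(y.mean()), float(y.std(ddof=1))
    if s1 == 0.0 or s2 == 0.0:
        raise ZeroVarianceError("degenerate (zero-variance) score set")
    if mu1 == mu2 and s1 == s2:
        return 0.5
    # g(t) = log f1(t) - log f2(t) = a t^2 + b t + c
    a = 0.5 * (1.0 / s2**2 - 1.0 / s1**2)
    b = mu1 / s1**2 - mu2 / s2**2
    c = mu2**2 / (2 * s2**2) - mu1**2 / (2 * s1**2) + np.log(s2 / s1)
    if a == 0.0:
        roots = [] if b == 0.0 else [-c / b]
    else:
        disc = b * b - 4 * a * c
        roots = [] if disc < 0 else sorted(
            {(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)}
        )
    edges = [-np.inf] + list(roots) + [np.inf]
    err = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        if np.isinf(lo) and np.isinf(hi):
            mid = 0.5 * (mu1 + mu2)
        elif np.isinf(lo):
            mid = hi - 1.0
        elif np.isinf(hi):
            mid = lo + 1.0
        else:
            mid = 0.5 * (lo + hi)
        g_mid = a * mid * mid + b * mid + c
        # where f1 < f2, class 1 is misclassified; ties contribute to class 2's error
        if g_mid < 0:
            err += 0.5 * (stats.norm.cdf(hi, mu1, s1) - stats.norm.cdf(lo, mu1, s1))
        else:
            err += 0.5 * (stats.norm.cdf(hi, mu2, s2) - stats.norm.cdf(lo, mu2, s2))
    return float(err)


def welch_difference_test(scores_true, scores_random) -> WelchResult:
    """Welch two-sample t-test on mean(true) - mean(random), two-sided, 95% CI."""
    x = np.asarray(scores_true, dtype=float)
    y = np.asarray(scores_random, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("each score set needs at least 2 values")
    res = stats.ttest_ind(x, y, equal_var=False)
    ci = res.confidence_interval(0.95)
    return WelchResult(
        difference=float(x.mean() - y.mean()),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        pvalue=float(res.pvalue),
    )


def run_discrimination_benchmark(
    cfg: BenchmarkConfig, training, em: EmissionModel
) -> BenchmarkResult:
    """Run the full discrimination study; bit-for-bit reproducible from cfg.seed.

    One transition model is trained per k on the training reference.  For
    every length, one true cohort (reference substrings) and one random
    cohort (i.i.d., composition-matched unless overridden) are drawn once and
    scored at every k.  Per-k statistics pool the scores over all lengths.
    """
    records = list(iter_sequences(training))
    if not records:
        raise ValueError("empty training input")
    comp_ref = base_composition([seq for _i, seq in records])
    composition = (
        tuple(comp_ref / 100.0) if cfg.composition is None else tuple(cfg.composition)
    )

    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(2 * len(cfg.lengths))
    cohorts: dict[int, dict[str, list[str]]] = {}
    for i, length in enumerate(cfg.lengths):
        cohorts[length] = {
            "true": sample_sequences_from_reference(
                records, cfg.n_per_length, length, seed=np.random.default_rng(children[2 * i])
            ),
            "random": simulate_random_sequences(
                cfg.n_per_length,
                length,
                composition,
                seed=np.random.default_rng(children[2 * i + 1]),
            ),
        }

    scores: dict = {}
    mean_difference: dict = {}
    nb_error: dict = {}
    t_test: dict = {}
    for k in cfg.k_values:
        space = KmerStateSpace(k)
        pseudo = cfg.pseudocount if cfg.pseudocount is not None else 4.0 ** (-k)
        tm = learn_transition_model(records, space, pseudocount=pseudo, mode=cfg.counting)
        for length in cfg.lengths:
            m = length // k
            entry = {}
            for cohort in ("true", "random"):
                seqs = cohorts[length][cohort]
                codes = np.stack(
                    [
                        encode_bases(s[: m * k]).astype(np.int64).reshape(m, k) @ space.powers
                        for s in seqs
                    ]
                )
                entry[cohort] = forward_batch(codes, tm, em) / (k * m)
            scores[(k, length)] = entry
        true_all = np.concatenate([scores[(k, l)]["true"] for l in cfg.lengths])
        rand_all = np.concatenate([scores[(k, l)]["random"] for l in cfg.lengths])
        mean_difference[k] = float(true_all.mean() - rand_all.mean())
        nb_error[k] = gaussian_nb_error(true_all, rand_all)
        t_test[k] = welch_difference_test(true_all, rand_all)

    drawn = [s for length in cfg.lengths for s in cohorts[length]["true"]]
    random_seqs = [s for length in cfg.lengths for s in cohorts[length]["random"]]
    composition_table = pd.DataFrame(
        {
            "reference": comp_ref,
            "drawn": base_composition(drawn),
            "random": base_composition(random_seqs),
        },
        index=list(ALPHABET),
    )
    return BenchmarkResult(
        config=cfg,
        scores=scores,
        mean_difference=mean_difference,
        nb_error=nb_error,
        t_test=t_test,
        composition=composition_table,
    )
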