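"""Assembly-level summary: z-scores, logistic mapping, HiMMe coefficient.

Each contig's normalized score ``s_hat`` is standardized against a reference
distribution of normalized scores (mean ``mu``, standard deviation
``sigma``), mapped to the unit interval with the standard logistic function
``1 / (1 + exp(-z))``, and the assembly coefficient is

    HiMMe_coeff = m_h / s_h,

the mean over the sample standard deviation of the logistic-mapped scores.
The numerator rewards assemblies whose contigs score high against the
reference; the denominator rewards consistency (low spread).

The reference distribution can be loaded from a pre-computed score file or
simulated from a trained model: sequences are drawn from the hidden chain
with emission noise applied, scored, and their normalized scores summarized.
The default simulated benchmark is 30,000 sequences of 1,000 nt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .emission import EmissionModel
from .exceptions import (
    DegenerateBenchmarkError,
    InsufficientDataError,
    ZeroVarianceError,
)
from .forward import forward_batch
from .scoring import ContigScore
from .transition import TransitionModel

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ReferenceDistribution:
    """Mean/spread of a benchmark of normalized scores used for z-scoring."""

    mu: float
    sigma: float
    n: int
    source: str  # "file" or "simulated-from-model"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InsufficientDataError("reference distribution needs n >= 2 scores")
        if not self.sigma > 0:
            raise DegenerateBenchmarkError("reference distribution has zero spread")


@dataclass(frozen=True)
class AssemblySummary:
    """The assembly-level report fields.

    ``himme_coeff`` is ``None`` only when constructed with
    ``summarize_assembly(..., strict=False)`` on a zero-variance assembly.
    """

    k: int
    n_contigs: int
    n_scored: int
    median_length: float
    length_variance: float
    mean_score: float
    score_variance: float
    score_ci95: tuple[float, float]
    mean_corrected: float
    corrected_variance: float
    corrected_ci95: tuple[float, float]
    himme_coeff: float | None


def build_reference_distribution(
    scores=None,
    *,
    model: TransitionModel | None = None,
    emission: EmissionModel | None = None,
    n: int = 30_000,
    length: int = 1_000,
    seed: int = 0,
) -> ReferenceDistribution:
    """Reference distribution from a score set or simulated from a model.

    Pass ``scores`` (array-like of normalized scores) for file mode, or a
    trained ``model`` plus ``emission`` for simulated mode, in which case
    ``n`` sequences of ``length`` nt are drawn from the model, scored, and
    summarized; the run is fully determined by ``seed``.
    """
    if scores is not None:
        vals = np.asarray(scores, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            raise InsufficientDataError("need at least 2 finite scores for a reference")
        return ReferenceDistribution(
            mu=float(vals.mean()),
            sigma=float(vals.std(ddof=1)),
            n=int(vals.size),
            source="file",
        )
    if model is None or emission is None:
        raise ValueError("provide either scores or (model, emission)")
    from .simulate import sample_from_model

    codes = sample_from_model(model, emission, n=n, length=length, seed=seed, return_codes=True)
    loglik = forward_batch(codes, model, emission)
    k = model.space.k
    shat = loglik / (k * codes.shape[1])
    shat = shat[np.isfinite(shat)]
    if shat.size < 2:
        raise InsufficientDataError("fewer than 2 finite simulated scores")
    return ReferenceDistribution(
        mu=float(shat.mean()),
        sigma=float(shat.std(ddof=1)),
        n=int(shat.size),
        source="simulated-from-model",
        seed=seed,
    )


def logistic_transform(s_hat, ref: ReferenceDistribution):
    """Map ``s_hat`` to (0, 1) via the standard logistic of its z-score."""
    from scipy.special import expit

    z = (np.asarray(s_hat, dtype=float) - ref.mu) / ref.sigma
    out = expit(z)
    return float(out) if out.ndim == 0 else out


def himme_coefficient(corrected) -> float:
    """``m_h / s_h``: mean over sample standard deviation of corrected scores."""
    vals = np.asarray(corrected, dtype=float)
    if vals.size < 2:
        raise InsufficientDataError("coefficient needs at least 2 corrected scores")
    s_h = float(vals.std(ddof=1))
    if s_h == 0.0:
        raise ZeroVarianceError("all corrected scores identical; coefficient undefined")
    return float(vals.mean()) / s_h


def summarize_assembly(
    scores: list[ContigScore],
    ref: ReferenceDistribution,
    k: int,
    strict: bool = True,
) -> AssemblySummary:
    """Assembly-level summary of a list of per-contig scores.

    Contigs flagged ``too_short`` (no scoreable k-mer) are excluded from all
    score statistics but still counted in ``n_contigs``; contigs with
    ``-inf`` scores are likewise excluded from the score statistics.  With
    ``strict=True`` a zero-variance corrected-score set raises
    :class:`ZeroVarianceError`; with ``strict=False`` the summary is returned
    with ``himme_coeff=None``.
    """
    n_contigs = len(scores)
    lengths = np.array([s.length_nt for s in scores], dtype=float)
    shat = np.array(
        [s.normalized_score for s in scores if s.normalized_score is not None], dtype=float
    )
    shat = shat[np.isfinite(shat)]
    if shat.size < 2:
        raise InsufficientDataError("need at least 2 scored contigs to summarize")
    corrected = logistic_transform(shat, ref)
    try:
        coeff = himme_coefficient(corrected)
    except ZeroVarianceError:
        if strict:
            raise
        coeff = None

    def _ci(vals: np.ndarray) -> tuple[float, float]:
        half = _Z95 * vals.std(ddof=1) / math.sqrt(vals.size)
        return (float(vals.mean() - half), float(vals.mean() + half))

    return AssemblySummary(
        k=k,
        n_contigs=n_contigs,
        n_scored=int(shat.size),
        median_length=float(np.median(lengths)),
        length_variance=float(lengths.var(ddof=1)) if n_contigs > 1 else 0.0,
        mean_score=float(shat.mean()),
        score_variance=float(shat.var(ddof=1)),
        score_ci95=_ci(shat),
        mean_corrected=float(corrected.mean()),
        corrected_variance=float(corrected.var(ddof=1)),
        corrected_ci95=_ci(corrected),
        himme_coeff=coeff,
    )
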