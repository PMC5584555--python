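"""Emission probabilities: per-base substitution matrices and k-mer emissions.

The observed contig is a noisy read-out of the hidden k-mer chain.  Under the
conditional-independence assumption, the probability of observing k-mer ``y``
given hidden k-mer ``x`` factorizes over positions,
``e(y|x) = prod_j e(y_j | x_j)``, so the whole emission model is a single
4x4 row-stochastic matrix of per-nucleotide substitution probabilities.

Two constructions are provided: a manual one (diagonal ``p_match``, the
remaining mass spread over the alternatives) and one estimated from a SNP
database in VCF format, where the off-diagonal mass is split proportionally
to observed REF->ALT substitution counts.  ``p_match = 1`` gives the identity
matrix and the model degenerates to a plain Markov chain; an all-0.25 matrix
imposes maximum uncertainty on the emissions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import InvalidDistributionError, InvalidProbabilityError
from .state_space import ALPHABET

_ROW_SUM_TOL = 1e-12


@dataclass
class EmissionModel:
    """4x4 per-base substitution matrix ``base_emission[x, y] = e(y|x)``."""

    base_emission: np.ndarray
    source: str = "manual"
    params: dict = field(default_factory=dict)
    _kmer_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.base_emission = np.asarray(self.base_emission, dtype=float)
        if self.base_emission.shape != (4, 4):
            raise ValueError("base_emission must be a 4x4 matrix")

    def validate(self) -> None:
        if (self.base_emission < 0).any():
            raise ValueError("negative emission probabilities")
        dev = np.abs(self.base_emission.sum(axis=1) - 1.0).max()
        if dev > 4 * _ROW_SUM_TOL:
            raise ValueError(f"emission rows deviate from stochasticity by {dev:g}")

    @property
    def is_identity(self) -> bool:
        return bool((self.base_emission == np.eye(4)).all())

    def kmer_matrix(self, k: int) -> np.ndarray:
        """(4**k, 4**k) matrix of k-mer emissions ``E_k[x, y] = prod e(y_j|x_j)``.

        Built as the k-fold Kronecker power of the base matrix (first k-mer
        character most significant, matching the state encoding); cached per k.
        """
        if k not in self._kmer_cache:
            mat = self.base_emission
            for _ in range(k - 1):
                mat = np.kron(mat, self.base_emission)
            self._kmer_cache[k] = mat
        return self._kmer_cache[k]


def build_emission_manual(p_match: float, bias: np.ndarray | None = None) -> EmissionModel:
    """Emission matrix with diagonal ``p_match`` and off-diagonal mass ``1 - p_match``.

    Without ``bias`` the off-diagonal mass is split evenly (the "no bias"
    setting, e.g. 0.85 on the diagonal and 0.05 elsewhere).  ``bias`` is a
    4x3 matrix of per-row weights over the three alternative bases, in
    alphabet order with the reference base removed; each row is normalized.
    """
    if not 0 < p_match <= 1:
        raise InvalidProbabilityError(f"p_match must be in (0, 1], got {p_match}")
    mat = np.zeros((4, 4))
    np.fill_diagonal(mat, p_match)
    off_mass = 1.0 - p_match
    if off_mass > 0:
        if bias is None:
            weights = np.full((4, 3), 1.0 / 3.0)
        else:
            weights = np.asarray(bias, dtype=float)
            if weights.shape != (4, 3) or (weights < 0).any():
                raise InvalidProbabilityError("bias must be a non-negative 4x3 matrix")
            sums = weights.sum(axis=1, keepdims=True)
            if (sums == 0).any():
                raise InvalidProbabilityError("bias rows must not be all zero")
            weights = weights / sums
        for x in range(4):
            others = [y for y in range(4) if y != x]
            mat[x, others] = off_mass * weights[x]
    em = EmissionModel(mat, source="manual", params={"p_match": p_match})
    em.validate()
    return em


def _iter_snp_pairs(vcf):
    """Yield (ref_code, alt_code) for biallelic-expanded SNP records.

    ``vcf`` is a VCF path (plain or bgzipped) or an iterable of
    ``(ref, alt)`` string pairs.  Indels, MNPs and records with ambiguous
    alleles are skipped.
    """
    if isinstance(vcf, (str, Path)):
        import pysam

        with pysam.VariantFile(str(vcf)) as vf:
            for rec in vf:
                ref = rec.ref
                for alt in rec.alts or ():
                    yield ref, alt
    else:
        yield from vcf


def build_emission_from_vcf(vcf, p_var: float = 0.15) -> EmissionModel:
    """Emission matrix whose off-diagonal mass follows SNP substitution counts.

    For each reference base ``x`` the diagonal entry is ``1 - p_var`` and the
    row mass ``p_var`` is distributed over the alternative bases ``y``
    proportionally to the number of REF=x -> ALT=y SNP records (evenly when a
    row has no counts).  Only single-nucleotide ACGT->ACGT substitutions are
    used.  Emits a warning (not an error) when no usable SNP record exists.
    """
    if not 0 <= p_var < 1:
        raise InvalidProbabilityError(f"p_var must be in [0, 1), got {p_var}")
    counts = np.zeros((4, 4))
    usable = 0
    for ref, alt in _iter_snp_pairs(vcf):
        if ref is None or alt is None or len(ref) != 1 or len(alt) != 1:
            continue
        ref, alt = ref.upper(), alt.upper()
        if ref not in ALPHABET or alt not in ALPHABET or ref == alt:
            continue
        counts[ALPHABET.index(ref), ALPHABET.index(alt)] += 1
        usable += 1
    if usable == 0:
        warnings.warn("no usable SNP record; off-diagonal mass split evenly", stacklevel=2)
    mat = np.zeros((4, 4))
    np.fill_diagonal(mat, 1.0 - p_var)
    if p_var > 0:
        for x in range(4):
            others = [y for y in range(4) if y != x]
            row = counts[x, others]
            weights = row / row.sum() if row.sum() > 0 else np.full(3, 1.0 / 3.0)
            mat[x, others] = p_var * weights
    em = EmissionModel(
        mat, source="vcf", params={"p_var": p_var, "n_snp_records": usable}
    )
    em.validate()
    return em


def kmer_emission_probability(y: str, x: str, em: EmissionModel) -> float:
    """Probability of observing k-mer ``y`` given hidden k-mer ``x``."""
    if len(y) != len(x):
        raise ValueError(f"symbol/state length mismatch: {len(y)} vs {len(x)}")
    from .state_space import encode_bases

    yc = encode_bases(y)
    xc = encode_bases(x)
    if (yc < 0).any() or (xc < 0).any():
        from .exceptions import AmbiguousBaseError

        raise AmbiguousBaseError(f"ambiguous base in {y!r} or {x!r}")
    return float(np.prod(em.base_emission[xc, yc]))


def state_entropy(p, log_base: float | None = None) -> float:
    """Shannon entropy ``-sum p_A log p_A`` of a state distribution.

    Natural log by default (nats); pass ``log_base`` for other units.  The
    convention ``0 * log 0 = 0`` applies.  Uniform over ``4**k`` states gives
    ``k * log 4``, the information capacity of a k-mer.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-6:
        raise InvalidDistributionError("p must be a probability vector summing to 1")
    nz = p[p > 0]
    s = float(-(nz * np.log(nz)).sum())
    if log_base is not None:
        s /= float(np.log(log_base))
    return s
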