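"""Reference distribution, logistic correction, and the assembly coefficient."""

import math

import numpy as np
import pytest

from himme import (
    build_emission_manual,
    build_reference_distribution,
    himme_coefficient,
    logistic_transform,
    score_contigs,
    summarize_assembly,
)
from himme.exceptions import (
    DegenerateBenchmarkError,
    InsufficientDataError,
    ZeroVarianceError,
)
from himme.scoring import ContigScore
from himme.summary import ReferenceDistribution


def _score(cid, shat, length=300, m=100):
    return ContigScore(cid, length, shat * 3 * m, shat, m)


class TestReferenceDistribution:
    def test_from_scores_hand_arithmetic(self):
        ref = build_reference_distribution([-1.0, -1.2, -1.4])
        assert ref.mu == pytest.approx(-1.2)
        assert ref.sigma == pytest.approx(0.2)
        assert ref.n == 3 and ref.source == "file"

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateBenchmarkError):
            build_reference_distribution([-1.0, -1.0, -1.0])
        with pytest.raises(InsufficientDataError):
            build_reference_distribution([-1.0])

    def test_simulated_mode_deterministic(self, model_k3, emission_085):
        a = build_reference_distribution(
            model=model_k3, emission=emission_085, n=200, length=300, seed=9
        )
        b = build_reference_distribution(
            model=model_k3, emission=emission_085, n=200, length=300, seed=9
        )
        assert (a.mu, a.sigma) == (b.mu, b.sigma)
        assert a.source == "simulated-from-model" and a.seed == 9

    def test_simulated_identity_emission_matches_mc_scores(self, model_k3):
        """With identity emission, simulated benchmark scores are MC path
        log-probabilities per modeled nucleotide."""
        from himme import mc_sequence_log_probability, tokenize_sequence
        from himme.simulate import sample_from_model

        identity = build_emission_manual(1.0)
        seqs = sample_from_model(model_k3, identity, n=30, length=120, seed=4)
        shat = [
            mc_sequence_log_probability(tokenize_sequence(s, model_k3.space), model_k3) / 120
            for s in seqs
        ]
        ref = build_reference_distribution(
            model=model_k3, emission=identity, n=30, length=120, seed=4
        )
        assert ref.mu == pytest.approx(np.mean(shat), rel=1e-12)


class TestLogistic:
    def test_center_and_one_sigma(self):
        ref = ReferenceDistribution(mu=-1.2, sigma=0.2, n=100, source="file")
        assert logistic_transform(-1.2, ref) == 0.5
        assert logistic_transform(-1.0, ref) == pytest.approx(1 / (1 + math.exp(-1)))

    def test_monotone_and_bounded(self):
        ref = ReferenceDistribution(mu=0.0, sigma=1.0, n=100, source="file")
        vals = logistic_transform(np.linspace(-10, 10, 101), ref)
        assert (np.diff(vals) > 0).all()
        assert vals[0] >= 0 and vals[-1] <= 1
        assert logistic_transform(-1e6, ref) == pytest.approx(0.0)
        assert logistic_transform(1e6, ref) == pytest.approx(1.0)

    def test_scale_contraction_toward_half(self):
        """Doubling sigma contracts all z toward 0, pulling scores toward 0.5."""
        narrow = ReferenceDistribution(mu=-1.0, sigma=0.1, n=50, source="file")
        wide = ReferenceDistribution(mu=-1.0, sigma=0.2, n=50, source="file")
        for s in (-1.5, -1.1, -0.9, -0.2):
            assert abs(logistic_transform(s, wide) - 0.5) < abs(
                logistic_transform(s, narrow) - 0.5
            )


class TestCoefficient:
    def test_hand_arithmetic(self):
        assert himme_coefficient([0.4, 0.5, 0.6]) == pytest.approx(5.0)
        assert himme_coefficient([0.4, 0.6]) == pytest.approx(0.5 / math.sqrt(0.02))

    def test_zero_variance(self):
        with pytest.raises(ZeroVarianceError):
            himme_coefficient([0.3, 0.3, 0.3])

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            himme_coefficient([0.5])


class TestSummarize:
    REF = ReferenceDistribution(mu=-1.2, sigma=0.1, n=1000, source="file")

    def test_field_values(self):
        scores = [_score("a", -1.1, 300), _score("b", -1.3, 500)]
        s = summarize_assembly(scores, self.REF, k=3)
        assert s.n_contigs == 2 and s.n_scored == 2
        assert s.median_length == 400
        assert s.mean_score == pytest.approx(-1.2)
        corrected = [1 / (1 + math.exp(-1)), 1 / (1 + math.exp(1))]
        assert s.mean_corrected == pytest.approx(np.mean(corrected))
        assert s.himme_coeff == pytest.approx(np.mean(corrected) / np.std(corrected, ddof=1))
        assert 0 < s.mean_corrected < 1
        lo, hi = s.score_ci95
        assert lo < s.mean_score < hi

    def test_zero_variance_paths(self):
        scores = [_score("a", -1.0), _score("b", -1.0)]
        with pytest.raises(ZeroVarianceError):
            summarize_assembly(scores, self.REF, k=3)
        s = summarize_assembly(scores, self.REF, k=3, strict=False)
        assert s.himme_coeff is None and s.mean_score == -1.0 and s.score_variance == 0.0

    def test_permutation_invariance(self):
        scores = [_score(f"c{i}", -1.0 - 0.05 * i, 100 + 40 * i) for i in range(6)]
        a = summarize_assembly(scores, self.REF, k=3)
        b = summarize_assembly(scores[::-1], self.REF, k=3)
        assert a.n_contigs == b.n_contigs and a.median_length == b.median_length
        for field in ("length_variance", "mean_score", "score_variance",
                      "mean_corrected", "corrected_variance", "himme_coeff"):
            assert getattr(a, field) == pytest.approx(getattr(b, field), rel=1e-12)

    def test_too_short_excluded_but_counted(self):
        scores = [
            _score("a", -1.1),
            _score("b", -1.3),
            ContigScore("tiny", 2, None, None, 0, frozenset({"too_short"})),
        ]
        s = summarize_assembly(scores, self.REF, k=3)
        assert s.n_contigs == 3 and s.n_scored == 2
        assert s.mean_score == pytest.approx(-1.2)

    def test_insufficient_scored_contigs(self):
        with pytest.raises(InsufficientDataError):
            summarize_assembly([_score("a", -1.0)], self.REF, k=3)

    def test_uniform_shift_raises_mean_and_coefficient(self):
        base = [-1.3, -1.25, -1.2, -1.15]
        lifted = [s + 0.05 for s in base]
        a = summarize_assembly([_score(f"a{i}", s) for i, s in enumerate(base)], self.REF, 3)
        b = summarize_assembly([_score(f"b{i}", s) for i, s in enumerate(lifted)], self.REF, 3)
        assert b.mean_corrected > a.mean_corrected


def test_model_assembly_beats_random_assembly(model_k3, emission_085, reference_100kb):
    """Assemblies made of reference material get a larger coefficient than
    composition-free random assemblies, against the same reference
    distribution (seeded trials)."""
    from himme.simulate import sample_sequences_from_reference, simulate_random_sequences

    ref_dist = build_reference_distribution(
        model=model_k3, emission=emission_085, n=400, length=500, seed=1
    )
    wins = 0
    n_trials = 8
    for t in range(n_trials):
        true_assembly = [
            (f"t{i}", s)
            for i, s in enumerate(
                sample_sequences_from_reference(reference_100kb, 40, 800, seed=t)
            )
        ]
        rand_assembly = [
            (f"r{i}", s)
            for i, s in enumerate(simulate_random_sequences(40, 800, seed=300 + t))
        ]
        coeff_true = summarize_assembly(
            score_contigs(true_assembly, model_k3, emission_085), ref_dist, 3
        ).himme_coeff
        coeff_rand = summarize_assembly(
            score_contigs(rand_assembly, model_k3, emission_085), ref_dist, 3
        ).himme_coeff
        wins += coeff_true > coeff_rand
    assert wins >= n_trials - 1
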