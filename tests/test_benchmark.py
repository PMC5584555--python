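"""Simulators and the discrimination benchmark statistics."""

import numpy as np
import pytest
from scipy import stats

from himme import build_emission_manual
from himme.benchmark import (
    BenchmarkConfig,
    base_composition,
    gaussian_nb_error,
    run_discrimination_benchmark,
    welch_difference_test,
)
from himme.exceptions import InsufficientDataError, ZeroVarianceError
from himme.simulate import (
    sample_from_model,
    sample_sequences_from_reference,
    simulate_random_sequences,
    synthetic_reference,
)

from helpers import numeric_nb_error, welch_by_hand


class TestSimulators:
    def test_random_sequences_seeded_and_shaped(self):
        a = simulate_random_sequences(5, 40, seed=3)
        b = simulate_random_sequences(5, 40, seed=3)
        assert a == b
        assert all(len(s) == 40 for s in a)

    def test_random_composition_extremes(self):
        (seq,) = simulate_random_sequences(1, 30, composition=(1, 0, 0, 0), seed=0)
        assert seq == "A" * 30

    def test_random_composition_converges(self):
        seqs = simulate_random_sequences(200, 500, seed=1)
        comp = base_composition(seqs)
        assert np.abs(comp - 25.0).max() < 1.0  # within 1% of 25%

    def test_substrings_are_contained(self, reference_20kb):
        seqs = sample_sequences_from_reference(reference_20kb, 20, 50, seed=2)
        assert all(len(s) == 50 and s in reference_20kb for s in seqs)

    def test_full_length_sample_is_the_reference(self):
        ref = "ACGTACGTAA"
        assert sample_sequences_from_reference(ref, 3, 10, seed=0) == [ref] * 3

    def test_sampling_skips_ambiguous_windows(self):
        ref = "ACGT" * 5 + "NNNN" + "TGCA" * 5
        seqs = sample_sequences_from_reference(ref, 50, 8, seed=1)
        assert all("N" not in s for s in seqs)
        with pytest.raises(ValueError):
            sample_sequences_from_reference("ACGNT", 1, 5, seed=0)

    def test_drawn_composition_tracks_reference(self, reference_100kb):
        drawn = sample_sequences_from_reference(reference_100kb, 400, 200, seed=5)
        ref_comp = base_composition(reference_100kb)
        drawn_comp = base_composition(drawn)
        assert np.abs(ref_comp - drawn_comp).max() < 1.5

    def test_synthetic_reference_seeded(self):
        assert synthetic_reference(500, seed=4) == synthetic_reference(500, seed=4)
        assert synthetic_reference(500, seed=4) != synthetic_reference(500, seed=5)

    def test_model_draws_match_chain_statistics(self, model_k3):
        """With identity emission, drawn k-mer bigrams follow the transition
        matrix: frequent transitions appear more often than rare ones."""
        codes = sample_from_model(
            model_k3, build_emission_manual(1.0), n=400, length=60, seed=8, return_codes=True
        )
        first = codes[:, 0]
        # initial states follow pi0: compare observed vs expected top-decile mass
        top = np.argsort(model_k3.pi0)[-6:]
        obs_mass = np.isin(first, top).mean()
        exp_mass = model_k3.pi0[top].sum()
        assert obs_mass == pytest.approx(exp_mass, abs=0.1)


class TestComposition:
    def test_hand_example(self):
        comp = base_composition("AACG")
        assert np.allclose(comp, [50, 25, 25, 0])

    def test_percentages_sum_to_100(self):
        comp = base_composition(["ACGTN", "GGTT"])
        assert comp.sum() == pytest.approx(100.0)

    def test_concatenation_is_length_weighted_mean(self):
        a, b = "AAAAC", "GGT"
        combined = base_composition([a, b])
        weighted = (len(a) * base_composition(a) + len(b) * base_composition(b)) / (
            len(a) + len(b)
        )
        assert np.allclose(combined, weighted)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            base_composition("NNN")


class TestNaiveBayesError:
    def test_identical_samples_give_half(self):
        x = np.array([0.1, 0.5, 0.9, 1.3, 2.0])
        assert gaussian_nb_error(x, x) == 0.5

    def test_equal_variance_closed_form(self):
        """N(0,1) vs N(2,1): boundary at 1, error = Phi(-1)."""
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 40_000)
        y = rng.normal(2, 1, 40_000)
        err = gaussian_nb_error(x, y)
        assert err == pytest.approx(stats.norm.cdf(-1), abs=0.01)

    def test_wide_separation_drives_error_to_zero(self):
        rng = np.random.default_rng(1)
        err = gaussian_nb_error(rng.normal(0, 1, 200), rng.normal(50, 1, 200))
        assert err < 1e-6

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_numeric_integration(self, seed):
        """Analytic boundary evaluation equals quadrature of 0.5*min(f1,f2),
        including unequal-variance (two-root) geometries."""
        rng = np.random.default_rng(seed)
        mu1, mu2 = rng.normal(0, 2, 2)
        s1, s2 = rng.uniform(0.3, 3, 2)
        x = rng.normal(mu1, s1, 5000)
        y = rng.normal(mu2, s2, 5000)
        got = gaussian_nb_error(x, y)
        want = numeric_nb_error(x.mean(), x.std(ddof=1), y.mean(), y.std(ddof=1))
        assert got == pytest.approx(want, abs=1e-8)
        assert 0 <= got <= 0.5 + 1e-12

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            gaussian_nb_error([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


class TestWelch:
    def test_identical_samples(self):
        res = welch_difference_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.difference == 0.0
        assert res.ci_low < 0 < res.ci_high
        assert res.pvalue == pytest.approx(1.0)

    def test_separated_samples(self):
        res = welch_difference_test([2.1, 1.9, 2.0], [1.0, 0.9, 1.1])
        assert res.difference == pytest.approx(1.0)
        assert res.pvalue < 0.01

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_hand_formulas(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 2, 50)
        res = welch_difference_test(x, y)
        diff, lo, hi, p = welch_by_hand(x, y)
        assert res.difference == pytest.approx(diff)
        assert res.ci_low == pytest.approx(lo, rel=1e-9)
        assert res.ci_high == pytest.approx(hi, rel=1e-9)
        assert res.pvalue == pytest.approx(p, rel=1e-9)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            welch_difference_test([1.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def small_result(reference_20kb):
    cfg = BenchmarkConfig(lengths=(20, 40), n_per_length=60, k_values=(1, 2), seed=3)
    return cfg, run_discrimination_benchmark(cfg, reference_20kb, build_emission_manual(0.85))


class TestBenchmarkRun:
    def test_bit_for_bit_reproducible(self, small_result, reference_20kb):
        cfg, first = small_result
        second = run_discrimination_benchmark(cfg, reference_20kb, build_emission_manual(0.85))
        for key in first.scores:
            for cohort in ("true", "random"):
                assert (first.scores[key][cohort] == second.scores[key][cohort]).all()
        assert first.nb_error == second.nb_error

    def test_true_scores_exceed_random(self, small_result):
        _cfg, res = small_result
        for k in (1, 2):
            assert res.mean_difference[k] > 0
            assert res.t_test[k].pvalue < 0.01

    def test_composition_matched_random_cohort(self, small_result):
        """Default random cohort matches the reference composition (the
        worst case: discrimination must come from transitions, not
        proportions) yet the true cohort still scores higher."""
        _cfg, res = small_result
        comp = res.composition
        assert np.abs(comp["reference"] - comp["random"]).max() < 2.0
        assert res.mean_difference[2] > 0

    def test_tables_and_output(self, small_result, tmp_path):
        _cfg, res = small_result
        assert res.nb_error_table().shape == (1, 2)
        assert list(res.t_test_table()["k-mer size"]) == [1, 2]
        res.write_tables(tmp_path)
        assert (tmp_path / "nb_error.tsv").exists()
        assert (tmp_path / "score_summary.tsv").exists()

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            BenchmarkConfig(n_per_length=1)
        with pytest.raises(ValueError):
            BenchmarkConfig(composition=(0.5, 0.5, 0.5, 0.5))
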