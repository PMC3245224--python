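"""Mutual-information estimation and offset-maximised episode similarity."""

import numpy as np
import pytest
import scipy.stats

from episodenet.exceptions import DegenerateInputError
from episodenet.segmentation import build_episodes, detect_cycles
from episodenet.similarity import (MiConfig, aligned_similarity,
                                   mutual_information, similarity_matrix)


def empirical_entropy_bits(x, n_bins):
    """Entropy of the equal-width bin distribution of x (oracle)."""
    counts, _ = np.histogram(x, bins=n_bins)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log2(p)))


class TestMutualInformation:
    def test_self_mi_equals_bin_entropy(self, rng):
        x = rng.random(1000)
        mi = mutual_information(x, x, MiConfig(n_bins=10))
        assert mi == pytest.approx(empirical_entropy_bits(x, 10), abs=1e-12)
        assert mi == pytest.approx(np.log2(10), abs=0.05)

    def test_independent_uniforms_near_zero(self, rng):
        x, y = rng.random(10_000), rng.random(10_000)
        mi = mutual_information(x, y, MiConfig(n_bins=10))
        # plug-in bias bound (B-1)^2 / (2 n ln 2) ~ 0.006 bits
        assert 0 <= mi < 0.02

    def test_gaussian_matches_closed_form(self, rng):
        r = 0.9
        xy = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=10_000)
        mi = mutual_information(xy[:, 0], xy[:, 1], MiConfig(n_bins=16))
        assert mi == pytest.approx(-0.5 * np.log2(1 - r ** 2), abs=0.15)

    def test_affine_invariance_exact(self, rng):
        x, y = rng.random(500), rng.random(500)
        cfg = MiConfig(n_bins=8)
        base = mutual_information(x, y, cfg)
        assert mutual_information(3.7 * x - 11.0, y, cfg) == pytest.approx(base, abs=1e-12)
        assert mutual_information(x, -2.0 * y + 5.0, cfg) == pytest.approx(base, abs=1e-12)

    def test_log_base_only_rescales(self, rng):
        x, y = rng.random(500), rng.random(500)
        bits = mutual_information(x, y, MiConfig(n_bins=8, log_base=2))
        nats = mutual_information(x, y, MiConfig(n_bins=8, log_base=np.e))
        assert nats == pytest.approx(bits * np.log(2), rel=1e-12)

    def test_errors(self, rng):
        cfg = MiConfig(n_bins=4)
        with pytest.raises(ValueError):
            mutual_information(rng.random(10), rng.random(11), cfg)
        with pytest.raises(DegenerateInputError):
            mutual_information(np.ones(50), rng.random(50), cfg)
        with pytest.raises(ValueError):  # n < 2 * n_bins
            mutual_information(rng.random(7), rng.random(7), cfg)


class TestPearsonMetric:
    def test_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        got = aligned_similarity(x, y, MiConfig(metric="pearson"))
        assert got == pytest.approx(scipy.stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_antisymmetric_under_negation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        cfg = MiConfig(metric="pearson")
        assert aligned_similarity(x, y, cfg) == pytest.approx(
            -aligned_similarity(x, -y, cfg))


class TestAlignedSimilarity:
    def test_equal_lengths_single_offset(self, rng):
        x, y = rng.random(200), rng.random(200)
        cfg = MiConfig(n_bins=10)
        # equal up to float summation order (the joint histogram is transposed)
        assert aligned_similarity(x, y, cfg) == pytest.approx(
            mutual_information(x, y, cfg), abs=1e-12)

    def test_embedded_subsequence_found_at_true_offset(self, rng):
        long_ = rng.random(300)
        short = long_[50:250]
        cfg = MiConfig(n_bins=12)
        got = aligned_similarity(long_, short, cfg)
        # brute force over all offsets (oracle)
        per_offset = [mutual_information(long_[o:o + 200], short, cfg)
                      for o in range(101)]
        assert int(np.argmax(per_offset)) == 50
        assert got == pytest.approx(per_offset[50], abs=1e-12)
        # at the matching offset MI equals the subsequence's bin entropy
        counts, _ = np.histogram(short, bins=12)
        p = counts[counts > 0] / counts.sum()
        assert got == pytest.approx(float(-np.sum(p * np.log2(p))), abs=1e-12)

    def test_aligned_value_dominates_offset_zero(self, rng):
        a, b = rng.random(250), rng.random(220)
        cfg = MiConfig(n_bins=10)
        assert aligned_similarity(a, b, cfg) >= mutual_information(a[:220], b, cfg) - 1e-12

    def test_order_invariance(self, rng):
        a, b = rng.random(250), rng.random(220)
        cfg = MiConfig(n_bins=10)
        assert aligned_similarity(a, b, cfg) == aligned_similarity(b, a, cfg)


class TestSimilarityMatrix:
    def test_two_episodes(self, rng):
        eps = [rng.random(100), rng.random(90)]
        cfg = MiConfig(n_bins=8)
        S = similarity_matrix(eps, cfg)
        assert S.size == 2
        assert S[0, 1] == aligned_similarity(eps[0], eps[1], cfg)
        assert S[0, 0] == S[1, 1] == 0.0

    def test_symmetric_zero_diagonal_nonnegative(self, rng):
        eps = [rng.random(rng.integers(80, 120)) for _ in range(6)]
        S = similarity_matrix(eps, MiConfig(n_bins=8))
        assert np.array_equal(S.values, S.values.T)
        assert np.all(np.diag(S.values) == 0)
        assert np.all(S.values >= 0)

    def test_entries_match_per_pair_oracle(self, rng):
        eps = [rng.random(rng.integers(60, 90)) for _ in range(5)]
        cfg = MiConfig(n_bins=8)
        S = similarity_matrix(eps, cfg)
        for i in range(5):
            for j in range(i + 1, 5):
                assert S[i, j] == pytest.approx(
                    aligned_similarity(eps[i], eps[j], cfg), abs=1e-12)

    def test_needs_two_episodes(self, rng):
        with pytest.raises(ValueError):
            similarity_matrix([rng.random(50)])


class TestDistributionShape:
    def test_mi_right_tailed_pearson_left_tailed(self, rossler_series):
        """On chaotic episodes, MI values skew right while correlations pile
        near their upper end (left skew) — mirrored distribution shapes."""
        cycles = detect_cycles(rossler_series)[:80]
        episodes = build_episodes(cycles, 2)
        mi_vals = similarity_matrix(episodes, MiConfig()).offdiagonal()
        r_vals = similarity_matrix(episodes, MiConfig(metric="pearson")).offdiagonal()
        assert scipy.stats.skew(mi_vals) > 0
        assert scipy.stats.skew(r_vals) < 0
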