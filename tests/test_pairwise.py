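import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lagnet.pairwise import (
    all_pair_stats,
    associativity_measure,
    centroids,
    default_bins,
    mutual_information,
    pearson_with_pvalue,
    stats_to_frame,
)

from conftest import make_profile, random_pair_stats


def brute_force_pearson(x, y):
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / math.sqrt(np.sum(xm**2) * np.sum(ym**2)))


def brute_force_mi(x, y, bins, base=2.0):
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    n = joint.sum()
    mi = 0.0
    for i in range(bins):
        for j in range(bins):
            pxy = joint[i, j] / n
            if pxy == 0:
                continue
            px = joint[i, :].sum() / n
            py = joint[:, j].sum() / n
            mi += pxy * math.log(pxy / (px * py), base)
    return mi


class TestPearson:
    def test_exact_linear(self):
        r, p = pearson_with_pvalue([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_exact_antilinear(self):
        r, _ = pearson_with_pvalue([1, 2, 3, 4], [4, 3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x, y = rng.normal(size=(2, 14))
            r, p = pearson_with_pvalue(x, y)
            assert r == pytest.approx(brute_force_pearson(x, y), abs=1e-12)
            assert 0.0 <= p <= 1.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 14))
        r0, p0 = pearson_with_pvalue(x, y)
        r1, p1 = pearson_with_pvalue(3.5 * x + 7.0, y)
        assert r1 == pytest.approx(r0, abs=1e-12)
        assert p1 == pytest.approx(p0, rel=1e-9)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_pvalue([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_pvalue([1, 2], [3, 4])


class TestMutualInformation:
    def test_identical_two_level_signal_is_one_bit(self):
        x = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        assert mutual_information(x, x, bins=2) == pytest.approx(1.0)

    def test_product_form_histogram_is_zero(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        assert mutual_information(x, y, bins=2) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("bins", [2, 3, 4])
    def test_matches_cell_sum_oracle(self, bins):
        rng = np.random.default_rng(3)
        for _ in range(30):
            x, y = rng.normal(size=(2, 14))
            assert mutual_information(x, y, bins) == pytest.approx(
                brute_force_mi(x, y, bins), abs=1e-12
            )

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 14))
        assert mutual_information(x, y, 4) == pytest.approx(
            mutual_information(y, x, 4), abs=1e-12
        )

    def test_self_mi_is_entropy_and_upper_bound(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 20))
        self_mi = mutual_information(x, x, 4)
        # self-MI equals the histogram entropy of x
        counts, _ = np.histogram(x, bins=4)
        px = counts / counts.sum()
        entropy = -np.sum(px[px > 0] * np.log2(px[px > 0]))
        assert self_mi == pytest.approx(entropy, abs=1e-12)
        assert mutual_information(x, y, 4) <= self_mi + 1e-12

    def test_bad_bins_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([1.0, 2, 3], [1.0, 2, 3], bins=1)

    def test_default_bins_rule(self):
        assert default_bins(14) == 3
        assert default_bins(7) == 2
        assert default_bins(20) == 4


class TestAssociativityMeasure:
    def test_three_four_five(self):
        am, alpha = associativity_measure(0.3, 0.4, 1.0, 1.0)
        assert am == pytest.approx(0.5)
        assert alpha == pytest.approx(math.atan2(4, 3))

    def test_zero_vector_convention(self):
        am, alpha = associativity_measure(0.0, 0.0, 1.0, 1.0)
        assert am == 0.0 and alpha == 0.0

    def test_pure_correlation_is_right_angle(self):
        _, alpha = associativity_measure(0.0, 0.7, 1.0, 1.0)
        assert alpha == pytest.approx(math.pi / 2)

    def test_negative_mi_rejected(self):
        with pytest.raises(ValueError):
            associativity_measure(-0.1, 0.5, 1.0, 1.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        mi=st.floats(0, 5),
        cor=st.floats(-1, 1),
        w1=st.floats(0.1, 10),
        w2=st.floats(0.1, 10),
        k=st.floats(0.1, 10),
    )
    def test_pythagorean_and_homogeneous(self, mi, cor, w1, w2, k):
        am, alpha = associativity_measure(mi, cor, w1, w2)
        assert am**2 == pytest.approx((w1 * mi) ** 2 + (w2 * cor) ** 2, rel=1e-12, abs=1e-12)
        assert 0.0 <= alpha <= math.pi / 2
        am_k, alpha_k = associativity_measure(mi, cor, k * w1, k * w2)
        assert am_k == pytest.approx(k * am, rel=1e-9)
        assert alpha_k == pytest.approx(alpha, abs=1e-9)


class TestAllPairStats:
    @pytest.mark.parametrize("n,expected", [(2, 1), (16, 120), (24, 276)])
    def test_pair_universe_size(self, n, expected):
        prof = make_profile(n_genes=n, seed=7)
        assert len(all_pair_stats(prof, bins=3, weights=(1, 1))) == expected

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            all_pair_stats(make_profile(n_genes=1), bins=3)

    def test_centroid_weights_normalise_both_axes(self, profile6):
        stats = all_pair_stats(profile6, weights="centroid")
        cents = centroids(stats)
        # weighted components have mean 1 on each axis
        w1, w2 = 1 / cents.mi_centroid, 1 / cents.cor_centroid
        mean_u = np.mean([w1 * s.mi_bits for s in stats])
        mean_v = np.mean([w2 * abs(s.pearson_r) for s in stats])
        assert mean_u == pytest.approx(1.0, abs=1e-9)
        assert mean_v == pytest.approx(1.0, abs=1e-9)

    def test_pairs_unique_and_ordered(self, profile6):
        stats = all_pair_stats(profile6, bins=3, weights=(1, 1))
        pairs = [s.pair for s in stats]
        assert len(set(pairs)) == len(pairs)
        assert all(a < b for a, b in pairs)

    def test_frame_export_columns(self, profile6):
        frame = stats_to_frame(all_pair_stats(profile6, bins=3, weights=(1, 1)))
        assert list(frame.columns) == [
            "gene_a", "gene_b", "mi_bits", "pearson_r", "p_value", "am", "alpha",
        ]


class TestCentroids:
    def test_single_pair_uses_absolute_r(self):
        rng = np.random.default_rng(0)
        stats = random_pair_stats(2, rng)
        s = stats[0]
        c = centroids(stats)
        assert c.mi_centroid == pytest.approx(s.mi_bits)
        assert c.cor_centroid == pytest.approx(abs(s.pearson_r))

    def test_matches_summation_oracle(self):
        rng = np.random.default_rng(8)
        stats = random_pair_stats(10, rng)
        c = centroids(stats)
        assert c.mi_centroid == pytest.approx(
            sum(s.mi_bits for s in stats) / len(stats), abs=1e-12
        )
        assert c.cor_centroid == pytest.approx(
            sum(abs(s.pearson_r) for s in stats) / len(stats), abs=1e-12
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            centroids([])
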