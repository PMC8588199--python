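"""Saliency features against independent brute-force oracles and invariants."""

import numpy as np
import pytest

from ttcseg import (
    PhantomSpec,
    color_distance,
    color_histogram_contrast,
    compute_features,
    global_color_saliency,
    local_color_saliency,
    make_compound_phantom,
    oversegment,
    spatial_color_distribution,
    superpixel_stats,
)
from ttcseg.saliency import DEFAULT_K, SuperpixelStats


def random_stats(k, rng, n_bins=64):
    hist = rng.random((k, n_bins))
    hist /= hist.sum(axis=1, keepdims=True)
    return SuperpixelStats(
        colors=rng.random((k, 6)),
        positions=rng.random((k, 2)),
        histograms=hist,
        areas=np.full(k, 10.0),
    )


# -- brute-force oracles (independent double/triple loops) --------------------

def gcs_oracle(stats):
    k = len(stats.colors)
    out = np.zeros(k)
    for i in range(k):
        for j in range(k):
            if i != j:
                out[i] += np.linalg.norm(stats.colors[i] - stats.colors[j])
    return out


def lcs_oracle(stats, sigma_p):
    k = len(stats.colors)
    out = np.zeros(k)
    for i in range(k):
        ws, terms = [], []
        for j in range(k):
            if i == j:
                continue
            d2 = ((stats.positions[i] - stats.positions[j]) ** 2).sum()
            ws.append(np.exp(-0.5 * d2 / sigma_p**2))
            terms.append(np.linalg.norm(stats.colors[i] - stats.colors[j]))
        ws = np.array(ws) / np.sum(ws)
        out[i] = float(np.dot(ws, terms))
    return out


def chc_oracle(stats):
    k, b = stats.histograms.shape
    out = np.zeros(k)
    for i in range(k):
        for j in range(k):
            for m in range(b):
                hi, hj = stats.histograms[i, m], stats.histograms[j, m]
                out[i] += (hi - hj) ** 2 / (hi + hj + 1e-12)
    return out


def scd_oracle(stats, sigma_c):
    k = len(stats.colors)
    out = np.zeros(k)
    for i in range(k):
        w = np.array(
            [
                np.exp(-0.5 * np.linalg.norm(stats.colors[i] - stats.colors[j]) ** 2 / sigma_c**2)
                for j in range(k)
            ]
        )
        w /= w.sum()
        mu = (w[:, None] * stats.positions).sum(axis=0)
        out[i] = float(np.sum(w * ((stats.positions - mu) ** 2).sum(axis=1)))
    return out


class TestColorDistance:
    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(6), rng.random(6)
        assert color_distance(a, a) == 0.0
        assert color_distance(a, b) == pytest.approx(color_distance(b, a))

    def test_unit_axis_pair_gives_sqrt_two(self):
        ci = np.array([1.0, 0, 0, 0, 0, 0])
        cj = np.array([0, 1.0, 0, 0, 0, 0])
        assert color_distance(ci, cj) == pytest.approx(np.sqrt(2.0))


class TestFeatureOracles:
    @pytest.mark.parametrize("k", [3, 7, 12])
    def test_all_four_features_match_brute_force(self, k):
        rng = np.random.default_rng(k)
        stats = random_stats(k, rng)
        np.testing.assert_allclose(global_color_saliency(stats), gcs_oracle(stats), atol=1e-9)
        np.testing.assert_allclose(
            local_color_saliency(stats, 0.25), lcs_oracle(stats, 0.25), atol=1e-9
        )
        np.testing.assert_allclose(color_histogram_contrast(stats), chc_oracle(stats), atol=1e-9)
        np.testing.assert_allclose(
            spatial_color_distribution(stats, 0.2), scd_oracle(stats, 0.2), atol=1e-9
        )

    def test_uniform_colors_zero_contrast(self):
        rng = np.random.default_rng(1)
        stats = random_stats(5, rng)
        stats = SuperpixelStats(
            colors=np.tile(stats.colors[:1], (5, 1)),
            positions=stats.positions,
            histograms=stats.histograms,
            areas=stats.areas,
        )
        assert np.allclose(global_color_saliency(stats), 0.0)
        assert np.allclose(local_color_saliency(stats, 0.25), 0.0)

    def test_two_color_pattern_doubles_minority_saliency(self):
        colors = np.zeros((3, 6))
        colors[2, 0] = 1.0  # A, A, B
        stats = SuperpixelStats(
            colors=colors,
            positions=np.array([[0.1, 0.1], [0.2, 0.2], [0.8, 0.8]]),
            histograms=np.full((3, 4), 0.25),
            areas=np.full(3, 1.0),
        )
        gcs = global_color_saliency(stats)
        assert gcs[2] == pytest.approx(2.0)
        assert gcs[0] == pytest.approx(1.0) and gcs[1] == pytest.approx(1.0)

    def test_pairwise_lcs_reduces_to_color_distance(self):
        stats = SuperpixelStats(
            colors=np.array([[0.0] * 6, [0.3] * 6]),
            positions=np.array([[0.2, 0.2], [0.7, 0.7]]),
            histograms=np.full((2, 4), 0.25),
            areas=np.full(2, 1.0),
        )
        expected = color_distance(stats.colors[0], stats.colors[1])
        np.testing.assert_allclose(local_color_saliency(stats, 0.25), [expected, expected])

    def test_disjoint_single_bin_histograms(self):
        hist = np.zeros((2, 4))
        hist[0, 0] = 1.0
        hist[1, 1] = 1.0
        stats = SuperpixelStats(
            colors=np.zeros((2, 6)),
            positions=np.zeros((2, 2)),
            histograms=hist,
            areas=np.full(2, 1.0),
        )
        np.testing.assert_allclose(color_histogram_contrast(stats), [2.0, 2.0], atol=1e-9)

    def test_scd_two_point_variance(self):
        p1, p2 = np.array([0.2, 0.3]), np.array([0.6, 0.9])
        stats = SuperpixelStats(
            colors=np.zeros((2, 6)),
            positions=np.array([p1, p2]),
            histograms=np.full((2, 4), 0.25),
            areas=np.full(2, 1.0),
        )
        expected = ((p1 - p2) ** 2).sum() / 4.0
        np.testing.assert_allclose(spatial_color_distribution(stats, 0.2), expected, atol=1e-12)

    def test_scd_translation_invariant(self):
        rng = np.random.default_rng(2)
        stats = random_stats(8, rng)
        shifted = SuperpixelStats(
            colors=stats.colors,
            positions=stats.positions + [0.13, -0.07],
            histograms=stats.histograms,
            areas=stats.areas,
        )
        np.testing.assert_allclose(
            spatial_color_distribution(stats, 0.2),
            spatial_color_distribution(shifted, 0.2),
            atol=1e-9,
        )

    def test_features_equivariant_under_label_permutation(self):
        rng = np.random.default_rng(3)
        stats = random_stats(9, rng)
        perm = rng.permutation(9)
        permuted = SuperpixelStats(
            colors=stats.colors[perm],
            positions=stats.positions[perm],
            histograms=stats.histograms[perm],
            areas=stats.areas[perm],
        )
        np.testing.assert_allclose(
            compute_features(stats)[perm], compute_features(permuted), atol=1e-9
        )


class TestOversegmentation:
    def test_default_superpixel_count_is_sixty_five(self):
        import inspect

        assert DEFAULT_K == 65
        assert inspect.signature(oversegment).parameters["n_segments"].default == 65

    def test_constant_image_near_grid_partition(self):
        img = np.full((200, 300, 3), 128, dtype=np.uint8)
        part = oversegment(img, 65)
        assert 33 <= part.n_segments <= 130
        assert np.array_equal(np.unique(part.labels), np.arange(part.n_segments))

    def test_rejects_tiny_image(self):
        with pytest.raises(ValueError):
            oversegment(np.zeros((4, 4, 3), dtype=np.uint8), 65)

    def test_each_truth_slice_owns_a_superpixel(self):
        img, truth = make_compound_phantom(PhantomSpec(seed=1))
        part = oversegment(img, 65)
        area = np.bincount(part.labels.ravel(), minlength=part.n_segments)
        for m in truth.slice_masks:
            inside = np.bincount(
                part.labels.ravel(), weights=m.ravel().astype(float), minlength=part.n_segments
            )
            assert (inside / np.maximum(area, 1)).max() >= 0.9

    def test_foreground_scd_below_background_scd(self):
        img, truth = make_compound_phantom(PhantomSpec(seed=2))
        part = oversegment(img, 65)
        stats = superpixel_stats(img, part)
        scd = spatial_color_distribution(stats)
        area = np.bincount(part.labels.ravel(), minlength=part.n_segments)
        inside = np.bincount(
            part.labels.ravel(),
            weights=truth.slice_union.ravel().astype(float),
            minlength=part.n_segments,
        )
        frac = inside / np.maximum(area, 1)
        assert scd[frac >= 0.8].mean() < scd[frac <= 0.2].mean()
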