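import numpy as np
import pytest

import asymseg as a
from asymseg import (AsymGaussianParams, GaussianParams, Histogram,
                     asymmetric_density, detect_overlap_voxels,
                     fit_asymmetric_mixture, fit_r, gaussian_density,
                     histogram_error, initial_labeling,
                     membership_probability, split_histogram)


def triangle(center, width, height, n_bins=120, span=120.0):
    """Histogram with a triangular bump (helper for split tests)."""
    edges = np.linspace(0, span, n_bins + 1)
    c = 0.5 * (edges[:-1] + edges[1:])
    return np.maximum(0, height * (1 - np.abs(c - center) / width)), edges


class TestSplitHistogram:
    def test_three_triangles_cut_in_gaps(self):
        t1, edges = triangle(20, 8, 100)
        t2, _ = triangle(60, 8, 80)
        t3, _ = triangle(100, 8, 60)
        h = Histogram(edges, np.rint(t1 + t2 + t3).astype(int))
        res = split_histogram(h, smoothing=3)
        assert 28 < res.cut_points[0] < 52
        assert 68 < res.cut_points[1] < 92
        lo, hi = res.mode_ranges[0]
        assert lo <= 20 < hi

    def test_true_means_fall_in_their_modes(self, noisefree_phantom):
        spec, vol, lab = noisefree_phantom
        h = a.compute_histogram(vol, mask=lab)
        res = split_histogram(h)
        for k, code in enumerate((1, 2, 3)):
            lo, hi = res.mode_ranges[k]
            assert lo <= spec.class_params[code].mean < hi

    def test_constant_histogram_raises(self):
        h = Histogram(np.arange(65.0), np.full(64, 10))
        with pytest.raises(ValueError, match="insufficient modes"):
            split_histogram(h)

    def test_cut_ordering(self):
        t1, edges = triangle(20, 8, 100)
        t2, _ = triangle(60, 8, 80)
        t3, _ = triangle(100, 8, 60)
        h = Histogram(edges, np.rint(t1 + t2 + t3).astype(int))
        res = split_histogram(h, smoothing=3)
        assert res.cut_points[0] < res.cut_points[1]
        assert res.mode_bin_ranges[0][1] == res.mode_bin_ranges[1][0]
        assert res.mode_bin_ranges[2][1] == h.n_bins


class TestAsymmetricDensity:
    def test_r1_equals_gaussian_pointwise(self):
        p = AsymGaussianParams(1.0, 10.0, 2.5, 1.0)
        g = GaussianParams(1.0, 10.0, 2.5 ** 2)
        z = np.linspace(-5, 25, 301)
        np.testing.assert_allclose(asymmetric_density(z, p),
                                   gaussian_density(z, g), atol=1e-12)

    @pytest.mark.parametrize("sigma", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("r", [0.5, 1.0, 3.0])
    def test_quadrature_integral_one(self, sigma, r):
        from scipy.integrate import quad
        p = AsymGaussianParams(1.0, 0.0, sigma, r)
        span = 10 * sigma * max(1.0, r)
        val, _ = quad(lambda z: asymmetric_density(z, p), -span, span)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_mean_below_mu_for_r_above_one(self):
        from scipy.integrate import quad
        p = AsymGaussianParams(1.0, 5.0, 1.0, 2.0)
        m, _ = quad(lambda z: z * asymmetric_density(z, p), -20, 20)
        assert m < 5.0

    def test_continuous_and_maximal_at_mu(self):
        p = AsymGaussianParams(1.0, 3.0, 1.5, 2.5)
        eps = 1e-9
        left, right = asymmetric_density(3.0 - eps, p), asymmetric_density(3.0 + eps, p)
        assert left == pytest.approx(right, rel=1e-6)
        z = np.linspace(-5, 11, 1000)
        assert asymmetric_density(3.0, p) >= np.max(asymmetric_density(z, p))


class TestHistogramError:
    def test_identity_zero(self):
        f = np.array([3.0, 5.0, 7.0])
        assert histogram_error(f, f) == 0.0

    def test_constant_offset(self):
        f = np.array([3.0, 5.0, 7.0])
        assert histogram_error(f, f + 1) == pytest.approx(1.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        f, g = rng.random(37) * 100, rng.random(37) * 100
        direct = sum(abs(fi - gi) for fi, gi in zip(f, g)) / 37
        assert histogram_error(f, g) == pytest.approx(direct, rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            histogram_error(np.ones(3), np.ones(4))


def _mode_histogram(mu, sigma, r, n=100_000, seed=0, n_bins=100):
    p = AsymGaussianParams(1.0, mu, sigma, r)
    s = a.sample_asymmetric_mixture([p], n, seed=seed)
    counts, edges = np.histogram(s, bins=n_bins)
    return Histogram(edges, counts)


class TestFitR:
    def test_symmetric_data_keeps_r_one(self):
        h = _mode_histogram(50.0, 5.0, 1.0)
        params, trace = fit_r(h, 50.0, 5.0)
        assert 1 / 1.1 <= params.ratio <= 1.1

    def test_recovers_r_two_within_step(self):
        h = _mode_histogram(50.0, 5.0, 2.0)
        params, trace = fit_r(h, 50.0, 5.0)
        assert 2 / 1.1 <= params.ratio <= 2 * 1.1

    def test_infinite_threshold_stops_at_one(self):
        h = _mode_histogram(50.0, 5.0, 2.0, n=1000)
        params, trace = fit_r(h, 50.0, 5.0, threshold=np.inf)
        assert params.ratio == 1.0
        assert trace.stop_reason == "threshold"
        assert len(trace.evaluations) == 1

    def test_empty_mode_raises(self):
        h = Histogram(np.arange(11.0), np.zeros(10, dtype=int))
        with pytest.raises(ValueError, match="empty mode"):
            fit_r(h, 5.0, 1.0)

    def test_chosen_never_worse_than_symmetric_start(self):
        for r_true, seed in [(0.5, 1), (1.5, 2), (2.5, 3)]:
            h = _mode_histogram(50.0, 5.0, r_true, seed=seed)
            params, trace = fit_r(h, 50.0, 5.0)
            assert trace.error_at(params.ratio) <= trace.error_at(1.0)

    def test_search_respects_bounds(self):
        h = _mode_histogram(50.0, 5.0, 4.0)
        params, trace = fit_r(h, 50.0, 5.0, r_bounds=(0.5, 2.0))
        rs = [r for r, _ in trace.evaluations]
        assert all(0.5 <= r <= 2.2 for r in rs)
        assert params.ratio <= 2.0 * 1.1


class TestFitAsymmetricMixture:
    def test_recovery_on_known_mixture(self):
        true = [AsymGaussianParams(1 / 3, 40.0, 8.0, 0.5),
                AsymGaussianParams(1 / 3, 105.0, 8.0, 1.5),
                AsymGaussianParams(1 / 3, 170.0, 8.0, 2.5)]
        s = a.sample_asymmetric_mixture(true, 300_000, seed=9)
        counts, edges = np.histogram(s, bins=256)
        fit, _, _ = fit_asymmetric_mixture(Histogram(edges, counts))
        bw = edges[1] - edges[0]
        for p, t in zip(fit, true):
            assert abs(p.mean - t.mean) <= 2 * bw
            assert abs(p.ratio - t.ratio) / t.ratio <= 0.25  # single-seed slack

    def test_all_symmetric_truth(self):
        true = [AsymGaussianParams(1 / 3, m, 8.0, 1.0) for m in (40.0, 105.0, 170.0)]
        s = a.sample_asymmetric_mixture(true, 300_000, seed=10)
        counts, edges = np.histogram(s, bins=256)
        fit, _, _ = fit_asymmetric_mixture(Histogram(edges, counts))
        for p in fit:
            assert 1 / 1.1 <= p.ratio <= 1.1

    def test_weights_match_volume_fractions(self, noisefree_phantom):
        _, vol, lab = noisefree_phantom
        h = a.compute_histogram(vol, mask=lab)
        fit, _, _ = fit_asymmetric_mixture(h)
        n_fg = lab.foreground().sum()
        for p, code in zip(fit, (1, 2, 3)):
            frac = (lab.labels == code).sum() / n_fg
            assert abs(p.weight - frac) <= 0.02


@pytest.fixture(scope="module")
def fitted(noisefree_phantom):
    _, vol, lab = noisefree_phantom
    h = a.compute_histogram(vol, mask=lab)
    params, _, _ = fit_asymmetric_mixture(h)
    post = membership_probability(vol, params)
    return vol, lab, params, post


class TestMembershipAndLabeling:

    def test_rows_sum_to_one_on_foreground(self, fitted):
        vol, lab, params, post = fitted
        fg = lab.foreground()
        np.testing.assert_allclose(post[fg].sum(axis=-1), 1.0, atol=1e-12)
        assert np.all(post[~fg] == 0)

    def test_dominant_class_at_its_mean(self, fitted):
        vol, lab, params, post = fitted
        for k, p in enumerate(params):
            v = a.Volume3D(np.full((1, 1, 1), p.mean + 0.1))
            pp = membership_probability(v, params)
            assert np.argmax(pp[0, 0, 0]) == k
            assert pp[0, 0, 0, k] > 0.99

    def test_matches_scalar_bayes_oracle(self, fitted):
        vol, lab, params, post = fitted
        rng = np.random.default_rng(0)
        fg_idx = np.argwhere(lab.foreground())
        for i in fg_idx[rng.choice(len(fg_idx), 20, replace=False)]:
            z = vol.data[tuple(i)]
            dens = np.array([p.weight * asymmetric_density(z, p) for p in params])
            np.testing.assert_allclose(post[tuple(i)], dens / dens.sum(), rtol=1e-8)

    def test_one_hot_posteriors_argmax_and_growth_noop(self):
        post = np.zeros((3, 3, 3, 3))
        post[..., 1] = 1.0
        post[0, 0, 0] = 0  # one background voxel
        plain = initial_labeling(post)
        grown = initial_labeling(post, region_grow=True)
        np.testing.assert_array_equal(plain.labels, grown.labels)
        assert plain.labels[1, 1, 1] == 2
        assert plain.labels[0, 0, 0] == 0

    def test_tie_breaks_to_lower_class(self):
        post = np.zeros((1, 1, 1, 3))
        post[0, 0, 0] = [0.5, 0.5, 0.0]
        assert initial_labeling(post).labels[0, 0, 0] == 1

    def test_noisefree_labels_equal_truth_up_to_boundary(self, fitted):
        vol, lab, params, post = fitted
        pred = initial_labeling(post)
        wrong = pred.labels != lab.labels
        if wrong.any():
            # any disagreement must sit on a true tissue boundary voxel
            from scipy import ndimage
            interior = np.ones_like(wrong)
            for c in (0, 1, 2, 3):
                m = lab.labels == c
                interior &= ~(m ^ ndimage.binary_erosion(m))
            assert not (wrong & interior).any()

    def test_region_growing_fills_low_confidence_from_neighbors(self):
        # a low-confidence voxel surrounded by confident class-3 voxels
        post = np.zeros((3, 3, 3, 3))
        post[..., 2] = 1.0
        post[1, 1, 1] = [0.4, 0.25, 0.35]  # argmax would say class 1
        lab = initial_labeling(post, region_grow=True, admit_threshold=0.5)
        assert lab.labels[1, 1, 1] == 3
        assert initial_labeling(post).labels[1, 1, 1] == 1


class TestDetectOverlap:
    def test_one_hot_gives_empty_mask(self):
        post = np.zeros((2, 2, 2, 3))
        post[..., 0] = 1.0
        mask, pairs = detect_overlap_voxels(post)
        assert not mask.any() and pairs == {}

    def test_tau_one_flags_every_foreground_voxel(self):
        rng = np.random.default_rng(1)
        raw = rng.random((3, 3, 3, 3))
        post = raw / raw.sum(-1, keepdims=True)
        mask, _ = detect_overlap_voxels(post, tau=1.0)
        assert mask.all()

    def test_noisy_flags_sit_in_ambiguous_intensity_bands(self, noisy_phantom):
        # The phantom draws intensities i.i.d. per class (no partial-volume
        # blur), so low-confidence voxels are the ambiguous-intensity draws:
        # they must be rare and must lie between the means of their two
        # competing classes, where adjacent class densities cross.
        spec, vol, lab = noisy_phantom
        h = a.compute_histogram(vol, mask=lab)
        params, _, _ = fit_asymmetric_mixture(h)
        post = membership_probability(vol, params)
        mask, pairs = detect_overlap_voxels(post)
        n_flags = int(mask.sum())
        assert 0 < n_flags < 0.02 * lab.foreground().sum()
        means = sorted(p.mean for p in params)
        vals = vol.data[mask]
        in_band = ((vals > means[0]) & (vals < means[1])) | \
                  ((vals > means[1]) & (vals < means[2]))
        assert in_band.mean() >= 0.95
        # flagged class pairs are intensity-adjacent (CSF/GM or GM/WM)
        assert set(pairs) <= {(1, 2), (2, 3)}
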