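"""Tensor-space NLM filter and the Gaussian baseline."""

import numpy as np
import pytest
import scipy.linalg

from tensornlm.metrics import MetricKind, euclidean_distance
from tensornlm.nlm import NLMConfig, denoise_nlm, gaussian_filter_tensor, nlm_weights
from tensornlm.tensors import TensorField, is_spd, to_lower_triangular

ALL_KINDS = list(MetricKind)


def _field_from_matrices(mats, mask=None):
    return TensorField(data=to_lower_triangular(np.asarray(mats)), mask=mask)


def _constant_field(shape=(6, 6)):
    t = np.diag([3.0, 2.0, 1.0])
    mats = np.broadcast_to(t, shape + (3, 3)).copy()
    return _field_from_matrices(mats)


class TestWeights:
    @pytest.mark.parametrize("metric", ALL_KINDS)
    def test_sum_to_one_and_positive(self, metric, random_spd):
        mats = random_spd(n=25).reshape(5, 5, 3, 3)
        f = _field_from_matrices(mats)
        cfg = NLMConfig(metric=metric)
        for center in [(0, 0), (2, 2), (4, 1)]:
            w = nlm_weights(center, f, cfg)
            assert all(v > 0 for v in w.values())
            assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)

    def test_constant_field_uniform(self):
        f = _constant_field((5, 5))
        w = nlm_weights((2, 2), f, NLMConfig(search_window=5))
        assert len(w) == 25
        for v in w.values():
            assert v == pytest.approx(1 / 25, abs=1e-12)
        # window clipped at the corner -> fewer, still uniform
        w = nlm_weights((0, 0), f, NLMConfig(search_window=5))
        assert len(w) == 9
        assert all(v == pytest.approx(1 / 9, abs=1e-12) for v in w.values())

    def test_large_h_gives_uniform(self, random_spd):
        mats = random_spd(n=25).reshape(5, 5, 3, 3)
        f = _field_from_matrices(mats)
        cfg = NLMConfig(metric="euclidean", h=1e12, h_mode="absolute")
        w = nlm_weights((2, 2), f, cfg)
        assert all(v == pytest.approx(1 / 25, rel=1e-10) for v in w.values())

    def test_hand_computed_toy_line(self):
        # three diagonal tensors on a line; euclidean distances computable by hand
        mats = np.array([np.diag([1.0, 1, 1]), np.diag([2.0, 1, 1]), np.diag([4.0, 1, 1])])
        f = _field_from_matrices(mats)
        h = 1.5
        cfg = NLMConfig(metric="euclidean", search_window=3, h=h, h_mode="absolute")
        w = nlm_weights((1,), f, cfg)
        # d(center, left) = 1, d(center, self) = 0, d(center, right) = 2
        raw = {(0,): np.exp(-1 / h**2), (1,): 1.0, (2,): np.exp(-4 / h**2)}
        z = sum(raw.values())
        for q, expected in raw.items():
            assert w[q] == pytest.approx(expected / z, rel=1e-12)

    def test_monotone_in_distance(self, random_spd):
        mats = random_spd(n=25).reshape(5, 5, 3, 3)
        f = _field_from_matrices(mats)
        cfg = NLMConfig(metric="euclidean")
        center = (2, 2)
        w = nlm_weights(center, f, cfg)
        c = f.matrices()[center]
        pairs = sorted(
            ((euclidean_distance(c, f.matrices()[q]), wt) for q, wt in w.items())
        )
        dists = [p[0] for p in pairs]
        wts = [p[1] for p in pairs]
        assert all(w2 <= w1 + 1e-12 for w1, w2 in zip(wts, wts[1:]))
        assert dists == sorted(dists)

    def test_center_outside_mask_errors(self):
        f = _constant_field((4, 4))
        f.mask[1, 1] = False
        with pytest.raises(ValueError, match="outside the mask"):
            nlm_weights((1, 1), f)


class TestDenoise:
    @pytest.mark.parametrize("metric", ALL_KINDS)
    def test_constant_field_is_fixed_point(self, metric):
        f = _constant_field()
        out = denoise_nlm(f, NLMConfig(metric=metric))
        np.testing.assert_allclose(out.data, f.data, rtol=1e-12, atol=1e-14)

    def test_two_point_geometric_mean(self, random_spd):
        a, b = random_spd(n=2)
        f = _field_from_matrices(np.stack([a, b]))
        cfg = NLMConfig(metric="euclidean", search_window=3, h=1e12, h_mode="absolute")
        out = denoise_nlm(f, cfg).matrices()
        expected = scipy.linalg.expm(0.5 * (scipy.linalg.logm(a) + scipy.linalg.logm(b)))
        np.testing.assert_allclose(out[0], expected, rtol=1e-8)
        np.testing.assert_allclose(out[1], expected, rtol=1e-8)

    @pytest.mark.parametrize("metric", ALL_KINDS)
    def test_output_spd_even_for_non_spd_input(self, metric, random_spd):
        mats = random_spd(n=16).reshape(4, 4, 3, 3)
        mats[1, 2] = np.diag([1.0, 0.5, -0.2])  # indefinite voxel
        f = _field_from_matrices(mats)
        out = denoise_nlm(f, NLMConfig(metric=metric, eigenvalue_floor=1e-6))
        assert is_spd(out.matrices()).all()

    def test_matches_nlm_weights(self, random_spd):
        """The vectorised filter agrees with explicit per-neighbor weights."""
        mats = random_spd(n=25).reshape(5, 5, 3, 3)
        f = _field_from_matrices(mats)
        for metric in ALL_KINDS:
            cfg = NLMConfig(metric=metric, search_window=3)
            out = denoise_nlm(f, cfg).matrices()
            center = (2, 3)
            w = nlm_weights(center, f, cfg)
            logs = sum(
                wt * scipy.linalg.logm(mats[q]) for q, wt in w.items()
            )
            np.testing.assert_allclose(out[center], scipy.linalg.expm(logs), rtol=1e-7)

    def test_flip_equivariance(self, random_spd):
        """Neighbor relabeling (axis flip) commutes with the filter."""
        mats = random_spd(n=30).reshape(5, 6, 3, 3)
        f = _field_from_matrices(mats)
        cfg = NLMConfig(metric="log_euclidean")
        out = denoise_nlm(f, cfg)
        flipped = _field_from_matrices(mats[::-1])
        out_flipped = denoise_nlm(flipped, cfg)
        np.testing.assert_allclose(out_flipped.data[::-1], out.data, rtol=1e-10)

    def test_mask_respected(self, random_spd):
        mats = random_spd(n=16).reshape(4, 4, 3, 3)
        mask = np.ones((4, 4), bool)
        mask[0, :] = False
        f = _field_from_matrices(mats, mask=mask)
        out = denoise_nlm(f, NLMConfig(metric="euclidean"))
        # background voxels pass through untouched
        np.testing.assert_array_equal(out.data[0, :], f.data[0, :])

    def test_patch_mode_consistency(self, random_spd):
        mats = random_spd(n=49).reshape(7, 7, 3, 3)
        f = _field_from_matrices(mats)
        cfg = NLMConfig(metric="euclidean", search_window=3, patch_radius=1)
        out = denoise_nlm(f, cfg).matrices()
        center = (3, 3)
        w = nlm_weights(center, f, cfg)
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)
        logs = sum(wt * scipy.linalg.logm(mats[q]) for q, wt in w.items())
        np.testing.assert_allclose(out[center], scipy.linalg.expm(logs), rtol=1e-7)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NLMConfig(search_window=4)
        with pytest.raises(ValueError):
            NLMConfig(h=-1.0)
        with pytest.raises(ValueError):
            NLMConfig(h_mode="bogus")


class TestGaussianFilter:
    def test_constant_field_identity(self):
        f = _constant_field()
        out = gaussian_filter_tensor(f, window=5, sigma=1.0)
        np.testing.assert_allclose(out.data, f.data, rtol=1e-12)

    def test_impulse_reproduces_kernel(self):
        shape = (9, 9)
        data = np.zeros(shape + (6,))
        data[4, 4, 0] = 1.0
        f = TensorField(data=data)
        sigma, window = 1.0, 5
        out = gaussian_filter_tensor(f, window=window, sigma=sigma)
        x = np.arange(-2, 3)
        k1 = np.exp(-(x**2) / (2 * sigma**2))
        kernel = np.outer(k1, k1)
        kernel /= kernel.sum()
        np.testing.assert_allclose(out.data[2:7, 2:7, 0], kernel, rtol=1e-12)
        assert out.data[..., 1:].max() == 0.0

    def test_blurs_across_boundary(self):
        """Anisotropic tensor leaks anisotropy into isotropic neighbors."""
        iso = np.eye(3)
        mats = np.broadcast_to(iso, (7, 7, 3, 3)).copy()
        mats[3, 3] = np.diag([5.0, 1.0, 1.0])
        f = _field_from_matrices(mats)
        out = gaussian_filter_tensor(f, window=5, sigma=1.0)
        from tensornlm.tensors import fractional_anisotropy

        assert fractional_anisotropy(out.matrices()[3, 4]) > 0.01

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            gaussian_filter_tensor(_constant_field(), window=4)
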