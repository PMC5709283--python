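"""DoG filtering tests: kernel construction, convolution oracle, scale rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import retinotilt as rt
from retinotilt.retina import (
    DoGParams,
    apply_dog,
    binarize,
    dog_kernel,
    edge_map,
    has_twisted_cord,
    mortar_bridging_labels,
    normalized_gaussian,
    suggest_scales,
    surround_coverage,
    window_size,
)


def direct_correlation(image, kernel, pad_mode="edge"):
    """Naive quadruple-loop correlation oracle (replicate padding)."""
    side = kernel.shape[0]
    pad = side // 2
    padded = np.pad(image, pad, mode=pad_mode)
    out = np.zeros_like(image, dtype=float)
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            acc = 0.0
            for i in range(side):
                for j in range(side):
                    acc += padded[r + i, c + j] * kernel[i, j]
            out[r, c] = acc
    return out


class TestWindowSize:
    @pytest.mark.parametrize(
        "sigma,h,expected", [(8, 8, 65), (1, 8, 9), (2, 8, 17), (1.5, 8, 13), (24, 8, 193)]
    )
    def test_rule(self, sigma, h, expected):
        assert window_size(sigma, h) == expected

    def test_side_is_always_odd(self):
        for sigma in np.linspace(0.3, 9.7, 40):
            assert window_size(sigma, 8) % 2 == 1

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            window_size(0, 8)
        with pytest.raises(ValueError):
            window_size(4, 1.5)


class TestNormalizedGaussian:
    def test_unit_sum_and_symmetry(self):
        g = normalized_gaussian(2.0, 17)
        assert g.sum() == pytest.approx(1.0, abs=1e-15)
        assert np.array_equal(g, g.T)
        assert np.array_equal(g, g[::-1])
        assert np.array_equal(g, g[:, ::-1])

    def test_delta_limit(self):
        g = normalized_gaussian(1e-6, 5)
        assert g[2, 2] == pytest.approx(1.0)
        assert g.sum() == pytest.approx(1.0)

    def test_centre_weight_against_direct_summation(self):
        # 3x3, sigma=1: centre = exp(0) / sum of the nine samples
        z = sum(
            np.exp(-(dx * dx + dy * dy) / 2.0) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
        )
        g = normalized_gaussian(1.0, 3)
        assert g[1, 1] == pytest.approx(1.0 / z, rel=1e-12)

    def test_rejects_even_side(self):
        with pytest.raises(ValueError):
            normalized_gaussian(1.0, 4)


class TestDoGKernel:
    def test_paper_scale_kernel(self):
        kern = dog_kernel(DoGParams(sigma_c=8, s=2, h=8))
        assert kern.side == 65
        assert abs(kern.weights.sum()) <= 1e-12 * np.abs(kern.weights).max()
        assert kern.weights[32, 32] > 0

    def test_fourfold_symmetry_exact(self):
        w = dog_kernel(DoGParams(sigma_c=3, s=2, h=8)).weights
        assert np.array_equal(w, w.T)
        assert np.array_equal(w, np.rot90(w))
        assert np.array_equal(w, w[::-1])

    def test_degenerates_as_surround_ratio_approaches_one(self):
        w = dog_kernel(DoGParams(sigma_c=4, s=1.0 + 1e-9, h=8)).weights
        assert np.abs(w).max() < 1e-9

    def test_surround_coverage_bound(self):
        # window half-width is 2 sigma_s for s=2, h=8: >= 95% of the
        # surround Gaussian's 1-D marginal mass is inside the filter
        assert surround_coverage(DoGParams(sigma_c=8, s=2, h=8)) >= 0.95
        assert surround_coverage(DoGParams(sigma_c=1, s=2, h=8)) >= 0.95

    def test_rejects_invalid_params(self):
        with pytest.raises(ValueError):
            DoGParams(sigma_c=-1)
        with pytest.raises(ValueError):
            DoGParams(sigma_c=1, s=1.0)
        with pytest.raises(ValueError):
            DoGParams(sigma_c=1, h=1.0)


class TestApplyDog:
    def test_zero_dc_on_constant_image(self):
        for value in (0.0, 0.31, 1.0):
            resp = apply_dog(np.full((40, 52), value), DoGParams(sigma_c=4))
            assert np.abs(resp).max() < 1e-10

    def test_matches_direct_convolution_oracle(self, rng):
        image = rng.random((24, 24))
        params = DoGParams(sigma_c=2, s=2, h=8)
        resp = apply_dog(image, params)
        expect = direct_correlation(image, dog_kernel(params).weights)
        assert np.abs(resp - expect).max() <= 1e-9

    def test_equals_blur_difference(self, rng):
        image = rng.random((48, 40))
        params = DoGParams(sigma_c=3, s=2, h=8)
        kern = dog_kernel(params)
        centre = normalized_gaussian(params.sigma_c, kern.side)
        surround = normalized_gaussian(params.sigma_s, kern.side)
        from scipy import signal

        pad = kern.side // 2
        padded = np.pad(image, pad, mode="edge")
        blur_c = signal.convolve(padded, centre, mode="valid")
        blur_s = signal.convolve(padded, surround, mode="valid")
        assert np.abs(apply_dog(image, params) - (blur_c - blur_s)).max() <= 1e-9

    def test_step_edge_antisymmetry(self):
        image = np.zeros((64, 64))
        image[:, 32:] = 1.0
        resp = apply_dog(image, DoGParams(sigma_c=4), boundary="replicate")
        mirrored = -resp[:, ::-1]
        assert np.abs(resp - mirrored).max() <= 1e-9

    def test_contrast_antisymmetry(self, rng):
        image = rng.random((30, 30))
        params = DoGParams(sigma_c=2)
        a = apply_dog(image, params)
        b = apply_dog(1.0 - image, params)
        assert np.abs(a + b).max() <= 1e-10

    def test_mirror_equivariance(self, rng):
        image = rng.random((30, 44))
        params = DoGParams(sigma_c=2)
        assert np.allclose(
            apply_dog(image[:, ::-1], params), apply_dog(image, params)[:, ::-1], atol=1e-12
        )

    def test_warns_when_kernel_dwarfs_image(self):
        with pytest.warns(UserWarning, match="window"):
            apply_dog(np.zeros((8, 8)), DoGParams(sigma_c=8))

    def test_rejects_unknown_boundary(self):
        with pytest.raises(ValueError, match="boundary"):
            apply_dog(np.zeros((8, 8)), DoGParams(sigma_c=1), boundary="wrap")


class TestBinarize:
    def test_strictly_positive_rule(self):
        assert not binarize(np.full((4, 4), -0.2)).any()
        assert not binarize(np.zeros((4, 4))).any()
        assert binarize(np.full((4, 4), 0.2)).all()

    def test_numerical_dust_is_not_activation(self):
        resp = np.array([[1.0, 1e-14], [-1e-14, -1.0]])
        assert binarize(resp).tolist() == [[True, False], [False, False]]

    def test_step_edge_bright_side(self):
        image = np.zeros((64, 64))
        image[:, 32:] = 1.0
        on = binarize(apply_dog(image, DoGParams(sigma_c=4)))
        assert on[:, 33:40].all()
        assert not on[:, 24:31].any()


class TestEdgeMap:
    def test_stack_levels_and_order(self, rng):
        image = rng.random((32, 32))
        stack = edge_map(image, [1, 2, 3])
        assert len(stack) == 3
        assert stack.scales == (1.0, 2.0, 3.0)
        for resp, binary in zip(stack.responses, stack.binaries):
            assert resp.shape == image.shape
            assert np.array_equal(binary, binarize(resp))

    def test_singleton_equals_apply_plus_binarize(self, rng):
        image = rng.random((20, 20))
        stack = edge_map(image, [2], s=1.6)
        resp = apply_dog(image, DoGParams(sigma_c=2, s=1.6))
        assert np.array_equal(stack.responses[0], resp)
        assert np.array_equal(stack.binaries[0], binarize(resp))

    def test_rejects_unsorted_scales(self, rng):
        with pytest.raises(ValueError, match="increasing"):
            edge_map(rng.random((8, 8)), [2, 1])
        with pytest.raises(ValueError, match="nonempty"):
            edge_map(rng.random((8, 8)), [])

    def test_save_roundtrip_manifest(self, rng, tmp_path):
        stack = edge_map(rng.random((12, 12)), [1, 2])
        manifest = stack.save(tmp_path)
        assert [f["sigma_c"] for f in manifest["files"]] == [1.0, 2.0]
        for entry in manifest["files"]:
            assert (tmp_path / entry["response"]).exists()
            assert (tmp_path / entry["binary"]).exists()
            assert (tmp_path / entry["sidecar"]).exists()


class TestSuggestScales:
    def test_bulge_feature_sizes(self):
        # 10 px dots, 36 px tiles: sigma 1 (window 9 < 10) up to sigma 8
        # (window 65, about twice the tile)
        assert suggest_scales(10, 36, h=8, step=1) == [1, 2, 3, 4, 5, 6, 7, 8]

    def test_tight_equal_features(self):
        assert suggest_scales(9, 9, h=8, step=1) == [1, 2]

    def test_oversized_step_degenerates_to_singleton(self):
        assert suggest_scales(10, 12, h=8, step=50) == [1]

    def test_rejects_when_no_scale_fits_smallest_feature(self):
        with pytest.raises(ValueError, match="smallest feature"):
            suggest_scales(5, 36, h=8, step=1)


class TestGrouping:
    def test_twisted_cord_appears_then_dissolves(self):
        spec = rt.StimulusSpec(
            kind="cafe_wall", rows=3, cols=6, tile_px=40, mortar_px=4, shift_frac=0.5
        )
        stack = edge_map(rt.generate_cafe_wall(spec), [2, 4, 20])
        assert has_twisted_cord(stack.binaries[0], spec)  # sigma <= mortar
        assert has_twisted_cord(stack.binaries[1], spec)
        assert not has_twisted_cord(stack.binaries[2], spec)  # tile-size blur

    def test_munsterberg_has_no_mortar_to_bridge(self):
        spec = rt.StimulusSpec(
            kind="cafe_wall", rows=3, cols=6, tile_px=40, mortar_px=0, shift_frac=0.5
        )
        stack = edge_map(rt.generate_munsterberg(spec), [2])
        assert mortar_bridging_labels(stack.binaries[0], spec) == set()
        assert not has_twisted_cord(stack.binaries[0], spec)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(
    image=arrays(
        np.float64,
        (16, 16),
        elements=st.floats(0.0, 1.0, allow_nan=False, width=64),
    ),
    sigma=st.sampled_from([1.0, 1.5, 2.0]),
)
def test_linearity_properties(image, sigma):
    """Contrast antisymmetry and mirror equivariance on arbitrary images."""
    params = DoGParams(sigma_c=sigma)
    resp = apply_dog(image, params)
    assert np.abs(resp + apply_dog(1.0 - image, params)).max() <= 1e-10
    assert np.allclose(apply_dog(image[::-1], params), resp[::-1], atol=1e-12)
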