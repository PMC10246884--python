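"""Gram matrices, masked-normalized style loss, baselines, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from citrusgen.losses import (StyleConfig, IdentityExtractor, VGGStyleExtractor,
                              extract_features, resize_mask_nearest, layer_masks,
                              gram, masked_normalized_gram, content_loss,
                              local_style_loss, local_perceptual_loss,
                              style_loss_gatys, style_loss_blackbg,
                              style_difference_matrix, quantize_levels)

ID = IdentityExtractor()


def feats(image):
    return extract_features(image, ID, ("input",))


def const_image(color, size=(8, 8)):
    """Uniform [0,255] image; identity features are color/255."""
    img = np.zeros(size + (3,), dtype=float)
    img[:] = color
    return img


def rect_mask(size, r0, r1, c0, c1):
    m = np.zeros(size, dtype=np.uint8)
    m[r0:r1, c0:c1] = 1
    return m


class TestGram:
    def test_single_channel_all_ones(self):
        g = gram(np.ones((1, 2, 2)))
        np.testing.assert_allclose(g, [[4.0]])

    def test_orthogonal_rows(self):
        f = np.array([[[1.0, 0.0]], [[0.0, 1.0]]])  # 2 channels, 1x2 maps
        np.testing.assert_allclose(gram(f), np.eye(2))

    def test_zero_tensor(self):
        np.testing.assert_allclose(gram(np.zeros((3, 2, 2))), np.zeros((3, 3)))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_matches_channel_pair_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.normal(size=(4, 5, 3))
        g = gram(f)
        expect = np.zeros((4, 4))
        for m in range(4):
            for n in range(4):
                expect[m, n] = (f[m].ravel() * f[n].ravel()).sum()
        np.testing.assert_allclose(g, expect, atol=1e-5)
        assert np.allclose(g, g.T)
        assert np.linalg.eigvalsh(g).min() > -1e-8  # PSD

    def test_psd_on_random_features(self, rng):
        for _ in range(20):
            g = gram(rng.normal(size=(3, 4, 4)))
            assert np.linalg.eigvalsh(g).min() > -1e-8


class TestMaskedNormalizedGram:
    def test_constant_color_size_invariance(self):
        f = np.zeros((3, 40, 40))
        c = np.array([0.8, 0.5, 0.2])
        f[:] = c[:, None, None]
        small = masked_normalized_gram(f, rect_mask((40, 40), 0, 2, 0, 5))
        large = masked_normalized_gram(f, rect_mask((40, 40), 0, 40, 0, 25))
        np.testing.assert_allclose(small, np.outer(c, c), atol=1e-10)
        np.testing.assert_allclose(large, small, atol=1e-10)

    def test_full_mask_reduces_to_scaled_gram(self, rng):
        f = rng.normal(size=(3, 4, 5))
        full = masked_normalized_gram(f, np.ones((4, 5)))
        np.testing.assert_allclose(full, np.asarray(gram(f)) / 20.0, atol=1e-10)

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="degenerate"):
            masked_normalized_gram(rng.normal(size=(3, 4, 4)), np.zeros((4, 4)))

    def test_mask_shape_checked(self, rng):
        with pytest.raises(ValueError, match="mask shape"):
            masked_normalized_gram(rng.normal(size=(3, 4, 4)), np.ones((5, 4)))

    def test_ignores_pixels_outside_mask(self, rng):
        f = rng.normal(size=(3, 6, 6))
        mask = rect_mask((6, 6), 0, 3, 0, 3)
        g1 = masked_normalized_gram(f, mask)
        f2 = f.copy()
        f2[:, 3:, :] = 99.0
        np.testing.assert_allclose(masked_normalized_gram(f2, mask), g1,
                                   atol=1e-8)


class TestExtractors:
    def test_identity_returns_channel_first_pixels(self, rng):
        img = (rng.random((4, 4, 3)) * 255).astype(np.uint8)
        f = feats(img)["input"].data
        np.testing.assert_allclose(f, img.transpose(2, 0, 1) / 255.0,
                                   atol=1e-6)

    def test_unknown_layer_rejected(self, rng):
        img = (rng.random((4, 4, 3)) * 255).astype(np.uint8)
        with pytest.raises(KeyError):
            extract_features(img, ID, ("Conv9_9",))
        with pytest.raises(KeyError):
            extract_features(img, VGGStyleExtractor(width_scale=0.05),
                             ("Conv9_9",))

    def test_vgg_downsampling_schedule(self, rng):
        ext = VGGStyleExtractor(seed=0, width_scale=0.0625)
        img = (rng.random((32, 32, 3)) * 255).astype(np.uint8)
        f = extract_features(img, ext, ("Conv1_1", "Conv2_1", "Conv3_1"))
        assert f["Conv1_1"].shape[-2:] == (32, 32)
        assert f["Conv2_1"].shape[-2:] == (16, 16)   # input size / 2
        assert f["Conv3_1"].shape[-2:] == (8, 8)
        assert ext.layer_factor("Conv2_1") == 2

    def test_extraction_repeatable(self, rng):
        ext = VGGStyleExtractor(seed=3, width_scale=0.0625)
        img = (rng.random((16, 16, 3)) * 255).astype(np.uint8)
        a = extract_features(img, ext, ("Conv2_1",))["Conv2_1"].data
        b = extract_features(img, ext, ("Conv2_1",))["Conv2_1"].data
        np.testing.assert_array_equal(a, b)

    def test_augmented_identity_appends_ones_channel(self, rng):
        img = (rng.random((4, 4, 3)) * 255).astype(np.uint8)
        f = extract_features(img, IdentityExtractor(augment_constant=True),
                             ("input",))["input"].data
        assert f.shape == (4, 4, 4)
        np.testing.assert_array_equal(f[3], np.ones((4, 4)))


class TestContentLoss:
    def test_zero_on_identity(self, rng):
        img = (rng.random((4, 4, 3)) * 255).astype(np.uint8)
        assert content_loss(feats(img), feats(img)) == 0.0

    def test_uniform_shift_gives_layer_count(self, rng):
        # identity features shifted by +1 -> mean squared diff 1 per layer
        f1 = {"a": np.zeros((3, 4, 4)), "b": np.zeros((2, 5, 5))}
        f2 = {k: v + 1.0 for k, v in f1.items()}
        assert content_loss(f1, f2, layers=("a", "b")) == pytest.approx(2.0)

    def test_single_pixel_difference(self):
        f1 = {"a": np.zeros((1, 4, 4))}
        f2 = {"a": np.zeros((1, 4, 4))}
        f2["a"][0, 1, 2] = 3.0
        assert content_loss(f1, f2, layers=("a",)) == pytest.approx(9.0 / 16)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            content_loss({"a": np.zeros((1, 2, 2))}, {"a": np.zeros((1, 3, 2))},
                         layers=("a",))


def _style_inputs(y, yhat, y_mask, yhat_mask, cfg=None):
    fy, fyh = feats(y), feats(yhat)
    return (fy, fyh, layer_masks(y_mask, fy), layer_masks(yhat_mask, fyh),
            cfg or StyleConfig())


class TestLocalStyleLoss:
    def test_zero_on_identity(self, rng):
        img = (rng.random((6, 6, 3)) * 255).astype(np.uint8)
        mask = rect_mask((6, 6), 1, 5, 1, 5)
        assert local_style_loss(*_style_inputs(img, img, mask, mask)) == 0.0

    def test_symmetric(self, rng):
        a = (rng.random((6, 6, 3)) * 255).astype(np.uint8)
        b = (rng.random((6, 6, 3)) * 255).astype(np.uint8)
        m = rect_mask((6, 6), 0, 4, 0, 4)
        assert local_style_loss(*_style_inputs(a, b, m, m)) == pytest.approx(
            local_style_loss(*_style_inputs(b, a, m, m)), rel=1e-9)

    def test_background_changes_do_not_matter(self, rng):
        y = (rng.random((8, 8, 3)) * 255).astype(np.uint8)
        yhat = (rng.random((8, 8, 3)) * 255).astype(np.uint8)
        mask = rect_mask((8, 8), 2, 6, 2, 6)
        before = local_style_loss(*_style_inputs(y, yhat, mask, mask))
        noisy = yhat.copy()
        noisy[~mask.astype(bool)] = rng.integers(0, 255, (48, 3))
        after = local_style_loss(*_style_inputs(y, noisy, mask, mask))
        assert after == before  # exact, by masked-Gram construction

    def test_constant_colors_closed_form(self):
        c1 = np.array([0.8, 0.4, 0.1])
        c2 = np.array([0.2, 0.6, 0.3])
        y = const_image(c1 * 255, (10, 10))
        yhat = const_image(c2 * 255, (10, 10))
        m_small = rect_mask((10, 10), 0, 2, 0, 2)
        m_large = rect_mask((10, 10), 0, 10, 0, 8)
        cfg = StyleConfig(prefactor_convention="channels_only")
        got = local_style_loss(*_style_inputs(y, yhat, m_small, m_large, cfg))
        expect = np.sum((np.outer(c1, c1) - np.outer(c2, c2)) ** 2) / 9.0
        assert got == pytest.approx(expect, rel=1e-4)

    def test_degenerate_mask_names_layer(self, rng):
        img = (rng.random((4, 4, 3)) * 255).astype(np.uint8)
        with pytest.raises(ValueError, match="input"):
            local_style_loss(*_style_inputs(img, img, np.zeros((4, 4),
                             dtype=np.uint8), np.ones((4, 4), dtype=np.uint8)))


class TestGatysAndBlackBackground:
    def test_identical_images_zero(self, rng):
        img = (rng.random((4, 4, 3)) * 255).astype(np.uint8)
        assert style_loss_gatys(feats(img), feats(img)) == 0.0
        m = np.ones((4, 4), dtype=np.uint8)
        assert style_loss_blackbg(img, img, m, m, ID) == 0.0

    def test_gatys_direct_formula_on_toy(self, rng):
        a = rng.random((2, 2, 3))
        b = rng.random((2, 2, 3))
        ga = np.asarray(gram(a.transpose(2, 0, 1)))
        gb = np.asarray(gram(b.transpose(2, 0, 1)))
        expect = ((gb - ga) ** 2).sum() / float(2 * 2 * 3) ** 2
        got = style_loss_gatys(feats(a * 255), feats(b * 255))
        assert got == pytest.approx(expect, rel=1e-5)

    def test_gatys_not_size_invariant(self):
        """Doubling a constant region's area changes the raw Gram
        quadratically, so the unmasked loss moves while L*_style does not."""
        c = np.array([0.9, 0.5, 0.1])
        size = (8, 8)
        y = const_image(c * 255, size)
        m1 = rect_mask(size, 0, 2, 0, 4)    # area 8
        m2 = rect_mask(size, 0, 4, 0, 4)    # area 16 (doubled)
        img1 = y * m1[..., None]
        img2 = y * m2[..., None]
        gat = style_loss_gatys(feats(img1), feats(img2))
        bb = style_loss_blackbg(y, y, m1, m2, ID)
        local = local_style_loss(*_style_inputs(y, y, m1, m2))
        assert gat > 1e-12 and bb > 1e-12
        assert local == pytest.approx(0.0, abs=1e-12)

    def test_blackbg_equals_gatys_on_masked_images(self, rng):
        y = (rng.random((6, 6, 3)) * 255).astype(np.uint8)
        yhat = (rng.random((6, 6, 3)) * 255).astype(np.uint8)
        my = rect_mask((6, 6), 0, 3, 0, 6)
        myh = rect_mask((6, 6), 2, 6, 0, 4)
        direct = style_loss_gatys(feats(y * my[..., None]),
                                  feats(yhat * myh[..., None]))
        assert style_loss_blackbg(y, yhat, my, myh, ID) == pytest.approx(
            direct, rel=1e-6)

    def test_blackbg_ignores_background_change(self, rng):
        y = (rng.random((6, 6, 3)) * 255).astype(np.uint8)
        m = rect_mask((6, 6), 1, 5, 1, 5)
        y2 = y.copy()
        y2[~m.astype(bool)] = 255
        assert style_loss_blackbg(y, y2, m, m, ID) == pytest.approx(0.0,
                                                                    abs=1e-12)


class TestPerceptualLoss:
    def test_zero_when_all_equal(self, rng):
        img = (rng.random((6, 6, 3)) * 255).astype(np.uint8)
        m = rect_mask((6, 6), 1, 5, 1, 5)
        f = feats(img)
        lm = layer_masks(m, f)
        assert local_perceptual_loss(f, f, f, lm, lm) == 0.0

    def test_additivity_of_components(self, rng):
        x = (rng.random((6, 6, 3)) * 255).astype(np.uint8)
        y = (rng.random((6, 6, 3)) * 255).astype(np.uint8)
        yhat = (rng.random((6, 6, 3)) * 255).astype(np.uint8)
        m = rect_mask((6, 6), 0, 4, 0, 4)
        fx, fy, fyh = feats(x), feats(y), feats(yhat)
        lmy, lmyh = layer_masks(m, fy), layer_masks(m, fyh)
        combined = local_perceptual_loss(fx, fy, fyh, lmy, lmyh)
        separate = (content_loss(fx, fyh)
                    + local_style_loss(fy, fyh, lmy, lmyh))
        assert combined == pytest.approx(separate, rel=1e-9)

    def test_reduces_to_content_when_styles_match(self, rng):
        x = (rng.random((6, 6, 3)) * 255).astype(np.uint8)
        y = (rng.random((6, 6, 3)) * 255).astype(np.uint8)
        m = rect_mask((6, 6), 0, 4, 0, 4)
        fx, fy = feats(x), feats(y)
        lm = layer_masks(m, fy)
        got = local_perceptual_loss(fx, fy, fy, lm, lm)
        assert got == pytest.approx(content_loss(fx, fy), rel=1e-9)


class TestPrefactorConvention:
    def test_single_layer_rescales_never_reorders(self, rng):
        images = [(rng.random((6, 6, 3)) * 255).astype(np.uint8)
                  for _ in range(4)]
        masks = [rect_mask((6, 6), 0, 4, 0, 4)] * 4
        m_print = style_difference_matrix(
            images, masks, "local",
            cfg=StyleConfig(prefactor_convention="as_printed"))
        m_chan = style_difference_matrix(
            images, masks, "local",
            cfg=StyleConfig(prefactor_convention="channels_only"))
        # single identity layer: the conventions differ by (H*W)^2 exactly
        np.testing.assert_allclose(m_print * float(6 * 6) ** 2, m_chan,
                                   rtol=1e-6)
        iu = np.triu_indices(4, 1)
        assert (np.argsort(m_print[iu]) == np.argsort(m_chan[iu])).all()


class TestDifferenceMatrix:
    def test_identical_images_zero_matrix(self, rng):
        img = (rng.random((4, 4, 3)) * 255).astype(np.uint8)
        m = np.ones((4, 4), dtype=np.uint8)
        out = style_difference_matrix([img, img], [m, m], "local")
        np.testing.assert_array_equal(out, np.zeros((2, 2)))

    def test_equals_pairwise_calls(self, rng):
        images = [(rng.random((5, 5, 3)) * 255).astype(np.uint8)
                  for _ in range(3)]
        out = style_difference_matrix(images, metric="gatys")
        assert np.allclose(out, out.T) and np.allclose(np.diag(out), 0)
        d01 = style_loss_gatys(feats(images[0]), feats(images[1]))
        assert out[0, 1] == pytest.approx(d01, rel=1e-6)

    def test_quantization_levels(self, rng):
        mat = rng.random((4, 4))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0)
        q = quantize_levels(mat)
        assert set(np.unique(q)) <= set(range(1, 6))
        assert q[mat.argmin() // 4, mat.argmin() % 4] == 1

    def test_masks_required_for_masked_metrics(self, rng):
        imgs = [(rng.random((4, 4, 3)) * 255).astype(np.uint8)] * 2
        with pytest.raises(ValueError, match="requires masks"):
            style_difference_matrix(imgs, None, "local")


class TestMaskResizing:
    def test_nearest_preserves_binarity(self, rng):
        mask = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        small = resize_mask_nearest(mask, (4, 4))
        assert set(np.unique(small)) <= {0, 1}
        assert small.shape == (4, 4)

    def test_vgg_layer_mask_background_tolerance(self, rng):
        """With the conv-net extractor, receptive fields blur the mask edge;
        after eroding the mask by the field radius, background perturbations
        move the local style loss by well under 1%."""
        from scipy import ndimage
        ext = VGGStyleExtractor(seed=1, width_scale=0.0625)
        layers = ("Conv1_1", "Conv2_1")
        y = (rng.random((16, 16, 3)) * 255).astype(np.uint8)
        yhat = (rng.random((16, 16, 3)) * 255).astype(np.uint8)
        mask = rect_mask((16, 16), 3, 13, 3, 13)
        eroded = ndimage.binary_erosion(mask, iterations=3).astype(np.uint8)
        fy = extract_features(y, ext, layers)
        fyh = extract_features(yhat, ext, layers)
        lm_y = layer_masks(eroded, fy)
        lm_yh = layer_masks(eroded, fyh)
        base = local_style_loss(fy, fyh, lm_y, lm_yh, layers=layers)
        far = ~ndimage.binary_dilation(mask, iterations=2)
        pert = yhat.copy()
        pert[far] = rng.integers(0, 255, (int(far.sum()), 3))
        fp = extract_features(pert, ext, layers)
        moved = local_style_loss(fy, fp, lm_y, layer_masks(eroded, fp),
                                 layers=layers)
        assert abs(moved - base) / base < 0.01


def test_heatmap_figure_written(tmp_path, rng):
    from citrusgen.losses import plot_difference_matrix
    mat = rng.random((3, 3))
    mat = (mat + mat.T) / 2
    np.fill_diagonal(mat, 0)
    plot_difference_matrix(mat, tmp_path / "levels.png")
    assert (tmp_path / "levels.png").stat().st_size > 0
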