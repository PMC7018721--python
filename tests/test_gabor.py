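"""Gabor codec: bank combinatorics, transforms, alpha fitting."""

import numpy as np
import pytest

from neurorecon import (
    GaborBankSpec,
    ImageStack,
    build_gabor_bank,
    decode_features,
    encode_images,
    fit_reverse_scale,
)
from neurorecon.gabor import FeatureMatrix, GaborBank


class TestBankGeometry:
    def test_standard_bank_filter_count(self, paper_bank):
        """4 orientations x 2 phases x (121+25+9+1) grid positions = 1248."""
        assert paper_bank.f == 1248
        per_scale = [np.sum(paper_bank.scale_index == s) for s in range(4)]
        assert per_scale == [8, 72, 200, 968]
        assert sum(per_scale) == paper_bank.f

    def test_analysis_raster_pixel_count(self, paper_bank):
        assert paper_bank.p == 1024
        assert paper_bank.spec.image_side == 32

    def test_degenerate_single_filter_bank(self):
        spec = GaborBankSpec(orientations=(0.0,), n_phases=1, scales=((64, 1, 0.02),))
        bank = build_gabor_bank(spec)
        assert bank.f == 1

    def test_filters_are_dc_free(self, paper_bank):
        assert np.max(np.abs(paper_bank.forward.mean(axis=1))) < 1e-10

    def test_reverse_is_scaled_transpose(self, fitted_bank):
        assert np.array_equal(fitted_bank.reverse, fitted_bank.alpha * fitted_bank.forward.T)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(scales=((64, 0, 0.02),)),
            dict(scales=((0, 1, 0.02),)),
            dict(scales=((64, 1, 0.18), (8, 11, 0.02))),  # cpd must increase
            dict(n_phases=0),
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            build_gabor_bank(GaborBankSpec(**bad))


class TestEncodeDecode:
    def test_zero_image_gives_zero_features(self, paper_bank):
        imgs = ImageStack(np.zeros((1024, 2)), 32)
        feats = encode_images(paper_bank, imgs)
        assert np.all(feats.values == 0)

    def test_encoding_is_the_forward_matrix_product(self, paper_bank, rng):
        """Encoding a reshaped filter row yields the Gram row of the bank."""
        k = int(rng.integers(paper_bank.f))
        img = ImageStack(paper_bank.forward[k][:, None], 32)
        feats = encode_images(paper_bank, img)
        expected = paper_bank.forward @ paper_bank.forward[k]
        np.testing.assert_allclose(feats.values[:, 0], expected, atol=1e-12)

    def test_linearity(self, paper_bank, rng):
        i1 = rng.normal(size=(1024, 1))
        i2 = rng.normal(size=(1024, 1))
        a, b = 2.5, -0.7
        lhs = encode_images(paper_bank, ImageStack(a * i1 + b * i2, 32)).values
        rhs = a * encode_images(paper_bank, ImageStack(i1, 32)).values + b * encode_images(
            paper_bank, ImageStack(i2, 32)
        ).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_shape_mismatch_raises(self, paper_bank):
        with pytest.raises(ValueError):
            encode_images(paper_bank, ImageStack(np.zeros((16 * 16, 1)), 16))
        with pytest.raises(ValueError):
            decode_features(paper_bank, np.zeros((17, 1)))

    def test_zero_features_decode_to_zero_image(self, paper_bank):
        out = decode_features(paper_bank, np.zeros((paper_bank.f, 3)))
        assert np.all(out.pixels == 0)

    def test_decode_is_scaled_adjoint(self, fitted_bank, rng):
        feats = rng.normal(size=(fitted_bank.f, 4))
        out = decode_features(fitted_bank, feats)
        np.testing.assert_array_equal(
            out.pixels, fitted_bank.alpha * (fitted_bank.forward.T @ feats)
        )

    def test_orthonormal_square_bank_roundtrip_is_identity(self, rng):
        """A unitary forward matrix with alpha=1 inverts exactly."""
        q, _ = np.linalg.qr(rng.normal(size=(16, 16)))
        spec = GaborBankSpec(image_side=4, scales=((4, 1, 0.02),))
        bank = GaborBank(spec=spec, forward=q, alpha=1.0)
        img = ImageStack(rng.normal(size=(16, 5)), 4)
        back = decode_features(bank, encode_images(bank, img))
        np.testing.assert_allclose(back.pixels, img.pixels, atol=1e-12)

    def test_natural_image_roundtrip_fidelity(self, fitted_bank, natural_images):
        """Mean pixel correlation of the round trip on 1/f images >= 0.85."""
        feats = encode_images(fitted_bank, natural_images)
        back = decode_features(fitted_bank, feats)
        cors = [
            np.corrcoef(natural_images.pixels[:, k], back.pixels[:, k])[0, 1]
            for k in range(natural_images.n_images)
        ]
        assert np.mean(cors) >= 0.85


class TestReverseScale:
    def test_orthonormal_bank_alpha_is_one(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(16, 16)))
        spec = GaborBankSpec(image_side=4, scales=((4, 1, 0.02),))
        bank = GaborBank(spec=spec, forward=q, alpha=1.0)
        fitted = fit_reverse_scale(bank, ImageStack(rng.normal(size=(16, 6)), 4))
        assert fitted.alpha == pytest.approx(1.0, abs=1e-10)

    def test_alpha_scales_inverse_square_with_forward_gain(
        self, fitted_bank, natural_images
    ):
        c = 3.0
        scaled = GaborBank(
            spec=fitted_bank.spec, forward=c * fitted_bank.forward, alpha=1.0
        )
        fitted = fit_reverse_scale(scaled, natural_images)
        assert fitted.alpha == pytest.approx(fitted_bank.alpha / c**2, rel=1e-10)

    def test_closed_form_matches_numeric_minimizer(self, fitted_bank, natural_images):
        from scipy.optimize import minimize_scalar

        sub = ImageStack(natural_images.pixels[:, :10], 32)
        M_I = fitted_bank.forward.T @ (fitted_bank.forward @ sub.pixels)

        def sse(a):
            return float(np.sum((sub.pixels - a * M_I) ** 2))

        res = minimize_scalar(sse, bounds=(0.0, 10.0), method="bounded",
                              options={"xatol": 1e-12})
        assert fit_reverse_scale(fitted_bank, sub).alpha == pytest.approx(
            res.x, abs=1e-8
        )

    def test_fitted_alpha_never_worse_than_unit(self, fitted_bank, natural_images):
        unit = GaborBank(spec=fitted_bank.spec, forward=fitted_bank.forward, alpha=1.0)
        for bank in (fitted_bank, unit):
            back = decode_features(bank, encode_images(bank, natural_images))
            err = np.sum((back.pixels - natural_images.pixels) ** 2)
            if bank is fitted_bank:
                fitted_err = err
            else:
                unit_err = err
        assert fitted_err <= unit_err

    def test_all_zero_images_rejected(self, paper_bank):
        with pytest.raises(ValueError):
            fit_reverse_scale(paper_bank, ImageStack(np.zeros((1024, 2)), 32))


class TestBankIO:
    def test_hdf5_roundtrip(self, fitted_bank, tmp_path):
        path = tmp_path / "bank.h5"
        fitted_bank.save(path)
        loaded = type(fitted_bank).load(path)
        np.testing.assert_array_equal(loaded.forward, fitted_bank.forward)
        assert loaded.alpha == fitted_bank.alpha
        assert loaded.spec == fitted_bank.spec


class TestImageIO:
    def test_png_files_map_to_unit_range(self, tmp_path, rng):
        from PIL import Image

        paths = []
        for k in range(3):
            arr = rng.integers(0, 256, size=(64, 48), dtype=np.uint8)
            p = tmp_path / f"img{k}.png"
            Image.fromarray(arr, mode="L").save(p)
            paths.append(p)
        stack = ImageStack.from_files(paths, side=32)
        assert stack.pixels.shape == (1024, 3)
        assert stack.pixels.min() >= -1.0 and stack.pixels.max() <= 1.0

    def test_tiff_roundtrip_write(self, tmp_path, natural_images):
        import tifffile

        out = tmp_path / "stack.tiff"
        natural_images.to_tiff(out)
        back = tifffile.imread(out)
        assert back.shape == (natural_images.n_images, 32, 32)
        np.testing.assert_allclose(
            back[0].ravel(), natural_images.pixels[:, 0], atol=1e-6
        )
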