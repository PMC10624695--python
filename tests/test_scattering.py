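import numpy as np
import pytest

from octscatter import (
    FilterParams,
    Image,
    build_filter_bank,
    energy_capture,
    extract_features,
    feature_count,
    scatter,
    scattering_paths,
)
from octscatter.scattering import ScatteringPath, convolve, pad_shape

from oracle_scattering import circular_conv, morlet_kernel, scatter_bruteforce


class TestConvolve:
    def test_delta_is_identity(self, rng):
        img = rng.random((16, 16))
        out = convolve(img, np.ones((16, 16)))
        assert np.max(np.abs(out - img)) < 1e-10

    def test_gaussian_preserves_constants(self, small_bank):
        out = convolve(np.full((32, 32), 0.6), small_bank.lowpass)
        assert np.max(np.abs(out - 0.6)) < 1e-10

    def test_matches_direct_space_summation(self, rng):
        img = rng.random((8, 8))
        kernel = morlet_kernel(0.85, (3 * np.pi / 4, 0.0), 0, 0.5, (8, 8))
        ref = circular_conv(img, kernel)
        out = convolve(img, np.fft.fft2(np.fft.ifftshift(kernel)))
        assert np.max(np.abs(out - ref)) / np.max(np.abs(ref)) < 1e-8

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            convolve(np.zeros((16, 16)), np.ones((8, 8)))


class TestScatter:
    def test_constant_image_only_order_zero(self, small_bank):
        feats = scatter(Image(np.full((32, 32), 0.37)), small_bank)
        s0 = feats.coefficients[ScatteringPath(order=0)]
        assert np.max(np.abs(s0 - 0.37)) < 1e-8
        for p in feats.paths:
            if p.order > 0:
                assert np.max(np.abs(feats.coefficients[p])) < 1e-8

    def test_nonnegative_higher_orders(self, small_bank, rng):
        feats = scatter(Image(rng.random((32, 32))), small_bank)
        for p in feats.paths:
            if p.order > 0:
                assert feats.coefficients[p].min() > -1e-12

    def test_canonical_path_order(self):
        paths = scattering_paths(J=3, r=2)
        assert paths[0].order == 0
        order1 = [p for p in paths if p.order == 1]
        order2 = [p for p in paths if p.order == 2]
        assert paths[1 : 1 + len(order1)] == order1
        assert [(p.j1, p.gamma1) for p in order1] == sorted(
            (p.j1, p.gamma1) for p in order1
        )
        assert all(p.j2 > p.j1 for p in order2)
        keys = [(p.j1, p.gamma1, p.j2, p.gamma2) for p in order2]
        assert keys == sorted(keys)
        with_equal = scattering_paths(J=3, r=2, include_equal_scale=True)
        assert any(p.order == 2 and p.j2 == p.j1 for p in with_equal)

    @pytest.mark.parametrize(
        "shape,J,r",
        [((64, 64), 2, 12), ((64, 64), 2, 4), ((32, 32), 2, 4),
         ((128, 128), 3, 8), ((32, 64), 1, 6), ((128, 128), 5, 12)],
    )
    def test_feature_count_formula(self, shape, J, r):
        H, W = shape
        expected = (1 + r * J + r * r * J * (J - 1) // 2) * (H * W) // 4**J
        assert feature_count(shape, J, r) == expected

    def test_worked_feature_count(self, small_bank):
        assert feature_count((64, 64), 2, 12) == 43_264
        feats = scatter(Image(np.random.default_rng(0).random((32, 32))), small_bank)
        assert feats.n_features == feature_count((32, 32), 2, 4)
        assert feats.vector.shape == (feats.n_features,)

    def test_matches_bruteforce_oracle_tiny(self, rng):
        img = rng.random((16, 16))
        bank = build_filter_bank(FilterParams((16, 16), J=2, r=2))
        v = scatter(Image(img), bank).vector
        ref = scatter_bruteforce(img, J=2, r=2)
        assert np.linalg.norm(v - ref) / np.linalg.norm(ref) < 1e-10

    def test_reflection_padding_for_nonmultiple_shapes(self, rng):
        img = rng.random((60, 60))
        assert pad_shape((60, 60), 3) == (64, 64)
        bank = build_filter_bank(FilterParams((64, 64), J=3, r=2))
        feats = scatter(Image(img), bank)
        assert feats.n_features == feature_count((60, 60), 3, 2)

    def test_too_small_image_rejected(self, small_bank):
        with pytest.raises(ValueError):
            scatter(Image(np.zeros((2, 2))), small_bank)

    def test_nonexpansive_on_random_pairs(self, small_bank):
        worst = 0.0
        for s in range(5):
            r = np.random.default_rng(s)
            f, g = r.random((32, 32)), r.random((32, 32))
            num = np.linalg.norm(
                scatter(Image(f), small_bank).vector
                - scatter(Image(g), small_bank).vector
            )
            worst = max(worst, num / np.linalg.norm(f - g))
        assert worst <= 1.05

    def test_shift_sensitivity_decreases_with_J(self, textured_fixtures):
        # cheap 64x64 variant of the translation-invariance property
        tex = textured_fixtures[0][:64, :64]
        rels = []
        for J in (2, 3, 4):
            bank = build_filter_bank(FilterParams((64, 64), J=J, r=4))
            v1 = scatter(Image(tex), bank).vector
            v2 = scatter(Image(np.roll(tex, (3, 3), axis=(0, 1))), bank).vector
            rels.append(np.linalg.norm(v1 - v2) / np.linalg.norm(v1))
        assert rels[0] > rels[1] > rels[2]


class TestEnergyCapture:
    def test_wide_blob_nearly_all_low_pass(self, bank128_J3r8):
        x = np.arange(128) - 64.0
        blob = np.exp(-(x[:, None] ** 2 + x[None, :] ** 2) / 25.0**2)
        assert energy_capture(Image(blob), bank128_J3r8) > 0.999

    def test_fraction_in_unit_interval(self, small_bank, rng):
        frac = energy_capture(Image(rng.random((32, 32))), small_bank)
        assert 0.0 <= frac <= 1.0

    def test_zero_image_rejected(self, small_bank):
        with pytest.raises(ValueError):
            energy_capture(Image(np.zeros((32, 32))), small_bank)


class TestExtractFeatures:
    def test_rows_match_single_scatter(self, small_bank, rng):
        imgs = [Image(rng.random((32, 32))) for _ in range(3)]
        X, table = extract_features(imgs, small_bank)
        assert X.shape[0] == 3
        np.testing.assert_array_equal(X[1], scatter(imgs[1], small_bank).vector)
        assert table[0][0] == "S0" and table[-1][2] == X.shape[1]

    def test_duplicates_and_permutation(self, small_bank, rng):
        img = Image(rng.random((32, 32)))
        other = Image(rng.random((32, 32)))
        X, _ = extract_features([img, img], small_bank)
        np.testing.assert_array_equal(X[0], X[1])
        Xab, _ = extract_features([img, other], small_bank)
        Xba, _ = extract_features([other, img], small_bank)
        np.testing.assert_array_equal(Xab, Xba[::-1])

    def test_heterogeneous_shapes_rejected(self, small_bank, rng):
        imgs = [Image(rng.random((32, 32))), Image(rng.random((16, 32)))]
        with pytest.raises(ValueError, match="resize"):
            extract_features(imgs, small_bank)
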