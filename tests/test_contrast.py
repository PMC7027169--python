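import numpy as np
import pytest

from emlddmm.contrast import (
    PolynomialContrast,
    basis_matrix,
    fit_weighted,
    identity_coefficients,
    monomial_exponents,
    n_basis,
    ncc_equivalent_matching_term,
)
from emlddmm.grids import Image, ImageGrid


class TestBasis:
    def test_full_cubic_rgb_has_twenty_columns_sixty_coefficients(self):
        # 1 constant + 3 linear + 6 quadratic + 10 cubic = 20 per output
        assert n_basis(3, 3, "full") == 20
        B = basis_matrix(np.random.default_rng(0).normal(size=(7, 3)), 3,
                         "full")
        assert B.shape == (7, 20)
        assert 3 * n_basis(3, 3, "full") == 60

    def test_separable_cubic_rgb_has_twelve_coefficients(self):
        assert n_basis(3, 3, "separable") == 4
        B = basis_matrix(np.zeros((5, 3)), 3, "separable")
        assert B.shape == (5, 4, 3)
        assert 3 * n_basis(3, 3, "separable") == 12

    def test_order_zero_is_single_constant_column(self):
        B = basis_matrix(np.random.default_rng(1).normal(size=(4, 2)), 0,
                         "full")
        assert B.shape == (4, 1)
        assert np.allclose(B, 1.0)

    def test_graded_lex_exponent_order_is_deterministic(self):
        e = monomial_exponents(2, 2)
        assert e.tolist() == [[0, 0], [1, 0], [0, 1], [2, 0], [1, 1], [0, 2]]

    def test_separable_requires_equal_channel_counts(self):
        with pytest.raises(ValueError):
            PolynomialContrast(order=1, mode="separable").fit(
                np.zeros((5, 2)), np.zeros((5, 3))
            )


class TestApply:
    def test_identity_coefficients_reproduce_input(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        for mode in ("full", "separable"):
            F = PolynomialContrast(order=3, mode=mode).set_identity(3)
            assert np.allclose(F.transform(X), X, atol=1e-12)

    def test_affine_map_applied_exactly_to_ramp_image(self):
        g = ImageGrid((4, 4), (1, 1), (0, 0))
        ramp = Image(g, g.coordinate_array()[..., 0])
        F = PolynomialContrast(order=1, mode="full", ridge=0).fit(
            ramp.values.reshape(-1, 1), 2 * ramp.values.reshape(-1, 1) + 1
        )
        out = F.transform_image(ramp)
        assert np.allclose(out.values, 2 * ramp.values + 1, atol=1e-10)

    def test_quadratic_solves_phantom_level_permutation(self):
        # exact solve of the 3x3 Vandermonde system for the simulated
        # intensity swap {0, 1, 1.25} -> {0, 0.9, 0.675}
        x = np.array([[0.0], [1.0], [1.25]])
        y = np.array([[0.0], [0.9], [0.675]])
        F = PolynomialContrast(order=2, mode="full", ridge=0).fit(x, y)
        assert np.allclose(F.theta_.ravel(), [0.0, 2.34, -1.44], atol=1e-10)
        assert np.allclose(F.transform(x), y, atol=1e-12)

    def test_channel_mismatch_rejected(self):
        F = PolynomialContrast(order=1).set_identity(2)
        with pytest.raises(ValueError):
            F.transform(np.zeros((3, 3)))


class TestFitWeighted:
    def test_self_fit_returns_identity(self):
        rng = np.random.default_rng(3)
        g = ImageGrid((8, 8), (1, 1), (0, 0))
        img = Image(g, rng.normal(size=(8, 8)))
        F = fit_weighted(img, img, order=1, ridge=0)
        assert np.allclose(F.theta_.ravel(), [0.0, 1.0], atol=1e-8)

    def test_noiseless_affine_target_recovered_to_machine_tolerance(self):
        rng = np.random.default_rng(4)
        g = ImageGrid((10, 10), (1, 1), (0, 0))
        img = Image(g, rng.normal(size=(10, 10)))
        tgt = Image(g, 2.0 * img.values[..., 0] + 1.0)
        F = fit_weighted(img, tgt, order=1, ridge=0)
        assert F.theta_[0, 0] == pytest.approx(1.0, abs=1e-10)
        assert F.theta_[1, 0] == pytest.approx(2.0, abs=1e-10)

    def test_zero_weight_pixels_are_ignored(self):
        # corrupting half the pixels changes nothing if their weight is 0
        rng = np.random.default_rng(5)
        g = ImageGrid((10, 10), (1, 1), (0, 0))
        img = Image(g, rng.normal(size=(10, 10)))
        clean = 0.5 * img.values - 0.2
        corrupt = clean.copy()
        mask = np.zeros((10, 10), dtype=bool)
        mask[:5] = True
        corrupt[mask] = 99.0
        w = (~mask).astype(float)
        F = fit_weighted(img, Image(g, corrupt), weights=w, order=1, ridge=0)
        g_half = ImageGrid((5, 10), (1, 1), (0, 0))
        F_clean = fit_weighted(
            Image(g_half, img.values[5:]), Image(g_half, clean[5:]),
            order=1, ridge=0,
        )
        assert np.allclose(F.theta_, F_clean.theta_, atol=1e-8)

    def test_all_zero_weights_rejected(self):
        g = ImageGrid((4, 4), (1, 1), (0, 0))
        img = Image(g, np.ones((4, 4)))
        with pytest.raises(ValueError, match="matching"):
            fit_weighted(img, img, weights=np.zeros(16), order=1)

    def test_cubic_recovery_with_standardization_in_raw_units(self):
        # de-standardization must express theta on raw intensities
        rng = np.random.default_rng(6)
        X = rng.normal(5.0, 2.0, (300, 3))
        theta = rng.normal(size=(20, 3))
        y = basis_matrix(X, 3, "full") @ theta
        F = PolynomialContrast(order=3, mode="full", ridge=0).fit(X, y)
        assert np.allclose(F.theta_, theta, atol=1e-7)
        X2 = rng.normal(5.0, 2.0, (50, 3))
        assert np.allclose(F.transform(X2), basis_matrix(X2, 3, "full") @ theta,
                           atol=1e-7)

    def test_fit_is_global_minimum_of_weighted_least_squares(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 1))
        y = rng.normal(size=(100, 1))
        w = rng.uniform(size=100)
        F = PolynomialContrast(order=2, ridge=0).fit(X, y, sample_weight=w)
        best = float(np.sum(w * (y - F.transform(X))[:, 0] ** 2))
        for seed in range(5):
            other = F.theta_ + np.random.default_rng(seed).normal(
                scale=0.1, size=F.theta_.shape
            )
            B = basis_matrix(X, 2, "full")
            alt = float(np.sum(w * (y - B @ other)[:, 0] ** 2))
            assert best <= alt + 1e-10


class TestNccEquivalence:
    def test_minimized_affine_matching_term_equals_ncc_closed_form(self):
        # the affine special case reduces to normalized cross-correlation:
        # min_theta 0.5/s^2 ||J - (aI+b)||^2 = 0.5/s^2 ||J-Jbar||^2 (1-rho^2)
        sm = 0.3
        for seed in range(20):
            rng = np.random.default_rng(seed)
            I = rng.normal(size=400)
            J = rng.normal(size=400)
            F = PolynomialContrast(order=1, mode="full", ridge=0).fit(
                I[:, None], J[:, None]
            )
            resid = J - F.transform(I[:, None])[:, 0]
            direct = 0.5 / sm**2 * np.sum(resid**2)
            closed = ncc_equivalent_matching_term(I, J, sm)
            assert abs(direct - closed) < 1e-10 * max(1.0, abs(closed))

    def test_order_two_fit_can_permute_three_intensity_levels(self):
        # non-monotonicity: gray/white brightness swap is expressible
        x = np.repeat([0.0, 1.0, 1.25], 30)[:, None]
        y = np.repeat([0.0, 0.9, 0.675], 30)[:, None]
        F = PolynomialContrast(order=2, ridge=0).fit(x, y)
        out = F.transform(np.array([[0.0], [1.0], [1.25]])).ravel()
        assert out[1] > out[2] > out[0]  # input order 0 < 1 < 1.25 permuted

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 2))
        y = rng.normal(size=(50, 2))
        F = PolynomialContrast(order=2, mode="full").fit(X, y)
        F2 = PolynomialContrast.from_dict(F.to_dict())
        assert np.allclose(F.transform(X), F2.transform(X))
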