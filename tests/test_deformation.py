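import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from emlddmm.deformation import (
    SobolevOperator,
    Transform,
    VelocityField,
    flow,
    jacobian_determinant,
    make_operator,
    matching_gradient,
    regularization_energy,
    taper_margin,
)
from emlddmm.grids import Image, ImageGrid, interpolate
from emlddmm.mixture import matching_term


def smooth_velocity(grid, nt, amp, seed, sigma=3.0, taper=3):
    rng = np.random.default_rng(seed)
    vals = gaussian_filter(
        rng.normal(size=(nt,) + grid.shape + (grid.ndim,)),
        (0,) + (sigma,) * grid.ndim + (0,), mode="wrap",
    )
    vals *= amp / np.abs(vals).max()
    vals *= taper_margin(grid, taper)[None, ..., None]
    return VelocityField(grid, vals)


class TestSobolevOperator:
    def test_zero_length_scale_is_identity(self):
        g = ImageGrid((8, 8), (1, 1), (0, 0))
        op = make_operator(g, 0.0, 4)
        assert np.allclose(op.multiplier, 1.0)
        x = np.random.default_rng(0).normal(size=(8, 8))
        assert np.allclose(op.apply(x), x, atol=1e-12)

    def test_multiplier_is_one_at_zero_frequency_and_at_least_one(self):
        g = ImageGrid((6, 10), (0.7, 1.3), (0, 0))
        op = make_operator(g, 2.5, 4)
        assert op.multiplier[0, 0] == pytest.approx(1.0)
        assert np.all(op.multiplier >= 1.0 - 1e-12)

    def test_nyquist_value_in_1d_symbol(self):
        # spacing 1, a=1, p=4: discrete symbol at Nyquist is 2(1-cos pi)=4,
        # so the multiplier is (1+4)^4 = 625
        g = ImageGrid((8, 1), (1, 1), (0, 0))
        with pytest.raises(ValueError):
            make_operator(g, -1.0)
        g = ImageGrid((8, 8), (1, 1), (0, 0))
        op = make_operator(g, 1.0, 4)
        assert op.multiplier[4, 0] == pytest.approx(625.0)

    def test_smooth_inverts_apply(self):
        g = ImageGrid((8, 8), (1, 1), (0, 0))
        op = make_operator(g, 1.5, 2)
        x = np.random.default_rng(1).normal(size=(8, 8, 2))
        assert np.allclose(op.smooth(op.apply(x)), x, atol=1e-10)


class TestFlow:
    def test_zero_velocity_gives_identity_exactly(self):
        g = ImageGrid((6, 6), (1, 1), (0, 0))
        fl = flow(VelocityField.zeros(g, 3))
        ident = g.coordinate_array()
        assert np.array_equal(fl.phi.values, ident)
        assert np.array_equal(fl.phi_inv.values, ident)

    def test_constant_velocity_integrates_to_translation(self):
        g = ImageGrid((16, 16), (1, 1), (0, 0))
        c = np.array([0.3, -0.2])
        nt = 4
        vals = np.broadcast_to(c, (nt,) + g.shape + (2,)).copy()
        fl = flow(VelocityField(g, vals))
        ident = g.coordinate_array()
        assert np.allclose(fl.phi.values, ident + c, atol=1e-12)
        # the clamped boundary contaminates one interpolation stencil per
        # timestep; the inverse is exact outside that margin
        m = nt + 1
        assert np.allclose(
            fl.phi_inv.values[m:-m, m:-m], (ident - c)[m:-m, m:-m], atol=1e-12
        )

    def test_inverse_consistency_improves_with_nt(self):
        g = ImageGrid((32, 32), (1, 1), (0, 0))
        errs = []
        for nt in (2, 4, 8, 16):
            base = smooth_velocity(g, 1, 2.0, seed=3, sigma=4.0)
            v = VelocityField(g, np.repeat(base.values, nt, axis=0))
            fl = flow(v)
            comp = interpolate(fl.phi.as_image(), fl.phi_inv.values)
            err = np.abs(comp - g.coordinate_array())[4:-4, 4:-4].max()
            errs.append(err)
        assert all(b < a for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 0.1

    def test_flow_of_smooth_field_stays_diffeomorphic(self):
        g = ImageGrid((32, 32), (1, 1), (0, 0))
        v = smooth_velocity(g, 4, 2.0, seed=4, sigma=4.0)
        fl = flow(v)
        assert jacobian_determinant(fl.phi).scalar().min() > 0
        assert jacobian_determinant(fl.phi_inv).scalar().min() > 0


class TestJacobianDeterminant:
    def test_identity_is_one(self):
        g = ImageGrid((5, 7), (0.5, 2.0), (0, 0))
        assert np.allclose(
            jacobian_determinant(Transform.identity(g)).scalar(), 1.0
        )

    def test_uniform_scaling_gives_power_of_scale(self):
        g = ImageGrid((6, 6), (1, 1), (0, 0))
        T = Transform(g, 1.7 * g.coordinate_array())
        assert np.allclose(jacobian_determinant(T).scalar(), 1.7**2)

    def test_translation_is_volume_preserving(self):
        g = ImageGrid((6, 6), (1, 1), (0, 0))
        T = Transform(g, g.coordinate_array() + np.array([2.0, -1.0]))
        assert np.allclose(jacobian_determinant(T).scalar(), 1.0)


class TestRegularizationEnergy:
    def test_zero_velocity_has_zero_energy(self):
        g = ImageGrid((8, 8), (1, 1), (0, 0))
        v = VelocityField.zeros(g, 2)
        A = make_operator(g, 1.0, 2)
        assert regularization_energy(v, A, 1.0) == 0.0

    def test_quadratic_scaling(self):
        g = ImageGrid((16, 16), (1, 1), (0, 0))
        v = smooth_velocity(g, 2, 1.0, seed=5)
        A = make_operator(g, 1.0, 2)
        e1 = regularization_energy(v, A, 1.0)
        e2 = regularization_energy(VelocityField(g, 2 * v.values), A, 1.0)
        assert e2 == pytest.approx(4 * e1)
        assert e1 > 0

    def test_single_frequency_matches_parseval_closed_form(self):
        # for v = sin(2 pi k x / n), <Av, v> = multiplier(k) * ||v||^2
        n = 16
        g = ImageGrid((n, n), (1, 1), (0, 0))
        A = make_operator(g, 1.2, 2)
        k = 3
        x = np.arange(n)
        field = np.zeros((1, n, n, 2))
        field[0, ..., 0] = np.sin(2 * np.pi * k * x / n)[:, None]
        v = VelocityField(g, field)
        sig = 1.5
        got = regularization_energy(v, A, sig)
        expected = (
            0.5 / sig**2 * A.multiplier[k, 0] * np.sum(field[0, ..., 0] ** 2)
        )
        assert got == pytest.approx(expected, rel=1e-10)

    def test_invalid_sigma_rejected(self):
        g = ImageGrid((8, 8), (1, 1), (0, 0))
        v = VelocityField.zeros(g, 1)
        with pytest.raises(ValueError):
            regularization_energy(v, make_operator(g, 1.0), 0.0)

    def test_energy_invariant_under_time_reversal_with_sign_flip(self):
        g = ImageGrid((16, 16), (1, 1), (0, 0))
        v = smooth_velocity(g, 4, 1.0, seed=6)
        A = make_operator(g, 1.0, 2)
        rev = VelocityField(g, -v.values[::-1])
        assert regularization_energy(rev, A, 1.0) == pytest.approx(
            regularization_energy(v, A, 1.0)
        )


class TestMatchingGradient:
    def _setup(self, seed=0, n=16):
        rng = np.random.default_rng(seed)
        g = ImageGrid((n, n), (1.0, 1.0), (0.0, 0.0))
        I = Image(g, gaussian_filter(rng.normal(size=(n, n)), 2.5, mode="wrap"))
        J = Image(g, gaussian_filter(rng.normal(size=(n, n)), 2.5, mode="wrap"))
        A = make_operator(g, 2.0, 2)
        return g, I, J, A

    def test_perfect_match_has_zero_gradient(self):
        g, I, _, A = self._setup()
        v = VelocityField.zeros(g, 2)
        fl = flow(v)
        preds = [I, I]
        grad = matching_gradient(
            v, fl, preds, I, np.ones(g.shape), 1.0, 0.5, A, smoothed=False
        )
        assert np.allclose(grad, 0.0, atol=1e-12)

    def test_zero_weight_reduces_to_regularization(self):
        g, I, J, A = self._setup()
        v = smooth_velocity(g, 2, 0.3, seed=1)
        fl = flow(v)
        preds = [Image(g, interpolate(I, fl.phi_inv_t[t].values))
                 for t in range(2)]
        grad = matching_gradient(
            v, fl, preds, J, np.zeros(g.shape), 2.0, 0.5, A, smoothed=True
        )
        assert np.allclose(grad, v.values / 2.0**2, atol=1e-12)

    @staticmethod
    def _objective(I, J, pi, vvals, g, A, sr, sm):
        v = VelocityField(g, vvals)
        fl = flow(v)
        pred = Image(g, interpolate(I, fl.phi_inv.values))
        return regularization_energy(v, A, sr) + matching_term(J, pred, pi, sm)

    def test_matches_finite_differences_at_flow_start(self):
        # central differences of the objective at interior voxels, probed at
        # the v=0 linearization point where the semi-Lagrangian transport is
        # exact; this validates the analytic optimality-condition gradient
        g, I, J, A = self._setup()
        rng = np.random.default_rng(42)
        pi = gaussian_filter(rng.uniform(size=g.shape), 2, mode="wrap")
        pi = (pi - pi.min()) / np.ptp(pi)
        sr, sm, nt = 2.0, 0.2, 3
        v = VelocityField.zeros(g, nt)
        fl = flow(v)
        preds = [Image(g, interpolate(I, fl.phi_inv_t[t].values))
                 for t in range(nt)]
        grad = matching_gradient(v, fl, preds, J, pi, sr, sm, A,
                                 smoothed=False)
        scale = np.abs(grad).max()
        dt, vv = 1.0 / nt, g.voxel_volume
        eps = 1e-4
        n_checked = 0
        for _ in range(40):
            t = rng.integers(nt)
            i, j = rng.integers(2, 14, 2)  # interior (taper margin)
            d = rng.integers(2)
            vp = v.values.copy()
            vp[t, i, j, d] += eps
            vm = v.values.copy()
            vm[t, i, j, d] -= eps
            fd = (
                self._objective(I, J, pi, vp, g, A, sr, sm)
                - self._objective(I, J, pi, vm, g, A, sr, sm)
            ) / (2 * eps) / (dt * vv)
            assert abs(fd - grad[t, i, j, d]) <= 1e-2 * scale
            n_checked += 1
        assert n_checked == 40

    def test_direction_agrees_at_nonzero_velocity(self):
        # at nonzero v the piecewise-linear interpolant makes pointwise
        # agreement unattainable; directional derivatives along smooth
        # perturbations validate the transported-residual factors at a
        # documented looser tolerance
        g, I, J, A = self._setup(seed=3)
        pi = np.ones(g.shape)
        sr, sm, nt = 2.0, 0.2, 5
        v = smooth_velocity(g, nt, 0.3, seed=7)
        fl = flow(v)
        preds = [Image(g, interpolate(I, fl.phi_inv_t[t].values))
                 for t in range(nt)]
        grad = matching_gradient(v, fl, preds, J, pi, sr, sm, A,
                                 smoothed=False)
        rels = []
        for s in range(5):
            w = smooth_velocity(g, nt, 1.0, seed=100 + s, sigma=2.0).values
            w /= np.sqrt(np.sum(w**2))
            eps = 1e-3
            fd = (
                self._objective(I, J, pi, v.values + eps * w, g, A, sr, sm)
                - self._objective(I, J, pi, v.values - eps * w, g, A, sr, sm)
            ) / (2 * eps)
            an = np.sum(grad * w) / nt * g.voxel_volume
            rels.append(abs(fd - an) / max(abs(fd), 1e-12))
        assert np.median(rels) < 0.25
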