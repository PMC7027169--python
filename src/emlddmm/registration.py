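"""Joint affine + diffeomorphic + contrast + mixture registration driver.

The outer loop is an EM algorithm.  The E-step computes per-pixel class
posteriors (matching / artifact / background) under the current prediction;
the M-step runs gradient descent on the velocity field and the affine
parameters simultaneously, with the polynomial contrast coefficients and the
constant class means re-estimated in closed form each iteration.  A
coarse-to-fine grid pyramid mitigates sensitivity to initialization.

The total map from target world coordinates to atlas coordinates is
``phi^{-1}(A^{-1} x)``: the atlas is deformed diffeomorphically in its own
space and then positioned affinely into the target.  The estimator stores
the affine as its target-to-atlas form internally and exposes both.

Evaluation helpers: landmark target-registration error normalized by the
image diagonal, and the Dice overlap coefficient.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import mixture as mx
from .contrast import PolynomialContrast
from .deformation import (
    Flow,
    SobolevOperator,
    Transform,
    VelocityField,
    flow,
    jacobian_determinant,
    matching_gradient,
    regularization_energy,
    taper_margin,
)
from .grids import Image, ImageGrid, block_average, build_pyramid, interpolate


class AffineMap:
    """Affine map acting about a fixed center: y = L (x - c) + c + t.

    Centering decorrelates the linear and translation parameters, which
    differ in scale by the size of the field of view; their gradient steps
    are preconditioned separately.
    """

    def __init__(self, linear: np.ndarray, translation: np.ndarray,
                 center: np.ndarray):
        self.linear = np.asarray(linear, dtype=float)
        self.translation = np.asarray(translation, dtype=float)
        self.center = np.asarray(center, dtype=float)

    @classmethod
    def identity(cls, ndim: int, center=None) -> "AffineMap":
        c = np.zeros(ndim) if center is None else np.asarray(center, float)
        return cls(np.eye(ndim), np.zeros(ndim), c)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return (points - self.center) @ self.linear.T + self.center + self.translation

    def inverse(self) -> "AffineMap":
        Linv = np.linalg.inv(self.linear)
        return AffineMap(Linv, -Linv @ self.translation, self.center)

    def matrix(self) -> np.ndarray:
        """Homogeneous (ndim+1) x (ndim+1) matrix form."""
        d = self.linear.shape[0]
        M = np.eye(d + 1)
        M[:d, :d] = self.linear
        M[:d, d] = self.center + self.translation - self.linear @ self.center
        return M

    def copy(self) -> "AffineMap":
        return AffineMap(self.linear.copy(), self.translation.copy(),
                         self.center.copy())


def project_rotation(L: np.ndarray) -> np.ndarray:
    """Nearest rotation (Frobenius) to L, with positive determinant."""
    U, _, Vt = np.linalg.svd(L)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
    return R


def project_similarity(L: np.ndarray) -> np.ndarray:
    U, s, Vt = np.linalg.svd(L)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
        s = s.copy()
        s[-1] *= -1
    return float(np.mean(s)) * R


class EMLDDMMRegistration(BaseEstimator):
    """EM-based diffeomorphic registration with intensity transforms.

    Fits a deformation (LDDMM velocity-field flow), an affine map, a
    polynomial contrast transform, and per-pixel class posteriors that
    discount artifact and background pixels, by alternating E-steps with
    simultaneous gradient descent on the geometric parameters.

    Parameters
    ----------
    sigma_m, sigma_a, sigma_b : float
        Noise standard deviations of the matching / artifact / background
        classes (intensity units).  ``None`` for sigma_a/sigma_b defaults to
        ``5 * sigma_m``.
    sigma_r : float
        Deformation penalty weight (larger = more deformation allowed).
    a : float
        Smoothness length scale of the velocity operator (physical units).
    p : float
        Power of the Sobolev operator (id - a^2 Laplacian)^p.
    order, contrast_mode : polynomial contrast configuration.
    classes : tuple of class names; ("matching",) disables the mixture.
    nt : number of flow timesteps.
    pyramid : descending block-average factors, e.g. (4, 2, 1).
    affine : {"none", "rigid", "similarity", "affine"} family of the linear
        part.
    n_em : EM cycles per pyramid level.
    n_iter : M-step gradient iterations per EM cycle.
    step_v, step_l, step_t : gradient step sizes for velocity / linear /
        translation parts; all are halved together when a step increases the
        objective (backtracking).  The velocity step is deliberately small
        relative to the affine steps so the linear transform stays near
        optimal throughout.
    tol : relative objective-change convergence tolerance (over a 10
        iteration window).
    priors : optional class prior dict (default uniform).

    Attributes
    ----------
    phi_, phi_inv_ : Transform
        Forward and inverse diffeomorphism (atlas space).
    affine_ : (ndim+1, ndim+1) array
        Atlas-to-target affine in homogeneous form.
    contrast_ : PolynomialContrast
        Fitted intensity transform (theta in ``contrast_.theta_``).
    posteriors_ : mixture.ClassPosteriors on the target grid.
    mixture_ : mixture.MixtureModel with final class means.
    objective_trace_ : list of per-iteration records (level, cycle,
        iteration, objective terms, backtracking events).
    nll_trace_ : penalized negative marginal log-likelihood per EM cycle
        (the quantity EM cannot increase).
    converged_ : bool
    """

    def __init__(self, sigma_m=0.1, sigma_a=None, sigma_b=None, sigma_r=1.0,
                 a=8.0, p=2.0, order=1, contrast_mode="full",
                 classes=(mx.MATCHING, mx.ARTIFACT, mx.BACKGROUND),
                 nt=5, pyramid=(1,), affine="affine", n_em=10, n_iter=30,
                 step_v=None, step_l=None, step_t=None, tol=1e-4,
                 priors=None, taper_width=2, rng=None):
        self.sigma_m = sigma_m
        self.sigma_a = sigma_a
        self.sigma_b = sigma_b
        self.sigma_r = sigma_r
        self.a = a
        self.p = p
        self.order = order
        self.contrast_mode = contrast_mode
        self.classes = classes
        self.nt = nt
        self.pyramid = pyramid
        self.affine = affine
        self.n_em = n_em
        self.n_iter = n_iter
        self.step_v = step_v
        self.step_l = step_l
        self.step_t = step_t
        self.tol = tol
        self.priors = priors
        self.taper_width = taper_width
        self.rng = rng

    # ------------------------------------------------------------------
    def fit(self, atlas: Image, target: Image):
        self._validate(atlas, target)
        atl_pyr = build_pyramid(atlas, list(self.pyramid))
        tgt_pyr = build_pyramid(target, list(self.pyramid))
        self.objective_trace_ = []
        self.nll_trace_ = []
        v = None
        aff = None
        for level, (I_l, J_l) in enumerate(zip(atl_pyr, tgt_pyr)):
            v, aff = self._fit_level(level, I_l, J_l, v, aff)
        self._finalize(atlas, target, v, aff)
        return self

    # ------------------------------------------------------------------
    def _validate(self, atlas: Image, target: Image):
        if atlas.grid.ndim != target.grid.ndim:
            raise ValueError("atlas and target dimensionality differ")
        # physical overlap check
        for d in range(atlas.grid.ndim):
            lo_a = atlas.grid.origin[d]
            hi_a = lo_a + (atlas.grid.shape[d] - 1) * atlas.grid.spacing[d]
            lo_t = target.grid.origin[d]
            hi_t = lo_t + (target.grid.shape[d] - 1) * target.grid.spacing[d]
            if hi_a < lo_t or hi_t < lo_a:
                raise ValueError(
                    f"atlas and target physical domains do not overlap on axis {d}"
                )
        if self.sigma_m <= 0 or self.sigma_r <= 0:
            raise ValueError("sigma_m and sigma_r must be > 0")
        if mx.MATCHING not in self.classes:
            raise ValueError('"matching" class is required')

    def _steps(self, grid: ImageGrid):
        """Target size of the *first* update at each level, physical units.

        The raw gradients are rescaled so the first velocity update moves at
        most ``step_v`` voxels worth of velocity, the first translation
        update at most ``step_t`` voxels, and the first linear-part update
        has max entry ``step_l``; backtracking halves all three together
        afterwards.  The velocity step is kept small relative to the affine
        steps so the linear transform stays near optimal throughout.
        """
        h = float(np.mean(grid.spacing))
        step_l = 0.02 if self.step_l is None else self.step_l
        step_t = 0.4 * h if self.step_t is None else self.step_t
        step_v = 0.1 * h if self.step_v is None else self.step_v
        return step_v, step_l, step_t

    def _fit_level(self, level: int, I_l: Image, J_l: Image, v_prev, aff_prev):
        grid = I_l.grid
        nt = int(self.nt)
        if v_prev is None:
            v = VelocityField.zeros(grid, nt)
        else:
            # upsample the coarse velocity to this level's grid
            vals = np.stack(
                [
                    interpolate(Image(v_prev.grid, v_prev.values[t]),
                                grid.coordinate_array())
                    for t in range(v_prev.nt)
                ]
            )
            v = VelocityField(grid, vals)
        center = np.array(
            [
                o + (n - 1) / 2.0 * d
                for n, d, o in zip(J_l.grid.shape, J_l.grid.spacing,
                                   J_l.grid.origin)
            ]
        )
        if aff_prev is None:
            M = AffineMap.identity(grid.ndim, center)  # target -> atlas
        else:
            M = aff_prev.copy()
        A_op = SobolevOperator(grid, self.a, self.p)
        taper = taper_margin(grid, self.taper_width)
        sigma_a = 5.0 * self.sigma_m if self.sigma_a is None else self.sigma_a
        sigma_b = 5.0 * self.sigma_m if self.sigma_b is None else self.sigma_b
        model = mx.MixtureModel.from_target(
            J_l, classes=tuple(self.classes), sigma_m=self.sigma_m,
            sigma_a=sigma_a, sigma_b=sigma_b, priors=self.priors,
        )
        F = PolynomialContrast(order=self.order, mode=self.contrast_mode)
        theta_ready = False
        tgt_coords = J_l.grid.coordinate_array()
        tgt_flat = J_l.values.reshape(-1, J_l.n_channels)
        use_em = len(self.classes) > 1
        step_v, step_l, step_t = self._steps(grid)
        step_v0, step_l0, step_t0 = step_v, step_l, step_t

        def predict(fl: Flow, Mmap: AffineMap, Fmap):
            """Deformed atlas sampled on the target grid, pre/post contrast."""
            pts = Mmap(tgt_coords.reshape(-1, grid.ndim))
            ID = interpolate(I_l, fl.phi_inv.values)  # atlas grid, pre-contrast
            samp = interpolate(Image(grid, ID), pts).reshape(
                J_l.grid.shape + (I_l.n_channels,)
            )
            pre = Image(J_l.grid, samp)
            if Fmap is None:
                return ID, pre, pre
            return ID, pre, Fmap.transform_image(pre)

        fl = flow(v)
        ID, pre, pred = predict(fl, M, None)
        # initialize contrast from the undeformed configuration
        F.fit(pre.values.reshape(-1, pre.n_channels), tgt_flat)
        theta_ready = True
        pred = F.transform_image(pre)

        pi_m = np.ones(J_l.grid.shape)
        post = mx.ClassPosteriors(J_l.grid, {mx.MATCHING: pi_m})
        objective_window = []
        converged = False
        grad_scale = None
        for cycle in range(self.n_em):
            # ---------------- E step ----------------
            if use_em:
                post = mx.e_step(J_l, pred, model)
                pi_m = post.matching
                # penalized negative marginal log-likelihood; the pixel sum
                # carries the voxel volume so it matches the Riemann-sum
                # discretization of the matching term (EM then cannot
                # increase this quantity)
                nll = regularization_energy(v, A_op, self.sigma_r) - (
                    mx.log_evidence(J_l, pred, model)
                ) * J_l.grid.voxel_volume
                self.nll_trace_.append(
                    {"level": level, "cycle": cycle, "nll": nll}
                )
            # ---------------- M step ----------------
            for it in range(self.n_iter):
                fl = flow(v)
                ID, pre, pred = predict(fl, M, F)
                # closed-form contrast and class means
                F.fit(
                    pre.values.reshape(-1, pre.n_channels),
                    tgt_flat,
                    sample_weight=pi_m.reshape(-1),
                )
                pred = F.transform_image(pre)
                if use_em:
                    mx.update_class_means(J_l, post, model)
                obj_reg = regularization_energy(v, A_op, self.sigma_r)
                obj_match = mx.matching_term(J_l, pred, pi_m, self.sigma_m)
                obj = obj_reg + obj_match
                self.objective_trace_.append(
                    {
                        "level": level, "cycle": cycle, "iter": it,
                        "reg": obj_reg, "match": obj_match, "total": obj,
                        "backtrack": False,
                    }
                )
                # ----- gradients -----
                g_v = self._velocity_gradient(
                    v, fl, I_l, J_l, F, M, pi_m, A_op, taper
                )
                if self.affine != "none":
                    g_l, g_t = self._affine_gradient(
                        J_l, pred, ID, grid, M, pi_m, F
                    )
                if grad_scale is None:
                    # normalize so the first update has the configured size
                    sv = np.abs(g_v).max()
                    sl = np.abs(g_l).max() if self.affine != "none" else 1.0
                    st = (
                        np.abs(g_t).max() if self.affine != "none" else 1.0
                    )
                    grad_scale = (
                        1.0 / max(sv, 1e-12),
                        1.0 / max(sl, 1e-12),
                        1.0 / max(st, 1e-12),
                    )
                g_v = g_v * grad_scale[0]
                if self.affine != "none":
                    g_l = g_l * grad_scale[1]
                    g_t = g_t * grad_scale[2]
                # ----- trial step with backtracking -----
                accepted = False
                for _ in range(12):
                    v_try = VelocityField(grid, v.values - step_v * g_v)
                    M_try = M.copy()
                    if self.affine != "none":
                        M_try.linear = M.linear - step_l * g_l
                        M_try.translation = M.translation - step_t * g_t
                        M_try.linear = self._project(M_try.linear)
                    fl_try = flow(v_try)
                    _, pre_try, pred_try = predict(fl_try, M_try, F)
                    obj_try = regularization_energy(
                        v_try, A_op, self.sigma_r
                    ) + mx.matching_term(J_l, pred_try, pi_m, self.sigma_m)
                    if obj_try <= obj + 1e-10 * max(abs(obj), 1.0):
                        accepted = True
                        break
                    step_v *= 0.5
                    step_l *= 0.5
                    step_t *= 0.5
                    self.objective_trace_[-1]["backtrack"] = True
                if not accepted:
                    break  # stuck at machine precision
                # accepted: cautiously grow the steps (capped) so plateaus
                # traverse quickly; backtracking halves them again if needed
                step_v = min(step_v * 1.1, 20.0 * step_v0)
                step_l = min(step_l * 1.1, 20.0 * step_l0)
                step_t = min(step_t * 1.1, 20.0 * step_t0)
                v, M, pred = v_try, M_try, pred_try
                if not np.isfinite(obj_try):
                    raise FloatingPointError(
                        "objective diverged (NaN/inf); last stable state kept"
                    )
                objective_window.append(obj_try)
                if len(objective_window) > 10:
                    rel = abs(objective_window[-11] - obj_try) / max(
                        abs(obj_try), 1e-12
                    )
                    if rel < self.tol:
                        converged = True
                        break
            fl = flow(v)
            ID, pre, pred = predict(fl, M, F)
            if converged and not use_em:
                break
        self._level_state = (model, F, post, pred, converged)
        return v, M

    def _project(self, L):
        if self.affine == "rigid":
            return project_rotation(L)
        if self.affine == "similarity":
            return project_similarity(L)
        return L

    def _velocity_gradient(self, v, fl, I_l, J_l, F, M, pi_m, A_op, taper):
        grid = v.grid
        Minv = M.inverse()
        # target and weights pulled back to atlas space through the affine
        atl_coords = grid.coordinate_array()
        back = Minv(atl_coords.reshape(-1, grid.ndim))
        J_A = interpolate(J_l, back).reshape(grid.shape + (J_l.n_channels,))
        pi_img = Image(J_l.grid, pi_m)
        pi_A = interpolate(pi_img, back).reshape(grid.shape)
        inside = J_l.grid.contains(back).reshape(grid.shape)
        pi_A = pi_A * inside
        detM = abs(np.linalg.det(Minv.linear))
        preds = []
        for t in range(v.nt):
            IDt = interpolate(I_l, fl.phi_inv_t[t].values)
            preds.append(F.transform_image(Image(grid, IDt)))
        g = matching_gradient(
            v, fl, preds, Image(grid, J_A), pi_A * detM,
            self.sigma_r, self.sigma_m, A_op, smoothed=True, taper=taper,
        )
        return g

    def _affine_gradient(self, J_l, pred, ID, grid, M, pi_m, F):
        tgt_coords = J_l.grid.coordinate_array().reshape(-1, grid.ndim)
        pts = M(tgt_coords)
        P = F.transform_image(Image(grid, ID))
        from .grids import spatial_gradient

        GP = spatial_gradient(P)  # (*grid, C, ndim)
        C = P.n_channels
        Gflat = GP.reshape(grid.shape + (C * grid.ndim,))
        Gsamp = interpolate(Image(grid, Gflat), pts).reshape(
            -1, C, grid.ndim
        )
        resid = (pred.values - J_l.values).reshape(-1, C)
        w = pi_m.reshape(-1) / self.sigma_m**2 * J_l.grid.voxel_volume
        r = np.einsum("nc,ncd->nd", resid, Gsamp) * w[:, None]
        xc = tgt_coords - M.center
        g_l = r.T @ xc
        g_t = r.sum(axis=0)
        # normalize by problem size so steps are resolution-independent
        npix = len(w)
        return g_l / npix, g_t / npix

    def _finalize(self, atlas, target, v, M):
        model, F, post, pred, converged = self._level_state
        fl = flow(v)
        self.velocity_ = v
        self.flow_ = fl
        self.phi_ = fl.phi
        self.phi_inv_ = fl.phi_inv
        self.affine_target_to_atlas_ = M
        self.affine_ = M.inverse().matrix()  # atlas -> target, homogeneous
        self.contrast_ = F
        self.posteriors_ = post
        self.mixture_ = model
        self.converged_ = bool(converged)
        self.atlas_grid_ = atlas.grid
        self.target_grid_ = target.grid
        self.prediction_ = pred

    # ------------------------------------------------------------------
    def map_target_to_atlas(self, points: np.ndarray) -> np.ndarray:
        """Total pullback phi^{-1}(A^{-1} x) at target-space world points."""
        self._check_fitted()
        pts = self.affine_target_to_atlas_(np.asarray(points, float))
        return interpolate(self.phi_inv_.as_image(), pts)

    def map_atlas_to_target(self, points: np.ndarray) -> np.ndarray:
        """Forward map A(phi(y)) at atlas-space world points."""
        self._check_fitted()
        moved = interpolate(self.phi_.as_image(), np.asarray(points, float))
        return self.affine_target_to_atlas_.inverse()(moved)

    def transform(self, img: Image, grid: ImageGrid = None,
                  order: int = 1) -> Image:
        """Resample an atlas-space image into target space.

        ``order=0`` gives nearest-neighbor sampling (label images).
        """
        self._check_fitted()
        grid = self.target_grid_ if grid is None else grid
        pts = self.map_target_to_atlas(
            grid.coordinate_array().reshape(-1, grid.ndim)
        )
        vals = interpolate(img, pts, order=order)
        return Image(grid, vals.reshape(grid.shape + (img.n_channels,)))

    def _check_fitted(self):
        if not hasattr(self, "phi_"):
            raise AttributeError("EMLDDMMRegistration is not fitted")


# ----------------------------------------------------------------------
def register(atlas: Image, target: Image, **config) -> EMLDDMMRegistration:
    """Fit the full EM registration (mixture classes enabled by default)."""
    return EMLDDMMRegistration(**config).fit(atlas, target)


def register_contrast_only(atlas: Image, target: Image,
                           **config) -> EMLDDMMRegistration:
    """Registration with the E-step disabled (pi_M = 1 everywhere)."""
    config = dict(config)
    config["classes"] = (mx.MATCHING,)
    return EMLDDMMRegistration(**config).fit(atlas, target)


def landmark_tre(points_moving: np.ndarray, points_fixed: np.ndarray,
                 transform_fn, image_diagonal: float) -> float:
    """Mean landmark distance error divided by the fixed-image diagonal.

    ``transform_fn`` maps moving-space points into fixed space (pass
    ``lambda p: p`` for the unregistered baseline).
    """
    pm = np.atleast_2d(np.asarray(points_moving, float))
    pf = np.atleast_2d(np.asarray(points_fixed, float))
    if pm.shape != pf.shape:
        raise ValueError("landmark sets must have equal shapes")
    if pm.shape[0] == 0:
        raise ValueError("no landmarks given")
    if image_diagonal <= 0:
        raise ValueError("image diagonal must be positive")
    moved = np.atleast_2d(np.asarray(transform_fn(pm), float))
    d = np.linalg.norm(moved - pf, axis=1)
    return float(d.mean() / image_diagonal)


def dice(label_a: np.ndarray, label_b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); two empty masks give 0."""
    a = np.asarray(label_a).astype(bool)
    b = np.asarray(label_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
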