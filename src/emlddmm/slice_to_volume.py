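"""Volume-to-slice-stack registration and tau-density quantification.

Histology sections are sparse (e.g. 1 x 1 x 1000 micron sampling), each with
its own position on the microscope slide and its own stain contrast.  The
transform chain mapping a pixel of slice ``i`` into volume (atlas)
coordinates composes, in order:

1. a per-slice 2D rigid motion (slide placement),
2. the scale/embedding into 3D at the slice's section coordinate z_i
   (slice spacing and pixel size),
3. a shared 3D rigid motion,
4. a shared 3D diffeomorphism (pullback through phi^{-1}).

All rigid, scale and deformation parameters are optimized jointly by
gradient descent — the chain is a composition, so gradients follow from the
chain rule — while each slice keeps its own polynomial contrast transform
and its own class posteriors (EM as in the 2D case).  Slices whose
matching-class fraction falls below a threshold are excluded from the
shared-parameter gradients for that cycle, so fully failed sections cannot
drive the 3D pose.

Quantification: per-slice tangle-density maps are resampled into atlas
coordinates through the fitted chain, and tangle area is tabulated per
(anatomical structure, atlas page).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import mixture as mx
from .contrast import PolynomialContrast
from .deformation import (
    SobolevOperator,
    Transform,
    VelocityField,
    flow,
    taper_margin,
)
from .grids import Image, ImageGrid, interpolate, spatial_gradient
from .registration import AffineMap, project_rotation


@dataclass
class SliceStack:
    """Ordered 2D sections with strictly increasing section coordinates."""

    images: list  # of 2D Image
    z: np.ndarray  # (n_slices,) physical section coordinate

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if len(self.images) == 0:
            raise ValueError("slice stack is empty")
        if len(self.images) != len(self.z):
            raise ValueError("one z per slice required")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("slice coordinates z must be strictly increasing")
        for im in self.images:
            if im.grid.ndim != 2:
                raise ValueError("stack entries must be 2D images")

    def __len__(self):
        return len(self.images)


def rot2(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])


class TransformChain:
    """Composition mapping slice pixels to volume coordinates and back.

    Components: per-slice 2D rigid (angle, shift about the slice center),
    in-plane scale, shared 3D rigid (AffineMap), shared diffeomorphism
    (``Flow`` or None).  The volume axis order is (z, row, col): a slice's
    2D coordinates land on the (row, col) axes at its z.
    """

    def __init__(self, z, slice_centers, scale_xy: float = 1.0,
                 rigid3d: AffineMap = None, flow3d=None):
        self.z = np.asarray(z, dtype=float)
        n = len(self.z)
        self.angles = np.zeros(n)
        self.shifts = np.zeros((n, 2))
        self.slice_centers = np.asarray(slice_centers, dtype=float)
        self.scale_xy = float(scale_xy)
        self.rigid3d = rigid3d or AffineMap.identity(3)
        self.flow3d = flow3d  # deformation.Flow or None
        self.fitted = False

    # -- forward: slice pixel -> atlas ---------------------------------
    def slice_to_volume_affine(self, i: int, pts2d: np.ndarray) -> np.ndarray:
        """Chain through the affine components only (no diffeomorphism)."""
        pts2d = np.asarray(pts2d, dtype=float)
        c = self.slice_centers[i]
        p = (pts2d - c) @ rot2(self.angles[i]).T + c + self.shifts[i]
        p = c + self.scale_xy * (p - c)
        q = np.concatenate(
            [np.full(p.shape[:-1] + (1,), self.z[i]), p], axis=-1
        )
        return self.rigid3d(q)

    def map_slice_points(self, i: int, pts2d: np.ndarray) -> np.ndarray:
        """Full pullback of slice-i pixel coordinates into atlas coordinates."""
        r = self.slice_to_volume_affine(i, pts2d)
        if self.flow3d is None:
            return r
        return interpolate(self.flow3d.phi_inv.as_image(), r)

    # -- inverse: atlas voxel -> slice plane ---------------------------
    def map_volume_points(self, pts3d: np.ndarray) -> np.ndarray:
        """Inverse chain: atlas points to (z', row', col') stack coordinates.

        z' is the continuous section coordinate; (row', col') are in-plane
        world coordinates *before* the per-slice rigid motions (those are
        applied per slice by :meth:`volume_to_slice`).
        """
        pts3d = np.asarray(pts3d, dtype=float)
        if self.flow3d is not None:
            pts3d = interpolate(self.flow3d.phi.as_image(), pts3d)
        return self.rigid3d.inverse()(pts3d)

    def volume_to_slice(self, i: int, pts3d: np.ndarray) -> np.ndarray:
        """In-plane slice-i pixel coordinates of atlas points (2D)."""
        q = self.map_volume_points(pts3d)
        c = self.slice_centers[i]
        p = c + (q[..., 1:] - c) / self.scale_xy
        return (p - c - self.shifts[i]) @ rot2(self.angles[i]) + c


class VolumeSliceRegistration(BaseEstimator):
    """Joint EM registration of a 3D volume to a sparse 2D slice stack.

    Each slice carries its own separable polynomial contrast transform and
    its own posteriors; the 3D rigid pose (and optional shared
    diffeomorphism) plus the per-slice 2D rigid motions are optimized
    jointly by gradient descent on the summed weighted matching objective.

    Parameters mirror :class:`~emlddmm.registration.EMLDDMMRegistration`
    where they share meaning.  ``deform`` enables the shared diffeomorphism
    (the velocity gradient deposits per-slice residual forces into the
    volume and smooths them with the Sobolev kernel); it is refined after
    the rigid components, which dominate for sparse stacks.

    Attributes
    ----------
    chain_ : TransformChain
    contrasts_ : list of per-slice PolynomialContrast
    posteriors_ : list of per-slice mixture.ClassPosteriors
    objective_trace_ : list of per-iteration records
    """

    def __init__(self, sigma_m=0.1, sigma_a=None, sigma_b=None, sigma_r=5.0,
                 a=6.0, p=2.0, order=3, contrast_mode="separable",
                 classes=(mx.MATCHING, mx.BACKGROUND), nt=3, deform=False,
                 n_em=5, n_iter=30, step_angle=0.02, step_shift=0.5,
                 step_v=0.1, min_matching_fraction=0.05, tol=1e-5):
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
        self.deform = deform
        self.n_em = n_em
        self.n_iter = n_iter
        self.step_angle = step_angle
        self.step_shift = step_shift
        self.step_v = step_v
        self.min_matching_fraction = min_matching_fraction
        self.tol = tol

    # ------------------------------------------------------------------
    def fit(self, volume: Image, stack: SliceStack):
        if volume.grid.ndim != 3:
            raise ValueError("volume must be 3D")
        if len(stack) == 0:
            raise ValueError("slice stack is empty")
        self.volume_ = volume
        centers = np.array(
            [
                [
                    o + (n - 1) / 2.0 * d
                    for n, d, o in zip(im.grid.shape, im.grid.spacing,
                                       im.grid.origin)
                ]
                for im in stack.images
            ]
        )
        chain = TransformChain(stack.z, centers)
        nslc = len(stack)
        sigma_a = 5.0 * self.sigma_m if self.sigma_a is None else self.sigma_a
        sigma_b = 5.0 * self.sigma_m if self.sigma_b is None else self.sigma_b
        models = [
            mx.MixtureModel.from_target(
                im, classes=tuple(self.classes), sigma_m=self.sigma_m,
                sigma_a=sigma_a, sigma_b=sigma_b,
            )
            for im in stack.images
        ]
        Fs = [
            PolynomialContrast(order=self.order, mode=self.contrast_mode)
            for _ in range(nslc)
        ]
        use_em = len(self.classes) > 1
        v = VelocityField.zeros(volume.grid, self.nt) if self.deform else None
        A_op = (
            SobolevOperator(volume.grid, self.a, self.p) if self.deform else None
        )
        taper = taper_margin(volume.grid, 2) if self.deform else None
        pts2d = [
            im.grid.coordinate_array().reshape(-1, 2) for im in stack.images
        ]
        J_flat = [
            im.values.reshape(-1, im.n_channels) for im in stack.images
        ]
        pis = [np.ones(len(p)) for p in pts2d]
        self.objective_trace_ = []

        def slice_pred(i):
            pts = chain.map_slice_points(i, pts2d[i])
            X = interpolate(volume, pts)
            return pts, X

        def total_objective():
            tot = 0.0
            for i in range(nslc):
                _, X = slice_pred(i)
                r = Fs[i].transform(X) - J_flat[i]
                tot += 0.5 / self.sigma_m**2 * float(
                    np.sum(pis[i] * np.sum(r**2, axis=1))
                ) * stack.images[i].grid.voxel_volume
            if v is not None:
                from .deformation import regularization_energy

                tot += regularization_energy(v, A_op, self.sigma_r)
            return tot

        eps_fd = 0.25 * min(volume.grid.spacing)
        for cycle in range(self.n_em):
            # E-step and closed-form per-slice updates
            for i in range(nslc):
                _, X = slice_pred(i)
                Fs[i].fit(X, J_flat[i], sample_weight=pis[i] if use_em else None)
                if use_em:
                    pred = Image(
                        stack.images[i].grid,
                        Fs[i].transform(X).reshape(
                            stack.images[i].grid.shape + (-1,)
                        ),
                    )
                    post = mx.e_step(stack.images[i], pred, models[i])
                    pis[i] = post.matching.reshape(-1)
                    mx.update_class_means(stack.images[i], post, models[i])
            obj = total_objective()
            sa, ss, st3, sl3 = (self.step_angle, self.step_shift,
                                self.step_shift, self.step_angle)
            sv = self.step_v
            scale0 = None
            for it in range(self.n_iter):
                g_ang = np.zeros(nslc)
                g_shift = np.zeros((nslc, 2))
                g_L = np.zeros((3, 3))
                g_T = np.zeros(3)
                g_v = np.zeros_like(v.values) if v is not None else None
                share_ok = []
                for i in range(nslc):
                    pts, X = slice_pred(i)
                    P = Fs[i].transform(X)
                    resid = P - J_flat[i]
                    w = pis[i] / self.sigma_m**2 * (
                        stack.images[i].grid.voxel_volume
                    )
                    # dF/dX (diagonal per channel for separable; full jac
                    # approximated by finite differences of F)
                    gI = self._volume_gradient(pts)
                    dF = self._contrast_jacobian(Fs[i], X)
                    # chain: dP/dy = dF/dX * dX/dy, dX/dy = grad I at y
                    # force on the 3D point: (n, 3)
                    rC = np.einsum("nc,nck->nk", resid, dF)  # (n, Cin)
                    force = np.einsum("nk,nkd->nd", rC, gI) * w[:, None]
                    # Jacobian of the diffeo pullback at the affine points
                    r_aff = chain.slice_to_volume_affine(i, pts2d[i])
                    if chain.flow3d is not None:
                        Dphi = self._map_jacobian(
                            chain.flow3d.phi_inv, r_aff, eps_fd
                        )
                        force_aff = np.einsum("nd,ndk->nk", force, Dphi)
                    else:
                        force_aff = force
                    # 3D rigid: r = R q + c-form via AffineMap
                    q = np.concatenate(
                        [
                            np.full((len(pts2d[i]), 1), chain.z[i]),
                            chain.slice_centers[i]
                            + chain.scale_xy
                            * (
                                (pts2d[i] - chain.slice_centers[i])
                                @ rot2(chain.angles[i]).T
                                + chain.shifts[i]
                            ),
                        ],
                        axis=1,
                    )
                    qc = q - chain.rigid3d.center
                    g_L += force_aff.T @ qc
                    g_T += force_aff.sum(axis=0)
                    # per-slice 2D rigid: in-plane force back through R3
                    f2 = force_aff @ chain.rigid3d.linear
                    f2 = f2[:, 1:] * chain.scale_xy
                    dR = rot2(chain.angles[i] + np.pi / 2.0)
                    xc = pts2d[i] - chain.slice_centers[i]
                    g_ang[i] = float(np.sum(f2 * (xc @ dR.T)))
                    g_shift[i] = f2.sum(axis=0)
                    frac = float(np.mean(pis[i] > 0.5))
                    share_ok.append(frac >= self.min_matching_fraction)
                    if v is not None and share_ok[-1]:
                        # deposit residual force at mapped coordinates
                        self._splat(g_v, pts, force, volume.grid)
                    if not share_ok[-1]:
                        # damaged slice: exclude from shared 3D gradients
                        g_L -= force_aff.T @ qc
                        g_T -= force_aff.sum(axis=0)
                npix = sum(len(p) for p in pts2d)
                g_L /= npix
                g_T /= npix
                if v is not None:
                    g_v = v.values / self.sigma_r**2 + np.stack(
                        [A_op.smooth(-g_v[t]) for t in range(self.nt)]
                    )
                    g_v *= taper[None, ..., None]
                if scale0 is None:
                    scale0 = (
                        1.0 / max(np.abs(g_ang).max(), 1e-12),
                        1.0 / max(np.abs(g_shift).max(), 1e-12),
                        1.0 / max(np.abs(g_L).max(), 1e-12),
                        1.0 / max(np.abs(g_T).max(), 1e-12),
                        1.0 / max(np.abs(g_v).max(), 1e-12)
                        if v is not None
                        else 1.0,
                    )
                accepted = False
                state = (
                    chain.angles.copy(), chain.shifts.copy(),
                    chain.rigid3d.copy(),
                    None if v is None else v.values.copy(),
                )
                for _ in range(10):
                    chain.angles = state[0] - sa * scale0[0] * g_ang
                    chain.shifts = state[1] - ss * scale0[1] * g_shift
                    L = state[2].linear - sl3 * scale0[2] * g_L
                    chain.rigid3d = AffineMap(
                        project_rotation(L),
                        state[2].translation - st3 * scale0[3] * g_T,
                        state[2].center,
                    )
                    if v is not None:
                        v = VelocityField(
                            volume.grid, state[3] - sv * scale0[4] * g_v
                        )
                        chain.flow3d = flow(v)
                    obj_try = total_objective()
                    if obj_try <= obj or np.isclose(obj_try, obj):
                        accepted = True
                        break
                    sa *= 0.5
                    ss *= 0.5
                    st3 *= 0.5
                    sl3 *= 0.5
                    sv *= 0.5
                if not accepted:
                    chain.angles, chain.shifts = state[0], state[1]
                    chain.rigid3d = state[2]
                    if v is not None:
                        v = VelocityField(volume.grid, state[3])
                        chain.flow3d = flow(v)
                    break
                self.objective_trace_.append(
                    {"cycle": cycle, "iter": it, "total": obj_try}
                )
                if abs(obj - obj_try) / max(abs(obj), 1e-12) < self.tol:
                    obj = obj_try
                    break
                obj = obj_try
        chain.fitted = True
        self.chain_ = chain
        self.contrasts_ = Fs
        self.models_ = models
        posts = []
        for i in range(nslc):
            _, X = slice_pred(i)
            pred = Image(
                stack.images[i].grid,
                Fs[i].transform(X).reshape(stack.images[i].grid.shape + (-1,)),
            )
            if use_em:
                posts.append(mx.e_step(stack.images[i], pred, models[i]))
            else:
                posts.append(
                    mx.ClassPosteriors(
                        stack.images[i].grid,
                        {mx.MATCHING: np.ones(stack.images[i].grid.shape)},
                    )
                )
        self.posteriors_ = posts
        self.stack_ = stack
        return self

    # -- helpers -------------------------------------------------------
    def _volume_gradient(self, pts):
        if not hasattr(self, "_vol_grad_img"):
            G = spatial_gradient(self.volume_)  # (*shape, C, 3)
            self._vol_grad_img = Image(
                self.volume_.grid,
                G.reshape(self.volume_.grid.shape + (-1,)),
            )
            self._vol_grad_channels = G.shape[-2]
        g = interpolate(self._vol_grad_img, pts)
        return g.reshape(len(pts), self._vol_grad_channels, 3)

    @staticmethod
    def _contrast_jacobian(F, X, eps=1e-4):
        """dF/dX by central differences; (n, M, N)."""
        n, N = X.shape
        cols = []
        for k in range(N):
            Xp = X.copy()
            Xp[:, k] += eps
            Xm = X.copy()
            Xm[:, k] -= eps
            cols.append((F.transform(Xp) - F.transform(Xm)) / (2 * eps))
        return np.stack(cols, axis=-1)  # (n, M, N)

    @staticmethod
    def _map_jacobian(T: Transform, pts: np.ndarray, eps: float) -> np.ndarray:
        """Finite-difference Jacobian of a stored map at points; (n, 3, 3)."""
        n = len(pts)
        J = np.zeros((n, 3, 3))
        img = T.as_image()
        for k in range(3):
            dp = np.zeros(3)
            dp[k] = eps
            J[:, :, k] = (
                interpolate(img, pts + dp) - interpolate(img, pts - dp)
            ) / (2 * eps)
        return J

    @staticmethod
    def _splat(g_v, pts, force, grid: ImageGrid):
        """Nearest-voxel deposit of per-pixel forces into the velocity grad."""
        idx = np.rint(grid.world_to_index(pts)).astype(int)
        ok = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
        idx = idx[ok]
        f = force[ok] / grid.voxel_volume
        for t in range(g_v.shape[0]):
            np.add.at(
                g_v[t], (idx[:, 0], idx[:, 1], idx[:, 2]), -f
            )

    def _check_fitted(self):
        if not hasattr(self, "chain_"):
            raise AttributeError("VolumeSliceRegistration is not fitted")


def register_volume_to_stack(volume: Image, stack: SliceStack,
                             **config) -> VolumeSliceRegistration:
    return VolumeSliceRegistration(**config).fit(volume, stack)


def map_detections_to_atlas(densities: list, chain: TransformChain,
                            atlas_grid: ImageGrid, z_tol: float = None
                            ) -> Image:
    """Resample per-slice density maps into atlas coordinates.

    Each atlas voxel is mapped through the chain inverse; voxels whose
    continuous section coordinate lies within ``z_tol`` (default: half the
    median slice gap) of a slice plane sample that slice's density; voxels
    with no slice support are NaN (missing, not zero).
    """
    if not getattr(chain, "fitted", False):
        raise ValueError("transform chain is not fitted")
    z = chain.z
    if z_tol is None:
        z_tol = 0.5 * float(np.median(np.diff(z))) if len(z) > 1 else np.inf
    out = np.full(atlas_grid.shape, np.nan)
    pts3d = atlas_grid.coordinate_array().reshape(-1, 3)
    q = chain.map_volume_points(pts3d)
    zq = q[:, 0]
    for i, zi in enumerate(z):
        sel = np.abs(zq - zi) <= z_tol
        if not sel.any():
            continue
        p2 = chain.volume_to_slice(i, pts3d[sel])
        inside = densities[i].grid.contains(p2)
        vals = interpolate(densities[i], p2)[:, 0]
        vals[~inside] = np.nan
        flat = out.reshape(-1)
        prev = flat[sel]
        take = ~np.isnan(vals)
        prev[take] = vals[take]
        flat[sel] = prev
    return Image(atlas_grid, out, allow_missing=True)


def tabulate_tau(density3d: Image, labels: Image, pixel_area: float,
                 pages=None) -> pd.DataFrame:
    """Per-(structure, page) tangle area, structure area and area fraction.

    ``density3d`` holds per-voxel tangle density in [0, 1] (NaN = no slice
    support); ``labels`` an integer structure map on the same grid; pages
    are z world coordinates binned to the nearest page plane.  Areas are in
    ``pixel_area`` units; an unsupported (0/0) fraction is reported as NaN.
    """
    if density3d.grid.shape != labels.grid.shape:
        raise ValueError("density and labels must share a grid")
    if pixel_area <= 0:
        raise ValueError("pixel_area must be positive")
    dens = density3d.scalar()
    lab = labels.scalar().astype(int)
    zc = density3d.grid.axis_coordinates()[0]
    if pages is None:
        pages = zc
    pages = np.asarray(pages, dtype=float)
    page_of_plane = pages[
        np.argmin(np.abs(zc[:, None] - pages[None, :]), axis=1)
    ]
    rows = []
    for s in sorted(np.unique(lab)):
        if s == 0:
            continue
        for pg in pages:
            planes = np.where(page_of_plane == pg)[0]
            m = np.zeros_like(lab, dtype=bool)
            m[planes] = lab[planes] == s
            supported = m & ~np.isnan(dens)
            tangle = float(np.nansum(dens[supported]) * pixel_area)
            area = float(m.sum() * pixel_area)
            frac = tangle / area if area > 0 else np.nan
            rows.append(
                {
                    "structure": s,
                    "page_z": float(pg),
                    "tangle_area": tangle,
                    "structure_area": area,
                    "fraction": frac,
                }
            )
    return pd.DataFrame(rows)
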