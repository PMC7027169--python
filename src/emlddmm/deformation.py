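"""Velocity-field flows, the Sobolev operator, and the LDDMM matching gradient.

The deformation model is the flow of a time-varying velocity field,

    d/dt phi_t = v_t(phi_t),   phi_0 = id,   phi = phi_1,

with the velocity penalized by the Sobolev quadratic form <A v, v> where
A = (id - a^2 Laplacian)^p.  A is applied in the frequency domain with the
periodic discrete-Laplacian symbol; K = A^{-1} smooths gradients into the
Hilbert space of admissible velocities (Beg-style preconditioned descent).

Transforms are stored as *destination world coordinates* per voxel (not
displacements), so composition is plain interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import Image, ImageGrid, interpolate, spatial_gradient


@dataclass
class Transform:
    """A spatial map stored as per-voxel destination world coordinates.

    ``values`` has shape ``(*grid.shape, ndim)``: ``values[k] = T(x_k)`` in
    world units.  Can hold phi, phi^{-1}, or any composition.
    """

    grid: ImageGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        expected = self.grid.shape + (self.grid.ndim,)
        if values.shape != expected:
            raise ValueError(f"transform values shape {values.shape} != {expected}")
        if not np.all(np.isfinite(values)):
            raise ValueError("transform values must be finite")
        self.values = values

    @classmethod
    def identity(cls, grid: ImageGrid) -> "Transform":
        return cls(grid, grid.coordinate_array())

    def as_image(self) -> Image:
        return Image(self.grid, self.values)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Evaluate the map at world points (multilinear, clamped)."""
        return interpolate(self.as_image(), points)

    def compose(self, other: "Transform") -> "Transform":
        """Return self∘other on other's grid: x -> self(other(x))."""
        return Transform(other.grid, self(other.values))

    def displacement(self) -> np.ndarray:
        return self.values - self.grid.coordinate_array()


@dataclass
class VelocityField:
    """Time-indexed velocity field, shape ``(nt, *grid.shape, ndim)``."""

    grid: ImageGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != self.grid.ndim + 2 or values.shape[-1] != self.grid.ndim:
            raise ValueError(
                f"velocity values must have shape (nt, *shape, ndim); got {values.shape}"
            )
        if values.shape[1:-1] != self.grid.shape:
            raise ValueError("velocity spatial shape does not match grid")
        if values.shape[0] < 1:
            raise ValueError("nt must be >= 1")
        if not np.all(np.isfinite(values)):
            raise ValueError("velocity values must be finite")
        self.values = values

    @classmethod
    def zeros(cls, grid: ImageGrid, nt: int) -> "VelocityField":
        return cls(grid, np.zeros((nt,) + grid.shape + (grid.ndim,)))

    @property
    def nt(self) -> int:
        return self.values.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.nt


class SobolevOperator:
    """Frequency-domain realization of A = (id - a^2 Laplacian)^p.

    The multiplier uses the periodic discrete Laplacian symbol

        Ahat(f) = (1 + a^2 * sum_d 2 (1 - cos(2 pi f_d h_d)) / h_d^2)^p

    so Ahat(0) = 1 and Ahat >= 1 everywhere.  ``apply`` multiplies by Ahat
    per vector component; ``smooth`` divides (K = A^{-1}).
    """

    def __init__(self, grid: ImageGrid, a: float, p: float = 4.0):
        if a < 0:
            raise ValueError(f"length scale a must be >= 0, got {a}")
        if p < 1:
            raise ValueError(f"operator power p must be >= 1, got {p}")
        self.grid = grid
        self.a = float(a)
        self.p = float(p)
        sym = np.zeros(grid.shape)
        for d, (n, h) in enumerate(zip(grid.shape, grid.spacing)):
            f = np.fft.fftfreq(n, d=h)
            term = 2.0 * (1.0 - np.cos(2.0 * np.pi * f * h)) / h**2
            shape = [1] * grid.ndim
            shape[d] = n
            sym = sym + term.reshape(shape)
        self.multiplier = (1.0 + self.a**2 * sym) ** self.p

    def _filter(self, values: np.ndarray, mult: np.ndarray) -> np.ndarray:
        axes = tuple(range(self.grid.ndim))
        fhat = np.fft.fftn(values, axes=axes)
        fhat *= mult[..., None] if values.ndim == self.grid.ndim + 1 else mult
        return np.real(np.fft.ifftn(fhat, axes=axes))

    def apply(self, values: np.ndarray) -> np.ndarray:
        """A applied per component; accepts (*shape,) or (*shape, k)."""
        return self._filter(np.asarray(values, dtype=float), self.multiplier)

    def smooth(self, values: np.ndarray) -> np.ndarray:
        """K = A^{-1} applied per component."""
        return self._filter(np.asarray(values, dtype=float), 1.0 / self.multiplier)


def make_operator(grid: ImageGrid, a: float, p: float = 4.0) -> SobolevOperator:
    return SobolevOperator(grid, a, p)


def taper_margin(grid: ImageGrid, width: int = 2) -> np.ndarray:
    """Multiplicative taper that ramps to zero in a `width`-voxel margin.

    The FFT realization of A is periodic; tapering velocities near the edge
    suppresses wrap-around coupling of opposite boundaries.
    """
    taper = np.ones(grid.shape)
    for d, n in enumerate(grid.shape):
        ramp = np.ones(n)
        w = min(width, (n - 1) // 2)
        if w > 0:
            edge = np.linspace(0.0, 1.0, w + 1)[:-1]
            ramp[:w] = edge
            ramp[-w:] = edge[::-1]
        shape = [1] * grid.ndim
        shape[d] = n
        taper = taper * ramp.reshape(shape)
    return taper


@dataclass
class Flow:
    """Flow integration products needed by the objective and its gradient.

    Attributes
    ----------
    phi : Transform
        Forward map phi_1.
    phi_inv : Transform
        Inverse map phi_1^{-1}.
    phi_inv_t : list of Transform
        phi_t^{-1} for t = 0..nt (phi_inv_t[0] is the identity).
    psi_t : list of Transform
        phi_1t^{-1} = phi_1 o phi_t^{-1} for t = 0..nt (psi_t[nt] is the
        identity); this is the map transporting the matching residual back
        to time t in the gradient.
    """

    phi: Transform
    phi_inv: Transform
    phi_inv_t: list
    psi_t: list


def flow(v: VelocityField) -> Flow:
    """Integrate the flow ODE with forward-Euler / semi-Lagrangian updates.

    Forward map:  phi_{t+dt}(x) = phi_t(x) + dt * v_t(phi_t(x)).
    Inverse map:  phi_{t+dt}^{-1}(x) = phi_t^{-1}(x - dt * v_t(x)).
    Residual transport (backward from t=1):
                  psi_t(x) = psi_{t+dt}(x + dt * v_t(x)),  psi_1 = id.
    """
    grid = v.grid
    dt = v.dt
    ident = grid.coordinate_array()
    phi = ident.copy()
    phi_inv = ident.copy()
    phi_inv_t = [Transform(grid, ident.copy())]
    for t in range(v.nt):
        vt_img = Image(grid, v.values[t])
        phi = phi + dt * interpolate(vt_img, phi)
        phi_inv = interpolate(Image(grid, phi_inv), ident - dt * v.values[t])
        phi_inv_t.append(Transform(grid, phi_inv.copy()))
    psi = ident.copy()
    psi_t = [None] * (v.nt + 1)
    psi_t[v.nt] = Transform(grid, psi.copy())
    for t in range(v.nt - 1, -1, -1):
        psi = interpolate(Image(grid, psi), ident + dt * v.values[t])
        psi_t[t] = Transform(grid, psi.copy())
    return Flow(
        phi=Transform(grid, phi),
        phi_inv=Transform(grid, phi_inv),
        phi_inv_t=phi_inv_t,
        psi_t=psi_t,
    )


def jacobian_determinant(T: Transform) -> Image:
    """Determinant of the finite-difference Jacobian of the map, per voxel."""
    grid = T.grid
    if any(n < 2 for n in grid.shape):
        raise ValueError("jacobian_determinant requires >= 2 samples per axis")
    grads = np.gradient(T.values, *grid.spacing, axis=tuple(range(grid.ndim)))
    # J[..., i, j] = d T_i / d x_j
    J = np.stack(grads, axis=-1)
    det = np.linalg.det(J)
    return Image(grid, det)


def regularization_energy(v: VelocityField, A: SobolevOperator,
                          sigma_r: float) -> float:
    """(1 / 2 sigma_R^2) * sum_t dt * sum_x <A v_t, v_t> * voxel volume."""
    if sigma_r <= 0:
        raise ValueError(f"sigma_r must be > 0, got {sigma_r}")
    total = 0.0
    for t in range(v.nt):
        Avt = A.apply(v.values[t])
        total += float(np.sum(Avt * v.values[t]))
    return 0.5 / sigma_r**2 * total * v.dt * v.grid.voxel_volume


def matching_gradient(
    v: VelocityField,
    fl: Flow,
    deformed_pred: list,
    target: Image,
    pi_m: np.ndarray,
    sigma_r: float,
    sigma_m: float,
    A: SobolevOperator,
    smoothed: bool = True,
    taper: np.ndarray | None = None,
) -> np.ndarray:
    """Per-timestep gradient of the weighted objective with respect to v.

    Implements the optimality condition of the weighted matching problem:

        grad_t = (1/sigma_R^2) A v_t
                 - (1/sigma_M^2) sum_c grad[D_t]_c (D_t - J o psi_t)_c
                   |D psi_t| (pi_M o psi_t)

    where ``D_t = F_theta(I o phi_t^{-1})`` is supplied per timestep in
    ``deformed_pred`` and ``psi_t = phi_1 o phi_t^{-1}`` transports the
    residual back to time t.  With ``smoothed=True`` (the default used for
    descent) the matching part is convolved with K = A^{-1} and the
    regularization part reduces to v_t / sigma_R^2, i.e. the Hilbert-space
    gradient; with ``smoothed=False`` the raw density above is returned
    (suitable for finite-difference verification).
    """
    grid = v.grid
    if len(deformed_pred) != v.nt:
        raise ValueError("need one deformed prediction per timestep")
    pi_img = Image(target.grid, pi_m)
    grad = np.zeros_like(v.values)
    for t in range(v.nt):
        Dt = deformed_pred[t]
        if Dt.grid.shape != grid.shape:
            raise ValueError("deformed prediction grid mismatch")
        psi = fl.psi_t[t]
        J_psi = interpolate(target, psi.values)
        pi_psi = interpolate(pi_img, psi.values)[..., 0]
        detpsi = jacobian_determinant(psi).scalar()
        gDt = spatial_gradient(Dt)  # (*shape, C, ndim)
        resid = Dt.values - J_psi  # (*shape, C)
        force = np.einsum("...cd,...c->...d", gDt, resid)
        force *= (detpsi * pi_psi)[..., None]
        force /= -(sigma_m**2)
        if smoothed:
            grad[t] = v.values[t] / sigma_r**2 + A.smooth(force)
            if taper is not None:
                # zero the update in the margin *after* smoothing so the
                # velocity stays exactly zero there (FFT wrap-around guard;
                # flows then fix the boundary pointwise)
                grad[t] *= taper[..., None]
        else:
            grad[t] = A.apply(v.values[t]) / sigma_r**2 + force
            if taper is not None:
                grad[t] *= taper[..., None]
    return grad
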