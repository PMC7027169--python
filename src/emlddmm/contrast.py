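"""Polynomial intensity transforms F_theta and their weighted estimation.

Cross-modality matching is achieved by letting the deformed atlas pass
through a polynomial map of its intensities before comparison with the
target.  Polynomials of order >= 2 are non-monotonic, so they can *permute*
the ranking of tissue intensities (e.g. the gray/white brightness swap
between tau and myelin stains); order 1 reduces to an affine contrast map,
equivalent to normalized cross-correlation (see
:func:`ncc_equivalent_matching_term`).

Two basis modes:

* ``full`` — all cross-channel monomials of total degree <= O; an R^N -> R^M
  map has C(N+O, O) coefficients per output channel (a full cubic
  R^3 -> R^3 map has 20 x 3 = 60 parameters);
* ``separable`` — an independent univariate polynomial per channel
  (requires N == M; a separable cubic RGB map has 4 x 3 = 12 parameters).

The weighted least-squares problem posed by the M-step is solved in closed
form via the normal equations.  For conditioning of cubic Vandermonde
systems, intensities are standardized (weighted zero mean / unit variance)
before the basis is built and the coefficients are mapped back to original
units afterwards, so the reported theta always applies to raw intensities.
"""

from __future__ import annotations

from itertools import combinations_with_replacement

import numpy as np
from sklearn.base import BaseEstimator

from .grids import Image


def monomial_exponents(n_channels: int, order: int) -> np.ndarray:
    """Exponent rows for all monomials of total degree <= order (graded lex).

    Returns an integer array of shape (n_basis, n_channels); rows sorted by
    total degree, then lexicographically, so coefficient files are portable.
    """
    if order < 0:
        raise ValueError(f"order must be >= 0, got {order}")
    rows = []
    for deg in range(order + 1):
        degrows = []
        for combo in combinations_with_replacement(range(n_channels), deg):
            e = np.zeros(n_channels, dtype=int)
            for c in combo:
                e[c] += 1
            degrows.append(tuple(e))
        rows.extend(sorted(degrows, reverse=True))
    return np.array(rows, dtype=int).reshape(len(rows), n_channels)


def basis_matrix(values: np.ndarray, order: int, mode: str = "full") -> np.ndarray:
    """Design matrix for polynomial contrast fitting.

    Parameters
    ----------
    values : (n, N) array of input intensities.
    order : polynomial order O >= 0.
    mode : "full" or "separable".

    Returns
    -------
    ``full``: (n, C(N+O, O)) matrix, one column per monomial in graded-lex
    order.  ``separable``: (n, O+1, N) array, basis (1, x_c, ..., x_c^O) per
    channel c.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if order < 0:
        raise ValueError(f"order must be >= 0, got {order}")
    n, N = values.shape
    if mode == "full":
        expo = monomial_exponents(N, order)
        # column j = prod_c values[:, c] ** expo[j, c]
        return np.prod(values[:, None, :] ** expo[None, :, :], axis=2)
    if mode == "separable":
        powers = np.arange(order + 1)
        return values[:, None, :] ** powers[None, :, None]
    raise ValueError(f"unknown basis mode {mode!r}")


def n_basis(n_channels: int, order: int, mode: str = "full") -> int:
    if mode == "full":
        from math import comb

        return comb(n_channels + order, order)
    if mode == "separable":
        return order + 1
    raise ValueError(f"unknown basis mode {mode!r}")


def identity_coefficients(n_channels: int, order: int, mode: str = "full"):
    """theta reproducing the input exactly (requires N == M)."""
    if mode == "separable":
        theta = np.zeros((order + 1, n_channels))
        if order >= 1:
            theta[1, :] = 1.0
        return theta
    expo = monomial_exponents(n_channels, order)
    theta = np.zeros((len(expo), n_channels))
    for m in range(n_channels):
        unit = np.zeros(n_channels, dtype=int)
        unit[m] = 1
        j = int(np.where((expo == unit).all(axis=1))[0][0])
        theta[j, m] = 1.0
    return theta


def _shift_scale_1d(coeffs: np.ndarray, mean: float, scale: float) -> np.ndarray:
    """Coefficients of p((x - mean)/scale) in powers of x (ascending)."""
    # substitute via numpy polynomial composition
    p = np.polynomial.Polynomial(coeffs)
    sub = np.polynomial.Polynomial([-mean / scale, 1.0 / scale])
    comp = p(sub)
    out = np.zeros_like(coeffs)
    out[: len(comp.coef)] = comp.coef
    return out


def _destandardize_full(theta_std, expo, mean, scale, out_mean, out_scale):
    """Map coefficients fitted on standardized inputs/outputs to raw units.

    The fitted map is  J ~ out_mean + out_scale * sum_j theta[j] z^expo[j]
    with z_c = (x_c - mean_c) / scale_c.  Each standardized monomial expands
    into raw monomials of equal or lower degree via products of 1D binomial
    expansions; the result is re-expressed in the same graded-lex basis.
    """
    n_b, N = expo.shape
    M = theta_std.shape[1]
    theta = np.zeros_like(theta_std)
    index = {tuple(e): j for j, e in enumerate(expo)}
    for j, e in enumerate(expo):
        # expand prod_c ((x_c - m_c)/s_c)^e_c into raw monomials
        terms = {tuple(np.zeros(N, dtype=int)): 1.0}
        for c in range(N):
            if e[c] == 0:
                continue
            coeffs1d = np.zeros(e[c] + 1)
            coeffs1d[e[c]] = 1.0
            exp1d = _shift_scale_1d(coeffs1d, mean[c], scale[c])
            new_terms = {}
            for raw_e, w in terms.items():
                for k, ck in enumerate(exp1d):
                    if ck == 0.0:
                        continue
                    e2 = list(raw_e)
                    e2[c] += k
                    key = tuple(e2)
                    new_terms[key] = new_terms.get(key, 0.0) + w * ck
            terms = new_terms
        for raw_e, w in terms.items():
            theta[index[raw_e]] += w * theta_std[j]
    theta *= out_scale[None, :]
    const = tuple(np.zeros(N, dtype=int))
    theta[index[const]] += out_mean
    return theta


class PolynomialContrast(BaseEstimator):
    """Polynomial intensity transform fitted by weighted least squares.

    Parameters
    ----------
    order : int
        Polynomial order O >= 0.
    mode : {"full", "separable"}
        ``full`` uses all cross-channel monomials of total degree <= O;
        ``separable`` fits an independent univariate polynomial per channel.
    ridge : float
        Relative Tikhonov regularization: the normal matrix B'WB receives
        ``ridge * trace(B'WB) / n_cols`` on its diagonal.  The default 1e-6
        keeps the solve well-posed on (near-)constant images; set 0 for the
        exact least-squares solution.
    standardize : bool
        Standardize intensities (weighted) before building the basis and map
        the coefficients back to raw units afterwards.

    Attributes
    ----------
    theta_ : (n_basis, M) array
        Coefficients in raw intensity units, graded-lex monomial order
        (``full``) or ascending powers per channel (``separable``).
    exponents_ : (n_basis, N) int array (``full`` mode only).
    """

    def __init__(self, order: int = 1, mode: str = "full", ridge: float = 1e-6,
                 standardize: bool = True):
        self.order = order
        self.mode = mode
        self.ridge = ridge
        self.standardize = standardize

    # -- estimator API ------------------------------------------------------
    def fit(self, X, y, sample_weight=None):
        """Fit theta minimizing sum_i w_i |y_i - F_theta(X_i)|^2.

        X : (n, N) atlas (deformed) intensities; y : (n, M) target
        intensities; sample_weight : per-sample weights in [0, 1] (the
        matching posteriors pi_M), default all ones.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        n, N = X.shape
        M = y.shape[1]
        if y.shape[0] != n:
            raise ValueError("X and y disagree on sample count")
        if self.mode == "separable" and N != M:
            raise ValueError(
                f"separable mode requires equal channel counts, got N={N}, M={M}"
            )
        if sample_weight is None:
            w = np.ones(n)
        else:
            w = np.asarray(sample_weight, dtype=float).reshape(n)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        wsum = w.sum()
        if wsum <= 0:
            raise ValueError("no matching pixels: all weights are zero")

        if self.standardize:
            mean = (w @ X) / wsum
            var = (w @ (X - mean) ** 2) / wsum
            scale = np.sqrt(np.maximum(var, 1e-30))
            scale[scale < 1e-15] = 1.0
            out_mean = (w @ y) / wsum
            out_var = (w @ (y - out_mean) ** 2) / wsum
            out_scale = np.sqrt(np.maximum(out_var, 1e-30))
            out_scale[out_scale < 1e-15] = 1.0
        else:
            mean = np.zeros(N)
            scale = np.ones(N)
            out_mean = np.zeros(M)
            out_scale = np.ones(M)
        Xs = (X - mean) / scale
        ys = (y - out_mean) / out_scale

        if self.mode == "full":
            B = basis_matrix(Xs, self.order, "full")
            theta_std = self._solve(B, ys, w)
            self.exponents_ = monomial_exponents(N, self.order)
            if self.standardize:
                self.theta_ = _destandardize_full(
                    theta_std, self.exponents_, mean, scale, out_mean, out_scale
                )
            else:
                self.theta_ = theta_std
        else:
            B = basis_matrix(Xs, self.order, "separable")  # (n, O+1, N)
            theta = np.zeros((self.order + 1, M))
            for c in range(M):
                th = self._solve(B[:, :, c], ys[:, c : c + 1], w)[:, 0]
                if self.standardize:
                    th = _shift_scale_1d(th, mean[c], scale[c])
                    th *= out_scale[c]
                    th[0] += out_mean[c]
                theta[:, c] = th
            self.theta_ = theta
            self.exponents_ = None
        self.n_input_channels_ = N
        self.n_output_channels_ = M
        return self

    def _solve(self, B, y, w):
        BtW = B.T * w[None, :]
        G = BtW @ B
        if self.ridge > 0:
            G = G + self.ridge * np.trace(G) / G.shape[0] * np.eye(G.shape[0])
        rhs = BtW @ y
        try:
            return np.linalg.solve(G, rhs)
        except np.linalg.LinAlgError:
            return np.linalg.lstsq(G, rhs, rcond=None)[0]

    def transform(self, X):
        """Evaluate F_theta at intensity samples X of shape (n, N)."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_input_channels_:
            raise ValueError(
                f"expected {self.n_input_channels_} channels, got {X.shape[1]}"
            )
        if self.mode == "full":
            B = basis_matrix(X, self.order, "full")
            return B @ self.theta_
        B = basis_matrix(X, self.order, "separable")
        return np.einsum("nbc,bc->nc", B, self.theta_)

    def predict(self, X):
        return self.transform(X)

    def _check_fitted(self):
        if not hasattr(self, "theta_"):
            raise AttributeError("PolynomialContrast is not fitted")

    # -- image-level conveniences ------------------------------------------
    def transform_image(self, img: Image) -> Image:
        flat = img.values.reshape(-1, img.n_channels)
        out = self.transform(flat)
        return Image(img.grid, out.reshape(img.grid.shape + (out.shape[1],)))

    def set_identity(self, n_channels: int) -> "PolynomialContrast":
        """Initialize theta to the identity map (requires N == M)."""
        self.theta_ = identity_coefficients(n_channels, self.order, self.mode)
        self.exponents_ = (
            monomial_exponents(n_channels, self.order) if self.mode == "full" else None
        )
        self.n_input_channels_ = n_channels
        self.n_output_channels_ = n_channels
        return self

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "order": int(self.order),
            "mode": self.mode,
            "N": int(self.n_input_channels_),
            "M": int(self.n_output_channels_),
            "exponents": None
            if self.exponents_ is None
            else self.exponents_.tolist(),
            "coefficients": self.theta_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolynomialContrast":
        obj = cls(order=d["order"], mode=d["mode"])
        obj.theta_ = np.asarray(d["coefficients"], dtype=float)
        obj.exponents_ = (
            None if d.get("exponents") is None else np.asarray(d["exponents"], int)
        )
        obj.n_input_channels_ = d["N"]
        obj.n_output_channels_ = d["M"]
        return obj


def fit_weighted(atlas_deformed: Image, target: Image, weights=None,
                 order: int = 1, mode: str = "full", ridge: float = 1e-6
                 ) -> PolynomialContrast:
    """Closed-form weighted polynomial contrast fit on image pairs."""
    if atlas_deformed.grid.shape != target.grid.shape:
        raise ValueError("images must share a grid")
    X = atlas_deformed.values.reshape(-1, atlas_deformed.n_channels)
    y = target.values.reshape(-1, target.n_channels)
    w = None if weights is None else np.asarray(weights, dtype=float).reshape(-1)
    est = PolynomialContrast(order=order, mode=mode, ridge=ridge)
    return est.fit(X, y, sample_weight=w)


def apply(F: PolynomialContrast, img: Image) -> Image:
    return F.transform_image(img)


def ncc_equivalent_matching_term(atlas_flat: np.ndarray, target_flat: np.ndarray,
                                 sigma_m: float) -> float:
    """Closed form of the minimized affine-contrast matching term.

    For an order-1 R -> R contrast map with unit weights, minimizing
    0.5 sigma_M^{-2} || J - (a I + b) ||^2 over (a, b) leaves

        0.5 sigma_M^{-2} ||J - Jbar||^2 (1 - rho^2)

    with rho the Pearson correlation of deformed atlas and target; i.e. the
    model reduces to normalized cross-correlation in the affine case.
    """
    I = np.asarray(atlas_flat, dtype=float).ravel()
    J = np.asarray(target_flat, dtype=float).ravel()
    Jc = J - J.mean()
    Ic = I - I.mean()
    denom = np.sqrt((Ic @ Ic) * (Jc @ Jc))
    rho = (Ic @ Jc) / denom if denom > 0 else 0.0
    return 0.5 / sigma_m**2 * (Jc @ Jc) * (1.0 - rho**2)
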