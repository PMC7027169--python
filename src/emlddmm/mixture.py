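"""Per-pixel class mixture: E-step posteriors, class means, weighted objective.

Each target pixel is modeled as a noisy observation of exactly one of a
small family of atlases: the deformed, contrast-mapped template ("matching"),
or constant-intensity atlases ("artifact", "background") that absorb streaks,
folds, tears and empty slide.  Treating the per-pixel label as missing data
yields an EM algorithm: the E-step computes Gaussian responsibilities, the
M-step re-estimates the deformation, contrast coefficients, and the constant
class means (posterior-weighted means of the target).

The per-class noise standard deviations are user parameters, not estimated:
they encode the physical noise model and must be chosen to reflect it.  By
default the constant classes are 5x noisier than the matching class, which
makes them broad catch-all explanations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deformation import SobolevOperator, VelocityField, regularization_energy
from .grids import Image

MATCHING = "matching"
ARTIFACT = "artifact"
BACKGROUND = "background"


@dataclass
class MixtureModel:
    """Gaussian class family for the per-pixel label model.

    ``classes`` always contains "matching"; the matching-class mean is the
    deformed, contrast-mapped atlas (supplied at E-step time, not stored
    here).  Constant classes carry an M-channel mean each.
    """

    classes: tuple = (MATCHING, ARTIFACT, BACKGROUND)
    sigma: dict = field(default_factory=dict)
    means: dict = field(default_factory=dict)
    priors: dict = field(default_factory=dict)

    def __post_init__(self):
        self.classes = tuple(self.classes)
        if MATCHING not in self.classes:
            raise ValueError('"matching" class is required')
        if not self.priors:
            self.priors = {c: 1.0 / len(self.classes) for c in self.classes}
        total = sum(self.priors[c] for c in self.classes)
        if not np.isclose(total, 1.0):
            raise ValueError(f"priors must sum to 1, got {total}")
        for c in self.classes:
            if self.sigma.get(c, 1.0) <= 0:
                raise ValueError(f"sigma for class {c!r} must be > 0")

    @classmethod
    def from_target(cls, target: Image, classes=(MATCHING, ARTIFACT, BACKGROUND),
                    sigma_m: float = 0.1, sigma_a: float = None,
                    sigma_b: float = None, priors: dict | None = None
                    ) -> "MixtureModel":
        """Build a model with data-driven constant-class mean initialization.

        The background mean starts at the mean of the 1% lowest-magnitude
        target pixels and the artifact mean at the 1% highest: background is
        typically empty/dark while artifacts (streaks, folds) are bright.
        """
        sigma_a = 5.0 * sigma_m if sigma_a is None else sigma_a
        sigma_b = 5.0 * sigma_m if sigma_b is None else sigma_b
        flat = target.values.reshape(-1, target.n_channels)
        mag = np.linalg.norm(flat, axis=1)
        k = max(1, int(round(0.01 * len(mag))))
        order = np.argsort(mag)
        means = {}
        if BACKGROUND in classes:
            means[BACKGROUND] = flat[order[:k]].mean(axis=0)
        if ARTIFACT in classes:
            means[ARTIFACT] = flat[order[-k:]].mean(axis=0)
        sigma = {MATCHING: sigma_m, ARTIFACT: sigma_a, BACKGROUND: sigma_b}
        sigma = {c: sigma[c] for c in classes}
        model = cls(classes=tuple(classes), sigma=sigma, means=means,
                    priors=dict(priors) if priors else {})
        return model


@dataclass
class ClassPosteriors:
    """Per-pixel responsibilities on the target grid, one array per class."""

    grid: object
    pi: dict

    def __getitem__(self, c: str) -> np.ndarray:
        return self.pi[c]

    @property
    def matching(self) -> np.ndarray:
        return self.pi[MATCHING]

    def argmax_labels(self) -> np.ndarray:
        """Integer label map: index into the class tuple of the max posterior."""
        classes = list(self.pi)
        stack = np.stack([self.pi[c] for c in classes], axis=-1)
        return np.argmax(stack, axis=-1)

    def class_names(self):
        return list(self.pi)


def _log_gauss(J: np.ndarray, mean: np.ndarray, sigma: float) -> np.ndarray:
    """Spherical Gaussian log-density per pixel; J (..., M), mean (..., M)."""
    M = J.shape[-1]
    sq = np.sum((J - mean) ** 2, axis=-1)
    return -0.5 * sq / sigma**2 - 0.5 * M * np.log(2.0 * np.pi * sigma**2)


def e_step(target: Image, predicted: Image, model: MixtureModel
           ) -> ClassPosteriors:
    """Gaussian responsibilities, computed in the log domain.

    pi_i^c  proportional to  prior_c (2 pi sigma_c^2)^{-M/2}
                             exp(-||J_i - mean_c,i||^2 / (2 sigma_c^2))

    normalized over classes per pixel; the matching-class mean is the
    supplied ``predicted`` image (F_theta of the deformed atlas).
    """
    if target.grid.shape != predicted.grid.shape:
        raise ValueError("target and predicted images must share a grid")
    J = target.values
    logs = []
    for c in model.classes:
        sigma = model.sigma[c]
        if sigma <= 0:
            raise ValueError(f"sigma for class {c!r} must be > 0")
        mean = predicted.values if c == MATCHING else np.broadcast_to(
            np.asarray(model.means[c], dtype=float), J.shape
        )
        logs.append(np.log(model.priors[c]) + _log_gauss(J, mean, sigma))
    stack = np.stack(logs, axis=-1)
    stack -= stack.max(axis=-1, keepdims=True)
    w = np.exp(stack)
    w /= w.sum(axis=-1, keepdims=True)
    pi = {c: w[..., k] for k, c in enumerate(model.classes)}
    return ClassPosteriors(grid=target.grid, pi=pi)


def log_evidence(target: Image, predicted: Image, model: MixtureModel
                 ) -> float:
    """Sum over pixels of log sum_c prior_c N(J_i; mean_c, sigma_c^2 Id).

    The (negative of the) quantity EM is guaranteed not to decrease; adding
    the deformation penalty gives the penalized marginal log-likelihood
    tracked for the monotonicity audit.
    """
    J = target.values
    logs = []
    for c in model.classes:
        mean = predicted.values if c == MATCHING else np.broadcast_to(
            np.asarray(model.means[c], dtype=float), J.shape
        )
        logs.append(np.log(model.priors[c]) + _log_gauss(J, mean, model.sigma[c]))
    stack = np.stack(logs, axis=-1)
    m = stack.max(axis=-1, keepdims=True)
    return float(np.sum(m[..., 0] + np.log(np.sum(np.exp(stack - m), axis=-1))))


def update_class_means(target: Image, posteriors: ClassPosteriors,
                       model: MixtureModel, min_weight: float = 1e-8) -> dict:
    """Posterior-weighted channel-wise means of the constant classes.

        mu_c = sum_i J_i pi_i^c / sum_i pi_i^c

    A degenerate class (total responsibility ~ 0) keeps its previous mean.
    Returns the updated means dict (also written into ``model.means``).
    """
    J = target.values.reshape(-1, target.n_channels)
    for c in model.classes:
        if c == MATCHING:
            continue
        w = posteriors[c].reshape(-1)
        total = w.sum()
        if total <= min_weight:
            continue  # degenerate class: keep previous mean
        model.means[c] = (w @ J) / total
    return dict(model.means)


def matching_term(target: Image, predicted: Image, pi_m: np.ndarray,
                  sigma_m: float, voxel_volume: float = None) -> float:
    """(1 / 2 sigma_M^2) sum_i pi_i^M ||J_i - pred_i||^2 * voxel volume."""
    if sigma_m <= 0:
        raise ValueError(f"sigma_m must be > 0, got {sigma_m}")
    vv = target.grid.voxel_volume if voxel_volume is None else voxel_volume
    sq = np.sum((target.values - predicted.values) ** 2, axis=-1)
    return 0.5 / sigma_m**2 * float(np.sum(pi_m * sq)) * vv


def weighted_objective(v: VelocityField, A: SobolevOperator, sigma_r: float,
                       target: Image, predicted: Image, pi_m: np.ndarray,
                       sigma_m: float) -> float:
    """The weighted registration objective (deformation penalty + matching).

    Reduces to the unweighted contrast-only objective when pi_M is one
    everywhere.
    """
    reg = regularization_energy(v, A, sigma_r)
    return reg + matching_term(target, predicted, pi_m, sigma_m)
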