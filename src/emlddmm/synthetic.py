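"""Synthetic fixtures: phantom pairs, stain swaps, hemispheres, tangle patches.

Every experiment in the test suite runs on data produced here, so the
generators are first-class, seeded, bit-reproducible code.  The phantom
emulates a T1-like atlas matched to a T2-like target: the atlas background
has intensity 0, gray matter 1 and white matter 1.25; the target background
is 0, gray matter 0.9, white matter 0.675 and a bright streak artifact 5.
Both images receive additive white Gaussian noise of standard deviation
0.05 and are blurred with a Gaussian kernel of standard deviation 2/3
pixels truncated to a 5 x 5 window.  A wedge of tissue is removed from the
target (set to background) to model torn/missing tissue.

The brain-like geometry itself (ellipse with a sulcus-like indentation and
concentric white matter) is a configurable invention; the intensity levels,
noise, and blur above are the fixed study conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import Image, ImageGrid

ATLAS_LEVELS = {"background": 0.0, "gray": 1.0, "white": 1.25}
TARGET_LEVELS = {"background": 0.0, "gray": 0.9, "white": 0.675, "artifact": 5.0}
NOISE_SD = 0.05
BLUR_SD = 2.0 / 3.0
BLUR_WINDOW = 5


def gaussian_blur_kernel(sd: float = BLUR_SD, window: int = BLUR_WINDOW
                         ) -> np.ndarray:
    """Gaussian kernel truncated to ``window x window``, normalized to sum 1."""
    half = window // 2
    x = np.arange(-half, half + 1)
    k1 = np.exp(-0.5 * (x / sd) ** 2)
    k = np.outer(k1, k1)
    return k / k.sum()


def _blur(values: np.ndarray) -> np.ndarray:
    return ndimage.convolve(values, gaussian_blur_kernel(), mode="nearest")


@dataclass
class PhantomSpec:
    """Study conditions for the simulated atlas/target pair."""

    size: int = 128
    atlas_levels: dict = field(default_factory=lambda: dict(ATLAS_LEVELS))
    target_levels: dict = field(default_factory=lambda: dict(TARGET_LEVELS))
    noise_sd: float = NOISE_SD
    blur_sd: float = BLUR_SD
    blur_window: int = BLUR_WINDOW
    wedge_angle: tuple = (-0.5, 0.5)  # radians, about the wedge apex
    streak_offset: float = 0.28  # fraction of size above center
    streak_width: float = 1.5  # pixels (half-width)
    warp_amplitude: float = 2.5  # pixels
    warp_scale: float = 0.25  # wavelength fraction of the image size
    seed: int = 0


@dataclass
class PhantomTruth:
    """Ground-truth annotations accompanying a phantom pair."""

    masks: dict  # {"tissue", "missing", "artifact"} boolean arrays (target grid)
    warp_target_to_atlas: object  # callable on (n, 2) world points
    warp_atlas_to_target: object  # numerical inverse of the above
    labels_atlas: np.ndarray
    labels_target: np.ndarray


def _brain_labels(size: int) -> np.ndarray:
    """0 = background, 1 = gray, 2 = white; ellipse with a sulcal notch."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = cx = (size - 1) / 2.0
    u = (yy - cy) / (0.38 * size)
    w = (xx - cx) / (0.30 * size)
    brain = u**2 + w**2 <= 1.0
    # sulcus-like indentation from the top
    notch = (np.abs(xx - cx) < 0.04 * size) & (yy < cy - 0.12 * size)
    brain &= ~notch
    ui = (yy - cy) / (0.24 * size)
    wi = (xx - cx - 0.03 * size) / (0.17 * size)
    white = (ui**2 + wi**2 <= 1.0) & brain
    labels = np.zeros((size, size), dtype=int)
    labels[brain] = 1
    labels[white] = 2
    return labels


class _SmoothWarp:
    """Smooth sinusoidal displacement x -> x + u(x), diffeomorphic for small
    amplitude; provides the numerical inverse by fixed-point iteration."""

    def __init__(self, size: int, amplitude: float, scale: float, seed: int):
        rng = np.random.default_rng(seed)
        self.size = size
        self.amp = amplitude
        self.k = 2.0 * np.pi / (scale * size)
        self.phase = rng.uniform(0, 2 * np.pi, size=(2, 2))
        self.weights = rng.uniform(0.5, 1.0, size=(2, 2))

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        u = np.zeros_like(pts)
        for d in range(2):
            u[..., d] = self.amp * (
                self.weights[d, 0] * np.sin(self.k * pts[..., 0] + self.phase[d, 0])
                * np.cos(0.7 * self.k * pts[..., 1] + self.phase[d, 1])
            )
        return u

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        """Target -> atlas pullback: T(x) = x + u(x)."""
        return np.asarray(pts, dtype=float) + self.displacement(pts)

    def inverse(self, pts: np.ndarray, n_iter: int = 30) -> np.ndarray:
        """Atlas -> target: solve y + u(y) = p by fixed-point iteration."""
        pts = np.asarray(pts, dtype=float)
        y = pts.copy()
        for _ in range(n_iter):
            y = pts - self.displacement(y)
        return y


def make_phantom_pair(spec: PhantomSpec = None):
    """Simulated atlas/target pair with contrast swap, streak and wedge.

    Returns ``(atlas, target, truth)`` where ``truth`` is a
    :class:`PhantomTruth` carrying the artifact/missing/tissue masks and the
    ground-truth warp in both directions.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    grid = ImageGrid((size, size), (1.0, 1.0), (0.0, 0.0))
    labels = _brain_labels(size)

    lut_atlas = np.array(
        [spec.atlas_levels["background"], spec.atlas_levels["gray"],
         spec.atlas_levels["white"]]
    )
    atlas_clean = lut_atlas[labels]

    warp = _SmoothWarp(size, spec.warp_amplitude, spec.warp_scale,
                       seed=spec.seed + 1)
    pts = grid.coordinate_array()
    src = warp(pts.reshape(-1, 2)).reshape(size, size, 2)
    labels_target = ndimage.map_coordinates(
        labels.astype(float), [src[..., 0], src[..., 1]], order=0,
        mode="constant", cval=0.0,
    ).astype(int)

    lut_target = np.array(
        [spec.target_levels["background"], spec.target_levels["gray"],
         spec.target_levels["white"]]
    )
    target_clean = lut_target[labels_target]
    tissue = labels_target > 0

    # missing wedge: angular sector about the brain center, cut to background
    cy = cx = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    ang = np.arctan2(yy - cy, xx - cx)
    wedge = (ang > spec.wedge_angle[0]) & (ang < spec.wedge_angle[1])
    missing = wedge & tissue
    target_clean[wedge] = spec.target_levels["background"]

    # bright streak artifact: horizontal line above center
    streak_row = cy - spec.streak_offset * size
    streak = np.abs(yy - streak_row) <= spec.streak_width
    target_clean[streak] = spec.target_levels["artifact"]

    atlas_vals = _blur(atlas_clean) + rng.normal(0, spec.noise_sd, (size, size))
    target_vals = _blur(target_clean) + rng.normal(0, spec.noise_sd, (size, size))

    truth = PhantomTruth(
        masks={
            "tissue": tissue & ~wedge & ~streak,
            "missing": missing & ~streak,
            "artifact": streak,
        },
        warp_target_to_atlas=warp,
        warp_atlas_to_target=warp.inverse,
        labels_atlas=labels,
        labels_target=labels_target,
    )
    return Image(grid, atlas_vals), Image(grid, target_vals), truth


def make_stain_pair(seed: int = 0, size: int = 96):
    """Two sections of one geometry with rank-permuted tissue intensities.

    Image A emulates a tau stain (gray darkest < white < background) and
    image B a myelin stain (white darkest < gray < background): the gray and
    white ranks are swapped, which no monotone (order-1) contrast map can
    undo.  Both carry mild independent warps, blur, and noise.
    """
    rng = np.random.default_rng(seed)
    grid = ImageGrid((size, size), (1.0, 1.0), (0.0, 0.0))
    labels = _brain_labels(size)
    levels_a = np.array([0.9, 0.3, 0.55])  # bg, gray, white
    levels_b = np.array([0.9, 0.55, 0.3])  # gray/white swapped
    pts = grid.coordinate_array().reshape(-1, 2)
    images = []
    warps = []
    for k, levels in enumerate([levels_a, levels_b]):
        warp = _SmoothWarp(size, 1.2, 0.35, seed=seed * 7 + k)
        src = warp(pts).reshape(size, size, 2)
        lab = ndimage.map_coordinates(
            labels.astype(float), [src[..., 0], src[..., 1]], order=0,
            mode="constant", cval=0.0,
        ).astype(int)
        vals = _blur(levels[lab]) + rng.normal(0, 0.02, (size, size))
        images.append(Image(grid, vals))
        warps.append(warp)
    truth = {"labels": labels, "warps": warps,
             "levels": {"A": levels_a, "B": levels_b}}
    return images[0], images[1], truth


def make_hemisphere_pair(seed: int = 0, size: int = 96):
    """Whole-brain atlas and a half-removed, contrast-shifted target.

    Emulates the whole-brain-to-hemisphere experiment: a synthetic 2D brain
    with gray matter, white matter and a ventricle, in two contrasts (the
    atlas b0-like, the target trace-like), with a mild warp between them and
    one hemisphere of the target replaced by background.

    Returns ``(whole, half, truth)`` with per-structure boolean label masks
    for both images and the retained-half mask in ``truth``.
    """
    rng = np.random.default_rng(seed)
    grid = ImageGrid((size, size), (1.0, 1.0), (0.0, 0.0))
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = cx = (size - 1) / 2.0
    brain = ((yy - cy) / (0.40 * size)) ** 2 + ((xx - cx) / (0.33 * size)) ** 2 <= 1
    white = ((yy - cy) / (0.26 * size)) ** 2 + ((xx - cx) / (0.20 * size)) ** 2 <= 1
    vent = ((yy - cy) / (0.10 * size)) ** 2 + (
        (xx - cx - 0.02 * size) / (0.05 * size)
    ) ** 2 <= 1
    labels = np.zeros((size, size), dtype=int)
    labels[brain] = 1  # gray
    labels[white & brain] = 2  # white
    labels[vent & brain] = 3  # ventricle
    # b0-like: CSF bright; trace-like: white bright, CSF dark
    levels_whole = np.array([0.0, 0.55, 0.4, 0.95])
    levels_half = np.array([0.0, 0.5, 0.8, 0.15])

    whole_vals = _blur(levels_whole[labels]) + rng.normal(0, 0.02, (size, size))

    warp = _SmoothWarp(size, 1.5, 0.4, seed=seed + 11)
    pts = grid.coordinate_array().reshape(-1, 2)
    src = warp(pts).reshape(size, size, 2)
    labels_t = ndimage.map_coordinates(
        labels.astype(float), [src[..., 0], src[..., 1]], order=0,
        mode="constant", cval=0.0,
    ).astype(int)
    half_vals = levels_half[labels_t]
    retained = xx >= cx  # keep the right hemisphere
    half_vals[~retained] = 0.0
    half_vals = _blur(half_vals) + rng.normal(0, 0.02, (size, size))

    names = {1: "gray", 2: "white", 3: "ventricle"}
    truth = {
        "labels_whole": {n: labels == k for k, n in names.items()},
        "labels_half": {n: (labels_t == k) & retained for k, n in names.items()},
        "labels_target_full": {n: labels_t == k for k, n in names.items()},
        "retained": retained,
        "warp": warp,
    }
    return Image(grid, whole_vals), Image(grid, half_vals), truth


# ----------------------------------------------------------------------
PATCH_SIZE = 56
PATCH_CLASSES = ("tangle", "tissue", "background")
DEFAULT_POSITIVE_FRACTION = 0.083


@dataclass
class PatchDataset:
    """Labeled 56 x 56 x 3 patches for the tangle detector."""

    patches: np.ndarray  # (n, 56, 56, 3) in [0, 1]
    labels: np.ndarray  # (n,) int: 0 tangle, 1 tissue, 2 background
    class_names: tuple = PATCH_CLASSES

    @property
    def positive_fraction(self) -> float:
        return float(np.mean(self.labels == 0))


def _tissue_texture(rng, size):
    base = rng.normal(0.62, 0.08, (size, size, 3))
    base[..., 0] += 0.08  # warm histology hue
    base = ndimage.gaussian_filter(base, (1.5, 1.5, 0))
    # scatter of faint nuclei
    for _ in range(rng.integers(4, 9)):
        r, c = rng.integers(4, size - 4, 2)
        rad = rng.uniform(1.0, 2.2)
        yy, xx = np.mgrid[0:size, 0:size]
        blob = np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * rad**2))
        base -= 0.18 * blob[..., None]
    return np.clip(base, 0, 1)


def make_tangle_patches(n: int = 240,
                        positive_fraction: float = DEFAULT_POSITIVE_FRACTION,
                        seed: int = 0) -> PatchDataset:
    """Synthetic stand-in for manually clicked training patches.

    "tangle": a dark compact blob at the patch center over tissue texture;
    "tissue": the same texture without a central blob; "background":
    near-white slide noise.  The non-tangle patches are split evenly between
    tissue and background.
    """
    if n < 10:
        raise ValueError("need at least 10 patches")
    if not (0.0 < positive_fraction < 1.0):
        raise ValueError("positive_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_pos = max(1, int(round(positive_fraction * n)))
    n_tis = (n - n_pos) // 2
    n_bg = n - n_pos - n_tis
    s = PATCH_SIZE
    patches = np.zeros((n, s, s, 3))
    labels = np.concatenate(
        [np.zeros(n_pos, int), np.ones(n_tis, int), np.full(n_bg, 2, int)]
    )
    yy, xx = np.mgrid[0:s, 0:s]
    c = (s - 1) / 2.0
    for i, lab in enumerate(labels):
        if lab == 2:
            patches[i] = np.clip(
                rng.normal(0.93, 0.03, (s, s, 3)), 0, 1
            )
            continue
        patch = _tissue_texture(rng, s)
        if lab == 0:
            rad = rng.uniform(3.0, 6.0)
            jy, jx = rng.uniform(-2, 2, 2)
            blob = np.exp(
                -(((yy - c - jy) ** 2 + (xx - c - jx) ** 2) / (2 * rad**2))
            )
            dark = np.array([0.45, 0.5, 0.55])  # brown-dark tangle core
            patch = patch * (1 - 0.9 * blob[..., None] * dark)
        patches[i] = np.clip(patch, 0, 1)
    perm = rng.permutation(n)
    return PatchDataset(patches=patches[perm], labels=labels[perm])
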