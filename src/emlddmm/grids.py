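"""Regular-grid images: sampling, gradients, block averaging, pyramids.

All images live on axis-aligned regular grids with physical metadata.
Conventions used throughout the package:

* voxel indices are 0-based; the *world* coordinate of voxel ``k`` along
  axis ``d`` is ``origin[d] + k * spacing[d]`` (voxel centers);
* the slowest-varying axis comes first, both in 2D and 3D;
* the channel axis is last; scalar images carry an explicit channel axis of
  size 1;
* all spatial transforms operate in world coordinates, so images of
  different resolution compose correctly.

Sampling outside the grid clamps to the nearest boundary sample.  The
mixture model — not padding — is responsible for explaining pixels that have
no atlas correspondence, and clamping avoids spurious matching gradients at
the edge of the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class ImageGrid:
    """Axis-aligned regular sampling grid with world coordinates.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels per axis (slowest-varying first).
    spacing : tuple of float
        Physical size of one voxel per axis; strictly positive.
    origin : tuple of float
        World coordinate of the *center* of voxel index 0 per axis.
    """

    shape: tuple
    spacing: tuple
    origin: tuple

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        ndim = len(shape)
        spacing = tuple(float(s) for s in np.broadcast_to(self.spacing, (ndim,)))
        origin = tuple(float(o) for o in np.broadcast_to(self.origin, (ndim,)))
        if ndim not in (2, 3):
            raise ValueError(f"grid must be 2D or 3D, got ndim={ndim}")
        if any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be positive, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"grid spacing must be positive, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def diagonal(self) -> float:
        """Physical length of the grid diagonal (extent corner to corner)."""
        extent = [(n - 1) * d for n, d in zip(self.shape, self.spacing)]
        return float(np.sqrt(np.sum(np.square(extent))))

    def axis_coordinates(self):
        """Per-axis 1D arrays of world coordinates of the voxel centers."""
        return [
            o + d * np.arange(n)
            for n, d, o in zip(self.shape, self.spacing, self.origin)
        ]

    def coordinate_array(self) -> np.ndarray:
        """World coordinates of every voxel, shape ``(*shape, ndim)``."""
        mesh = np.meshgrid(*self.axis_coordinates(), indexing="ij")
        return np.stack(mesh, axis=-1)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices of world points ``(..., ndim)``."""
        points = np.asarray(points, dtype=float)
        return (points - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        indices = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + indices * np.asarray(self.spacing)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the sampled field of view."""
        idx = self.world_to_index(points)
        upper = np.asarray(self.shape) - 1
        return np.all((idx >= 0) & (idx <= upper), axis=-1)


@dataclass
class Image:
    """Channel-valued function sampled on an :class:`ImageGrid`.

    ``values`` has shape ``(*grid.shape, C)``.  A spatial-only array is
    promoted to a single channel on construction.  Values must be finite
    unless ``allow_missing`` is set, in which case NaN marks voxels without
    support (used by the quantification outputs, never by registration
    inputs).
    """

    grid: ImageGrid
    values: np.ndarray = field(repr=False)
    allow_missing: bool = False

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape == self.grid.shape:
            values = values[..., None]
        if values.shape[: self.grid.ndim] != self.grid.shape:
            raise ValueError(
                f"values shape {values.shape} does not match grid {self.grid.shape}"
            )
        if values.ndim != self.grid.ndim + 1:
            raise ValueError(
                "values must have exactly one trailing channel axis; "
                f"got shape {values.shape} on a {self.grid.ndim}D grid"
            )
        finite = np.isfinite(values)
        if self.allow_missing:
            if np.any(np.isinf(values)):
                raise ValueError("image values must not be infinite")
        elif not np.all(finite):
            raise ValueError("image values must be finite")
        self.values = values

    @property
    def n_channels(self) -> int:
        return self.values.shape[-1]

    def scalar(self) -> np.ndarray:
        """The values with the channel axis dropped (single-channel only)."""
        if self.n_channels != 1:
            raise ValueError("scalar() requires a single-channel image")
        return self.values[..., 0]


def interpolate(img: Image, points: np.ndarray, order: int = 1) -> np.ndarray:
    """Multilinear interpolation of ``img`` at world ``points`` ``(..., ndim)``.

    Points outside the grid are clamped to the nearest boundary sample.
    Returns an array of shape ``points.shape[:-1] + (C,)``.  ``order=0``
    selects nearest-neighbor sampling (for label images).
    """
    points = np.asarray(points, dtype=float)
    if points.shape[-1] != img.grid.ndim:
        raise ValueError(
            f"points have dimension {points.shape[-1]}, grid is {img.grid.ndim}D"
        )
    bad = ~np.isfinite(points).all(axis=-1)
    if bad.any():
        first = np.argwhere(bad)[0]
        raise ValueError(f"non-finite interpolation point at index {tuple(first)}")
    idx = img.grid.world_to_index(points)
    # clamp-to-edge: equivalent to map_coordinates mode="nearest"
    coords = [idx[..., d] for d in range(img.grid.ndim)]
    out = np.empty(points.shape[:-1] + (img.n_channels,), dtype=float)
    for c in range(img.n_channels):
        out[..., c] = ndimage.map_coordinates(
            img.values[..., c], coords, order=order, mode="nearest"
        )
    return out


def spatial_gradient(img: Image) -> np.ndarray:
    """Finite-difference gradient, shape ``(*shape, C, ndim)``.

    Central differences in the interior, one-sided at the boundaries, scaled
    by 1/spacing (``numpy.gradient`` semantics).
    """
    if any(n < 2 for n in img.grid.shape):
        raise ValueError("spatial_gradient requires at least 2 samples per axis")
    grads = np.gradient(
        img.values, *img.grid.spacing, axis=tuple(range(img.grid.ndim))
    )
    if img.grid.ndim == 1:  # pragma: no cover - grids are 2D/3D by contract
        grads = [grads]
    return np.stack(grads, axis=-1)


def _block_reduce_axis(values: np.ndarray, counts_like: np.ndarray, axis: int,
                       factor: int):
    """Sum `values` over non-overlapping blocks of `factor` along `axis`."""
    n = values.shape[axis]
    starts = np.arange(0, n, factor)
    sums = np.add.reduceat(values, starts, axis=axis)
    cnts = np.add.reduceat(counts_like, starts, axis=axis)
    return sums, cnts


def block_average(img: Image, factor) -> Image:
    """Non-overlapping block means (e.g. 32x32 histology downsampling).

    ``factor`` is a positive integer or one per axis.  Output spacing is the
    input spacing times the factor; the output origin sits at the center of
    the first (full) block.  Trailing partial blocks are averaged over the
    samples actually available.
    """
    factors = np.broadcast_to(factor, (img.grid.ndim,)).astype(int)
    if np.any(factors < 1):
        raise ValueError(f"block factor must be >= 1, got {tuple(factors)}")
    vals = img.values
    cnts = np.ones(img.grid.shape, dtype=float)[..., None]
    for ax, f in enumerate(factors):
        if f == 1:
            continue
        vals, cnts = _block_reduce_axis(vals, cnts, ax, int(f))
    out = vals / cnts
    new_spacing = tuple(d * f for d, f in zip(img.grid.spacing, factors))
    new_origin = tuple(
        o + (f - 1) / 2.0 * d
        for o, d, f in zip(img.grid.origin, img.grid.spacing, factors)
    )
    grid = ImageGrid(out.shape[:-1], new_spacing, new_origin)
    return Image(grid, out)


def build_pyramid(img: Image, factors) -> list:
    """One block-averaged image per factor; factors descend, e.g. [4, 2, 1].

    The coarse-to-fine schedule mitigates the sensitivity of the joint
    optimization to initialization; factor 1 returns the original image.
    """
    factors = list(factors)
    if len(factors) == 0:
        raise ValueError("pyramid factor list must not be empty")
    if any(f < 1 for f in factors):
        raise ValueError("pyramid factors must be >= 1")
    if list(sorted(factors, reverse=True)) != factors:
        raise ValueError(f"pyramid factors must be descending, got {factors}")
    out = []
    for f in factors:
        out.append(img if f == 1 else block_average(img, f))
    return out


def resample(img: Image, grid: ImageGrid) -> Image:
    """Sample ``img`` at the voxel centers of ``grid`` (clamped multilinear)."""
    return Image(grid, interpolate(img, grid.coordinate_array()))
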