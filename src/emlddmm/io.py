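"""Readers/writers for images, transforms and run manifests.

2D images travel as PNG (8/16-bit integer) or TIFF (integer or 32-bit
float); 3D volumes as NIfTI-1 with spacing/origin taken from the header
affine, whose rotation part must be axis-aligned (a diagonal matrix up to
sign) — oblique acquisitions must be resampled upstream.  Values are always
presented to the library as float with the channel axis last; integer PNG
values are promoted to float unchanged (an 8-bit image yields values in
[0, 255]).

Transforms are exported as displacement-field volumes (multi-channel TIFF
in 2D, NIfTI in 3D) plus a JSON sidecar holding the grid metadata, the
affine, the contrast coefficients and the composition order.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import tifffile

from .contrast import PolynomialContrast
from .deformation import Transform
from .grids import Image, ImageGrid

_VERSION = "0.1.0"


def read_image(path, spacing=None, origin=None) -> Image:
    """Read PNG/TIFF (2D) or NIfTI (3D) into an :class:`Image`.

    For 2D formats, ``spacing``/``origin`` default to 1 and 0 per axis;
    NIfTI takes both from the header affine.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    try:
        if suffixes.endswith((".nii", ".nii.gz")):
            return _read_nifti(path)
        if suffixes.endswith((".tif", ".tiff")):
            arr = tifffile.imread(path)
        elif suffixes.endswith(".png"):
            arr = iio.imread(path)
        else:
            raise ValueError(f"unsupported image format: {path.name}")
    except ValueError:
        raise
    except Exception as e:  # corrupt file
        raise ValueError(f"could not read image file {path}: {e}") from e
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[..., None]
    grid = ImageGrid(
        arr.shape[:2],
        (1.0, 1.0) if spacing is None else spacing,
        (0.0, 0.0) if origin is None else origin,
    )
    return Image(grid, arr)


def _read_nifti(path) -> Image:
    img = nib.load(str(path))
    aff = img.affine
    R = aff[:3, :3]
    # axis-aligned check: one nonzero entry per row/column
    mask = np.abs(R) > 1e-6 * max(np.abs(R).max(), 1e-30)
    if np.any(mask.sum(axis=0) != 1) or np.any(mask.sum(axis=1) != 1):
        raise ValueError(
            f"{path}: NIfTI affine rotation part is not axis-aligned; "
            "resample the volume to an axis-aligned grid first"
        )
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    spacing = np.abs(R).sum(axis=0)[:3]
    origin = aff[:3, 3]
    grid = ImageGrid(data.shape[:3], tuple(spacing), tuple(origin))
    return Image(grid, data)


def write_image(path, img: Image) -> None:
    """Write an Image; format chosen from the extension (TIFF/PNG/NIfTI)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    name = path.name.lower()
    vals = img.values
    if name.endswith((".nii", ".nii.gz")):
        aff = np.eye(4)
        for d in range(img.grid.ndim):
            aff[d, d] = img.grid.spacing[d]
            aff[d, 3] = img.grid.origin[d]
        data = vals[..., 0] if vals.shape[-1] == 1 else vals
        nib.save(nib.Nifti1Image(data, aff), str(path))
    elif name.endswith((".tif", ".tiff")):
        tifffile.imwrite(path, vals.astype(np.float32),
                         photometric="minisblack")
    elif name.endswith(".png"):
        out = vals[..., 0] if vals.shape[-1] == 1 else vals
        iio.imwrite(path, np.clip(out, 0, 255).astype(np.uint8))
    else:
        raise ValueError(f"unsupported output format: {path.name}")


# ----------------------------------------------------------------------
def save_transform(out_dir, phi: Transform, phi_inv: Transform = None,
                   affine: np.ndarray = None,
                   contrast: PolynomialContrast = None,
                   composition: str = "target->affine_inverse->phi_inverse->atlas",
                   ) -> None:
    """Write displacement fields plus a JSON sidecar describing the chain."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": _VERSION,
        "composition": composition,
        "ndim": phi.grid.ndim,
        "grid": {
            "shape": list(phi.grid.shape),
            "spacing": list(phi.grid.spacing),
            "origin": list(phi.grid.origin),
        },
        "affine": None if affine is None else np.asarray(affine).tolist(),
        "contrast": None if contrast is None else contrast.to_dict(),
        "fields": {},
    }
    for name, T in (("forward", phi), ("inverse", phi_inv)):
        if T is None:
            continue
        fn = f"displacement_{name}.tif" if T.grid.ndim == 2 else (
            f"displacement_{name}.nii.gz"
        )
        write_image(out / fn, Image(T.grid, T.displacement()))
        meta["fields"][name] = fn
    (out / "transform.json").write_text(json.dumps(meta, indent=2))


def load_transform(in_dir):
    """Reconstruct transforms saved by :func:`save_transform`.

    Returns a dict with "forward"/"inverse" Transforms (those present),
    "affine" (or None) and "contrast" (or None).
    """
    in_dir = Path(in_dir)
    sidecar = in_dir / "transform.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"missing transform sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    grid = ImageGrid(
        tuple(meta["grid"]["shape"]),
        tuple(meta["grid"]["spacing"]),
        tuple(meta["grid"]["origin"]),
    )
    out = {
        "affine": None if meta["affine"] is None else np.asarray(meta["affine"]),
        "contrast": None
        if meta["contrast"] is None
        else PolynomialContrast.from_dict(meta["contrast"]),
        "composition": meta["composition"],
    }
    for name, fn in meta["fields"].items():
        img = read_image(in_dir / fn, spacing=grid.spacing, origin=grid.origin)
        disp = img.values
        if disp.shape != grid.shape + (grid.ndim,):
            raise ValueError(
                f"displacement field {fn} shape {disp.shape} does not match "
                f"sidecar grid {grid.shape}"
            )
        out[name] = Transform(grid, grid.coordinate_array() + disp)
    return out


# ----------------------------------------------------------------------
def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


class RunManifest:
    """Provenance record written once per CLI run."""

    def __init__(self, command: str, config: dict, seed=None):
        self.data = {
            "command": command,
            "version": _VERSION,
            "seed": seed,
            "config": config,
            "inputs": {},
            "outputs": [],
            "timings": {},
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self._t0 = time.time()
        self._stage_t = self._t0

    def add_input(self, path):
        p = Path(path)
        if p.is_file():
            self.data["inputs"][str(p)] = file_checksum(p)

    def add_output(self, path):
        self.data["outputs"].append(str(path))

    def stage(self, name):
        now = time.time()
        self.data["timings"][name] = round(now - self._stage_t, 3)
        self._stage_t = now

    def write(self, out_dir):
        self.data["elapsed"] = round(time.time() - self._t0, 3)
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, default=str))
        return path


def read_landmarks(path) -> np.ndarray:
    """CSV landmarks with a header and x,y[,z] world-coordinate columns."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = [c for c in ("x", "y", "z") if c in df.columns]
    if len(cols) < 2:
        raise ValueError(
            f"{path}: landmark CSV must have a header with x,y[,z] columns"
        )
    return df[cols].to_numpy(dtype=float)
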