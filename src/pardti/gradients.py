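"""Diffusion gradient schemes, b-matrix algebra, and file I/O.

A multi-shell acquisition is described by per-volume b-values (s/mm^2) and
unit gradient directions; the full diffusion weighting of volume *i* is the
symmetric b-matrix ``b_i = bval_i * g_i g_i^T``, whose double contraction
with a diffusion tensor D gives the (dimensionless) exponent of the
mono-exponential signal decay.

Gradient tables use the FSL text dialect: one row of b-values in ``.bval``
and three rows of direction components in ``.bvec``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GradientScheme",
    "ImageGrid",
    "build_default_scheme",
    "bmatrix_contract",
    "read_bvalbvec",
    "write_bvalbvec",
    "read_volume",
    "write_volume",
    "read_field",
    "write_field",
    "read_table",
    "write_table",
]

_UNIT_TOL = 1e-6


class FormatError(ValueError):
    """Malformed on-disk input (wrong shape, missing column, ...)."""


@dataclass(frozen=True)
class GradientScheme:
    """Per-volume diffusion weightings of a DWI acquisition.

    Attributes
    ----------
    bvals : (V,) array
        Diffusion weighting per volume, s/mm^2. Non-negative.
    bvecs : (V, 3) array
        Unit gradient directions; the zero vector is allowed (and
        conventional) for b=0 volumes.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvals.ndim != 1:
            raise FormatError("bvals must be a 1-D sequence")
        if bvecs.shape != (bvals.size, 3):
            raise FormatError(
                f"bvecs shape {bvecs.shape} does not match {bvals.size} b-values"
            )
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        norms = np.linalg.norm(bvecs, axis=1)
        ok = (np.abs(norms - 1.0) <= _UNIT_TOL) | (norms == 0.0)
        if not np.all(ok):
            raise ValueError(
                f"{np.count_nonzero(~ok)} gradient direction(s) are neither "
                "unit vectors nor zero"
            )
        if np.any((bvals > 0) & (norms == 0.0)):
            raise ValueError("nonzero b-value with zero gradient direction")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_volumes(self) -> int:
        return self.bvals.size

    @property
    def bmats(self) -> np.ndarray:
        """(V, 3, 3) symmetric b-matrices, ``bval * g g^T`` (s/mm^2)."""
        return self.bvals[:, None, None] * (
            self.bvecs[:, :, None] * self.bvecs[:, None, :]
        )

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    def shells(self) -> np.ndarray:
        """Sorted distinct nonzero b-values."""
        return np.unique(self.bvals[self.bvals > 0])


@dataclass(frozen=True)
class ImageGrid:
    """Sampling grid of an image volume (voxel counts, spacing, affine)."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"invalid grid shape {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))


def _repulsion_directions(n: int, seed: int, n_iter: int = 300) -> np.ndarray:
    """Approximately uniform unit directions by electrostatic repulsion.

    Antipodally symmetric energy (directions and their negatives repel), as
    appropriate for diffusion encoding where g and -g are equivalent.
    Deterministic for a given (n, seed).
    """
    rng = np.random.default_rng(seed)
    p = rng.standard_normal((n, 3))
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    step = 0.1
    for _ in range(n_iter):
        # forces between all pairs, including antipodes
        force = np.zeros_like(p)
        for sign in (1.0, -1.0):
            d = p[:, None, :] - sign * p[None, :, :]
            r2 = np.sum(d * d, axis=-1)
            np.fill_diagonal(r2, np.inf)
            if sign < 0:
                r2[r2 < 1e-12] = np.inf  # a point and its own antipode
            force += np.sum(d / (r2[..., None] ** 1.5 + 1e-12), axis=1)
        # project onto tangent plane and take a small step
        force -= np.sum(force * p, axis=1, keepdims=True) * p
        p = p + step * force / n
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        step *= 0.99
    return p


def build_default_scheme(
    seed: int = 0,
    n_b0: int = 10,
    shells: tuple[tuple[float, int], ...] = ((300.0, 10), (1100.0, 60)),
) -> GradientScheme:
    """Default multi-shell scheme: 10 x b0, 10 x b300, 60 x b1100 s/mm^2.

    Nonzero directions are spread approximately uniformly on the sphere by
    electrostatic-repulsion minimisation, deterministically per seed. b0
    volumes carry the zero vector and are interleaved first.
    """
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for k, (b, count) in enumerate(shells):
        dirs = _repulsion_directions(count, seed=seed * 1009 + k + 1)
        bvals.extend([float(b)] * count)
        bvecs.extend(list(dirs))
    return GradientScheme(np.asarray(bvals), np.asarray(bvecs))


def _check_symmetric(m: np.ndarray, name: str, tol: float = 1e-10) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"{name} must be 3x3, got {m.shape}")
    scale = max(np.max(np.abs(m)), 1.0)
    if np.max(np.abs(m - m.T)) > tol * scale:
        raise ValueError(f"{name} is not symmetric")
    return m


def bmatrix_contract(bmat: np.ndarray, D: np.ndarray) -> float:
    """Full double contraction ``sum_ij b_ij D_ij`` (off-diagonals twice).

    This is the dimensionless exponent of the tensor signal decay
    ``S = S0 exp(-b:D)``.
    """
    bmat = _check_symmetric(bmat, "bmat")
    D = _check_symmetric(D, "D")
    return float(np.sum(bmat * D))


# --------------------------------------------------------------------------
# file I/O


def read_bvalbvec(bval_path, bvec_path) -> GradientScheme:
    """Read an FSL-dialect gradient table (.bval one row, .bvec three rows)."""
    bvals = np.atleast_2d(np.loadtxt(bval_path, dtype=float))
    if bvals.shape[0] != 1:
        raise FormatError(f"bval file must have exactly 1 row, got {bvals.shape[0]}")
    bvals = bvals[0]
    bvecs = np.atleast_2d(np.loadtxt(bvec_path, dtype=float))
    if bvecs.shape[0] != 3:
        raise FormatError(f"bvec file must have exactly 3 rows, got {bvecs.shape[0]}")
    if bvecs.shape[1] != bvals.size:
        raise FormatError(
            f"bval/bvec length mismatch: {bvals.size} b-values vs "
            f"{bvecs.shape[1]} direction columns"
        )
    return GradientScheme(bvals, bvecs.T)


def write_bvalbvec(scheme: GradientScheme, bval_path, bvec_path) -> None:
    """Write FSL-dialect gradient files with 6 significant digits."""
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.6g")


def _grid_from_img(img) -> ImageGrid:
    zooms = img.header.get_zooms()[:3]
    return ImageGrid(tuple(img.shape[:3]), tuple(float(z) for z in zooms),
                     np.asarray(img.affine))


def read_volume(path, ndim: int | None = None) -> tuple[np.ndarray, ImageGrid]:
    """Read a NIfTI volume; ``ndim`` (3 or 4) enforces the expected role."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if ndim is not None and data.ndim != ndim:
        raise FormatError(
            f"{path}: expected a {ndim}-D volume, got {data.ndim}-D "
            f"with shape {data.shape}"
        )
    return data, _grid_from_img(img)


def write_volume(path, data: np.ndarray, grid: ImageGrid | None = None) -> None:
    affine = np.eye(4) if grid is None else grid.affine
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_field(path) -> tuple[np.ndarray, ImageGrid]:
    """Read a displacement field: 4-D NIfTI with 3 components on the last axis."""
    data, grid = read_volume(path, ndim=4)
    if data.shape[-1] != 3:
        raise FormatError(
            f"{path}: displacement field must have 3 components, "
            f"got {data.shape[-1]}"
        )
    return data, grid


def write_field(path, field_data: np.ndarray, grid: ImageGrid | None = None) -> None:
    field_data = np.asarray(field_data)
    if field_data.ndim != 4 or field_data.shape[-1] != 3:
        raise FormatError("displacement field must be (X, Y, Z, 3)")
    write_volume(path, field_data, grid)


def read_table(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a TSV table with header; ``required`` columns must be present."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
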