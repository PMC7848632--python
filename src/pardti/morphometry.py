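"""Tensor-based morphometry: log-Jacobian-determinant maps of warps.

A displacement field u(x) (voxel units) defines the forward map
phi(x) = x + u(x) from subject grid to template grid. The log of the
Jacobian determinant of phi quantifies local volume relative to the
template: logJ < 0 means the subject is locally smaller (atrophy),
logJ = 0 the identity.

Derivatives use central differences in the interior and one-sided
differences at the boundary; the determinant map is not smoothed here
(smoothing, if wanted, is a statistics-stage choice).
"""

from __future__ import annotations

import numpy as np

__all__ = ["jacobian_determinant", "log_jacobian"]


def _check_field(field: np.ndarray) -> np.ndarray:
    field = np.asarray(field, dtype=float)
    if field.ndim != 4 or field.shape[-1] != 3:
        raise ValueError(f"displacement field must be (X, Y, Z, 3), got {field.shape}")
    if not np.all(np.isfinite(field)):
        raise ValueError("displacement field contains non-finite values")
    return field


def jacobian_determinant(field: np.ndarray) -> np.ndarray:
    """Per-voxel determinant of d(phi)/dx for phi(x) = x + u(x)."""
    u = _check_field(field)
    # J[..., i, j] = d phi_i / d x_j = delta_ij + d u_i / d x_j
    J = np.empty(u.shape[:3] + (3, 3))
    for i in range(3):
        grads = np.gradient(u[..., i], axis=(0, 1, 2))
        for j in range(3):
            J[..., i, j] = grads[j]
    J += np.eye(3)
    return np.linalg.det(J)


def log_jacobian(field: np.ndarray, max_report: int = 5) -> np.ndarray:
    """Natural log of the Jacobian determinant; errors on non-invertible warps."""
    det = jacobian_determinant(field)
    bad = det <= 0
    if bad.any():
        locs = np.argwhere(bad)[:max_report]
        raise ValueError(
            f"warp is not invertible: {int(bad.sum())} voxel(s) with "
            f"non-positive Jacobian determinant, e.g. at "
            f"{[tuple(int(c) for c in l) for l in locs]}"
        )
    return np.log(det)
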