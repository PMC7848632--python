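"""Single- and dual-compartment diffusion tensor models and fitting.

The single-compartment (conventional) model is the mono-exponential decay

    S_i = S0 * exp(-b_i : D)

with ``b_i : D`` the full double contraction of the volume's b-matrix with
the diffusion tensor. The dual-compartment model splits each voxel into a
parenchymal tensor compartment and an isotropic CSF-like free-water
compartment with fixed diffusivity 3e-3 mm^2/s (free water at body
temperature):

    S_i = S0 * ( f_par * exp(-b_i : D_par) + (1 - f_par) * exp(-3e-3 * bval_i) )

``f_par`` is the parenchymal volume fraction (pVF); the free-water fraction
is 1 - f_par by construction. FA and MD of ``D_par`` are the parenchymal
pFA and pMD, which are insensitive to partial-volume contamination by free
water that biases the single-compartment FA and MD.

Fitting is unweighted nonlinear least squares on magnitude signals. The
dual fit is multi-modal near the f_par = 1 boundary, so it is multi-started
over a grid of f_par initial values; constraints (f_par in [0,1], D_par
positive semi-definite with eigenvalues capped at 3e-3 mm^2/s) are enforced
by a logistic transform for f_par and a Cholesky parameterisation plus a
final spectral clip for D_par. The per-voxel solver is a vectorised
Levenberg-Marquardt with analytic Jacobians, so whole volumes fit in
batches rather than one scipy call per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .gradients import GradientScheme

__all__ = [
    "D_CSF",
    "EIG_MAX",
    "DualFitVoxel",
    "FitResult",
    "predict_single",
    "predict_dual",
    "fit_single_loglinear",
    "fit_single_nls",
    "fit_dual_nls",
    "tensor_eigenvalues",
    "md_of",
    "fa_of",
    "fit_volume",
]

D_CSF = 3.0e-3  # mm^2/s, fixed free-water diffusivity at 37 C
EIG_MAX = 3.0e-3  # mm^2/s, cap on parenchymal eigenvalues

# internal scaling: b in ms/um^2 (=s/mm^2 / 1000), D in um^2/ms (= mm^2/s * 1000)
_B_SCALE = 1.0e-3
_D_SCALE = 1.0e3
_DCSF_S = D_CSF * _D_SCALE

# Voigt order for the six unique tensor components
_VOIGT = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
# lower-triangular Cholesky entry order
_LOWER = [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]
_DEFAULT_INIT_GRID = (0.5, 0.7, 0.9, 1.0)


def tensor_to_vec6(D: np.ndarray) -> np.ndarray:
    """Symmetric (..., 3, 3) tensor -> (..., 6) Voigt vector (xx,yy,zz,xy,xz,yz)."""
    D = np.asarray(D)
    return np.stack([D[..., i, j] for i, j in _VOIGT], axis=-1)


def vec6_to_tensor(v: np.ndarray) -> np.ndarray:
    """(..., 6) Voigt vector -> symmetric (..., 3, 3) tensor."""
    v = np.asarray(v)
    out = np.zeros(v.shape[:-1] + (3, 3), dtype=v.dtype)
    for k, (i, j) in enumerate(_VOIGT):
        out[..., i, j] = v[..., k]
        out[..., j, i] = v[..., k]
    return out


@dataclass
class DualFitVoxel:
    """Dual-compartment fit of a single voxel."""

    s0: float
    f_par: float
    d_par: np.ndarray  # (3, 3) symmetric, mm^2/s
    rss: float
    converged: bool

    @property
    def f_csf(self) -> float:
        """Free-water volume fraction; 1 - f_par by model construction."""
        return 1.0 - self.f_par


@dataclass
class FitResult:
    """Whole-volume fit: named scalar maps plus per-voxel fit volumes.

    ``maps`` holds the derived scalar maps (FA/MD for the single model,
    pFA/pMD/pVF for the dual model); voxels outside the mask are zero.
    """

    maps: dict[str, np.ndarray]
    s0: np.ndarray
    tensors: np.ndarray  # (X, Y, Z, 6) Voigt components, mm^2/s
    rss: np.ndarray
    converged: np.ndarray  # bool; False outside mask and for failed voxels
    mask: np.ndarray
    model: str = "dual"
    f_par: np.ndarray | None = field(default=None)


# --------------------------------------------------------------------------
# forward models


def predict_single(s0: float, D: np.ndarray, scheme: GradientScheme) -> np.ndarray:
    """Mono-exponential signal ``S0 exp(-b:D)`` per volume."""
    if s0 <= 0:
        raise ValueError("S0 must be positive")
    D = np.asarray(D, dtype=float)
    q = np.einsum("vij,ij->v", scheme.bmats, D)
    return s0 * np.exp(-q)


def predict_dual(
    s0: float, f_par: float, d_par: np.ndarray, scheme: GradientScheme
) -> np.ndarray:
    """Biexponential two-compartment signal with fixed free-water diffusivity."""
    if not 0.0 <= f_par <= 1.0:
        raise ValueError(f"f_par must be in [0, 1], got {f_par}")
    tissue = predict_single(s0, d_par, scheme)
    csf = s0 * np.exp(-D_CSF * scheme.bvals)
    return f_par * tissue + (1.0 - f_par) * csf


# --------------------------------------------------------------------------
# log-linear (OLS) initialiser


def _design_loglinear(scheme: GradientScheme) -> np.ndarray:
    """(V, 7) design: log S = [1, -b_voigt_weighted] @ [log S0, D_voigt]."""
    bm = tensor_to_vec6(scheme.bmats)  # (V, 6)
    w = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
    return np.hstack([np.ones((scheme.n_volumes, 1)), -bm * w])


def fit_single_loglinear(
    signals: np.ndarray, scheme: GradientScheme
) -> tuple[float, np.ndarray]:
    """OLS tensor fit on log signals; the standard initialiser for NLS.

    Requires at least 7 volumes including one b=0 and strictly positive
    signals. No positivity constraint is placed on the tensor.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 1 or signals.size != scheme.n_volumes:
        raise ValueError("signals must be 1-D matching the scheme's volume count")
    if scheme.n_volumes < 7:
        raise ValueError("at least 7 volumes are needed for a tensor fit")
    if not np.any(scheme.b0_mask):
        raise ValueError("at least one b=0 volume is required")
    if np.any(signals <= 0):
        raise ValueError("non-positive signal; floor or mask before log-fitting")
    X = _design_loglinear(scheme)
    coef, *_ = np.linalg.lstsq(X, np.log(signals), rcond=None)
    return float(np.exp(coef[0])), vec6_to_tensor(coef[1:])


def _loglinear_batch(Y: np.ndarray, scheme: GradientScheme) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised log-linear fit. Y (N, V) positive. Returns (S0 (N,), D6 (N, 6))."""
    X = _design_loglinear(scheme)
    coef, *_ = np.linalg.lstsq(X, np.log(Y).T, rcond=None)
    coef = coef.T  # (N, 7)
    return np.exp(coef[:, 0]), coef[:, 1:]


# --------------------------------------------------------------------------
# eigen-derived scalars


def tensor_eigenvalues(D: np.ndarray) -> np.ndarray:
    """Eigenvalues of a symmetric tensor, sorted descending."""
    w = np.linalg.eigvalsh(np.asarray(D, dtype=float))
    return w[..., ::-1]


def md_of(D: np.ndarray) -> float:
    """Mean diffusivity: the eigenvalue mean, i.e. trace/3."""
    D = np.asarray(D, dtype=float)
    return float(np.trace(D) / 3.0)


def fa_of(D: np.ndarray) -> float:
    """Fractional anisotropy; defined as 0 for the zero tensor."""
    lam = tensor_eigenvalues(D)
    norm2 = float(np.sum(lam**2))
    if norm2 == 0.0:
        return 0.0
    dev = lam - lam.mean()
    return float(np.sqrt(1.5 * np.sum(dev**2) / norm2))


def _fa_md_batch(D6: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """FA and MD for (N, 6) Voigt tensors (mm^2/s)."""
    lam = np.linalg.eigvalsh(vec6_to_tensor(D6))
    md = lam.mean(axis=-1)
    norm2 = np.sum(lam**2, axis=-1)
    dev2 = np.sum((lam - md[..., None]) ** 2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * dev2 / norm2)
    fa[norm2 == 0.0] = 0.0
    return fa, md


# --------------------------------------------------------------------------
# vectorised Levenberg-Marquardt

def _levmar(Y, theta0, model_jac, max_iter=60, gtol=1e-11, xtol=1e-11):
    """Batched LM minimising ||Y - m(theta)||^2 per row.

    ``model_jac(theta) -> (m, J)`` with m (N, V) and J (N, V, P). Damping is
    per voxel on the scaled diagonal; finished voxels drop out of the active
    set. Returns (theta, rss, converged) -- voxels whose damping blew up
    without progress are reported unconverged.
    """
    theta = np.array(theta0, dtype=float)
    N, P = theta.shape
    m, _ = model_jac(theta, want_jac=False)
    r = Y - m
    cost = np.einsum("nv,nv->n", r, r)
    lam = np.full(N, 1e-3)
    converged = np.zeros(N, dtype=bool)
    stuck = np.zeros(N, dtype=bool)
    eye = np.eye(P)
    active = np.arange(N)
    for _ in range(max_iter):
        if active.size == 0:
            break
        th_a = theta[active]
        _, J = model_jac(th_a)
        r_a = Y[active] - _
        Jt = J.transpose(0, 2, 1)
        A = Jt @ J
        g = (Jt @ r_a[..., None])[..., 0]
        diag = np.einsum("npp->np", A)
        floor = np.maximum(diag.max(axis=1, keepdims=True) * 1e-14, 1e-30)
        damp = lam[active][:, None] * np.maximum(diag, floor) + 1e-30
        Ad = A + damp[:, :, None] * eye
        try:
            step = np.linalg.solve(Ad, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.einsum("npq,nq->np", np.linalg.pinv(Ad), g)
        theta_try = th_a + step
        m_try, _ = model_jac(theta_try, want_jac=False)
        r_try = Y[active] - m_try
        cost_try = np.einsum("nv,nv->n", r_try, r_try)
        cost_a = cost[active]
        ok = cost_try <= cost_a
        small_step = np.max(np.abs(step), axis=1) <= xtol * (
            1.0 + np.max(np.abs(th_a), axis=1)
        )
        tiny_gain = (cost_a - cost_try) <= gtol * (cost_a + 1e-30)
        idx_ok = active[ok]
        theta[idx_ok] = theta_try[ok]
        cost[idx_ok] = cost_try[ok]
        lam[idx_ok] = np.maximum(lam[idx_ok] / 3.0, 1e-12)
        idx_rej = active[~ok]
        lam[idx_rej] = lam[idx_rej] * 4.0
        converged[active[ok & (small_step | tiny_gain)]] = True
        stuck[idx_rej[lam[idx_rej] >= 1e9]] = True
        active = np.where(~converged & ~stuck)[0]
    return theta, cost, converged


def _chol_from_entries(l6: np.ndarray) -> np.ndarray:
    """(N, 6) lower-triangular entries -> (N, 3, 3) Cholesky factor L."""
    N = l6.shape[0]
    L = np.zeros((N, 3, 3))
    for k, (i, j) in enumerate(_LOWER):
        L[:, i, j] = l6[:, k]
    return L


def _entries_from_chol(L: np.ndarray) -> np.ndarray:
    return np.stack([L[:, i, j] for i, j in _LOWER], axis=-1)


def _safe_chol(D6: np.ndarray, lam_min: float = 1e-3, lam_max: float = 2.99) -> np.ndarray:
    """Cholesky factors of (N, 6) scaled tensors with eigenvalues clipped
    into [lam_min, lam_max] (um^2/ms) so the factorisation always exists."""
    D = vec6_to_tensor(D6)
    w, V = np.linalg.eigh(D)
    w = np.clip(w, lam_min, lam_max)
    Dc = np.einsum("nij,nj,nkj->nik", V, w, V)
    return np.linalg.cholesky(Dc)


def _dual_model_jac(scheme_cache):
    # b-matrices are rank one (b g g^T), so with w = L^T g the tissue
    # exponent is q = b |w|^2 and dq/dL_pq = 2 b g_p w_q -- no (3,3)
    # matrix products needed per voxel/volume.
    g, bvals_s = scheme_cache  # g (V,3) directions, bvals_s (V,)
    Ec = np.exp(-_DCSF_S * bvals_s)  # (V,)

    def fn(theta, want_jac=True):
        s, a, l6 = theta[:, 0], theta[:, 1], theta[:, 2:]
        S0 = np.exp(s)
        f = expit(a)
        L = _chol_from_entries(l6)
        w = np.einsum("va,naq->nvq", g, L)
        q = bvals_s[None, :] * np.einsum("nvq,nvq->nv", w, w)
        Ep = np.exp(-q)
        mix = f[:, None] * Ep + (1.0 - f)[:, None] * Ec[None, :]
        m = S0[:, None] * mix
        if not want_jac:
            return m, None
        J = np.empty(theta.shape[:1] + (bvals_s.size, theta.shape[1]))
        J[:, :, 0] = m
        J[:, :, 1] = (S0 * f * (1.0 - f))[:, None] * (Ep - Ec[None, :])
        pref = -2.0 * (S0 * f)[:, None] * Ep * bvals_s[None, :]
        for k, (i, j) in enumerate(_LOWER):
            J[:, :, 2 + k] = pref * g[None, :, i] * w[:, :, j]
        return m, J

    return fn


def _single_model_jac(scheme_cache):
    g, bvals_s = scheme_cache

    def fn(theta, want_jac=True):
        s, l6 = theta[:, 0], theta[:, 1:]
        S0 = np.exp(s)
        L = _chol_from_entries(l6)
        w = np.einsum("va,naq->nvq", g, L)
        q = bvals_s[None, :] * np.einsum("nvq,nvq->nv", w, w)
        m = S0[:, None] * np.exp(-q)
        if not want_jac:
            return m, None
        J = np.empty(theta.shape[:1] + (bvals_s.size, theta.shape[1]))
        J[:, :, 0] = m
        pref = -2.0 * m * bvals_s[None, :]
        for k, (i, j) in enumerate(_LOWER):
            J[:, :, 1 + k] = pref * g[None, :, i] * w[:, :, j]
        return m, J

    return fn


def _scheme_cache(scheme: GradientScheme):
    return scheme.bvecs, scheme.bvals * _B_SCALE


def _clip_eigs(D6_scaled: np.ndarray, eig_max_s: float = EIG_MAX * _D_SCALE):
    """Spectrally clip (N, 6) scaled tensors into [0, eig_max] eigenvalues."""
    D = vec6_to_tensor(D6_scaled)
    w, V = np.linalg.eigh(D)
    w = np.clip(w, 0.0, eig_max_s)
    return tensor_to_vec6(np.einsum("nij,nj,nkj->nik", V, w, V))


def _fit_single_batch(Y: np.ndarray, scheme: GradientScheme, max_iter=60):
    """NLS single-compartment fit of (N, V) signals.

    Returns (S0, D6 in mm^2/s, rss, converged); log-linear initialisation.
    """
    cache = _scheme_cache(scheme)
    s0_lin, D6_lin = _loglinear_batch(Y, scheme)
    l0 = _entries_from_chol(_safe_chol(D6_lin * _D_SCALE, lam_min=1e-3, lam_max=50.0))
    theta0 = np.column_stack([np.log(s0_lin), l0])
    theta, rss, conv = _levmar(Y, theta0, _single_model_jac(cache), max_iter=max_iter)
    L = _chol_from_entries(theta[:, 1:])
    D6 = tensor_to_vec6(np.einsum("nij,nkj->nik", L, L)) / _D_SCALE
    return np.exp(theta[:, 0]), D6, rss, conv


def _fit_dual_batch(
    Y: np.ndarray,
    scheme: GradientScheme,
    init_grid=_DEFAULT_INIT_GRID,
    max_iter=60,
):
    """Multi-start constrained dual-compartment fit of (N, V) signals.

    Returns (S0, f_par, D6 in mm^2/s, rss, converged). Ties in rss are
    broken toward the larger f_par (the near-single-compartment solution).
    """
    if scheme.shells().size < 2:
        raise ValueError(
            "dual-compartment fitting needs >= 2 distinct nonzero shells to "
            "separate tissue and free-water decay (identifiability)"
        )
    cache = _scheme_cache(scheme)
    N = Y.shape[0]
    s0_lin, D6_lin = _loglinear_batch(Y, scheme)
    l_lin = _entries_from_chol(_safe_chol(D6_lin * _D_SCALE))
    s0_b0 = Y[:, scheme.b0_mask].mean(axis=1)
    s_init = np.log(np.maximum(s0_b0, 1e-12))

    best = None
    for f0 in init_grid:
        a0 = float(logit(np.clip(f0, 1e-3, 1.0 - 1e-3)))
        theta0 = np.column_stack([s_init, np.full(N, a0), l_lin])
        theta, rss, conv = _levmar(Y, theta0, _dual_model_jac(cache), max_iter=max_iter)
        f = expit(theta[:, 1])
        if best is None:
            best = [theta.copy(), rss.copy(), conv.copy(), f.copy()]
        else:
            tol = 1e-9 * (best[1] + 1e-30)
            better = rss < best[1] - tol
            tie = (np.abs(rss - best[1]) <= tol) & (f > best[3])
            take = better | tie
            for arr, new in zip(best, (theta, rss, conv, f)):
                arr[take] = new[take]
    theta, rss, conv, f = best
    L = _chol_from_entries(theta[:, 2:])
    D6s = tensor_to_vec6(np.einsum("nij,nkj->nik", L, L))
    D6 = _clip_eigs(D6s) / _D_SCALE
    s0 = np.exp(theta[:, 0])
    # f_par = 0 boundary candidate: with no parenchymal compartment the
    # model collapses to S0 * exp(-3e-3 b), linear in S0. On a pure
    # free-water voxel the interior fit is degenerate (D_par -> D_CSF makes
    # f_par unidentifiable), so accept the boundary whenever it fits as well.
    Ec = np.exp(-_DCSF_S * (scheme.bvals * _B_SCALE))
    s0_fw = Y @ Ec / float(Ec @ Ec)
    rss_fw = np.einsum("nv,nv->n", Y - s0_fw[:, None] * Ec, Y - s0_fw[:, None] * Ec)
    fw = rss_fw <= rss * (1.0 + 1e-9) + (1e-7 * s0_b0) ** 2
    if fw.any():
        f[fw] = 0.0
        D6[fw] = 0.0
        s0[fw] = s0_fw[fw]
        rss[fw] = rss_fw[fw]
        conv[fw] = True
    # total failure fallback: log-linear tensor, f_par = 1, flagged
    bad = ~conv & ~np.isfinite(rss)
    if bad.any():
        D6[bad] = _clip_eigs(D6_lin[bad] * _D_SCALE) / _D_SCALE
        f[bad] = 1.0
        s0[bad] = s0_lin[bad]
    return s0, f, D6, rss, conv


def fit_single_nls(
    signals: np.ndarray,
    scheme: GradientScheme,
    init: tuple[float, np.ndarray] | None = None,
) -> tuple[float, np.ndarray, float, bool]:
    """Nonlinear single-compartment fit of one voxel.

    Returns (S0, D, rss, converged); on non-convergence the log-linear
    estimate is returned with ``converged=False``.
    """
    Y = np.asarray(signals, dtype=float)[None, :]
    if init is not None:
        cache = _scheme_cache(scheme)
        s0_0, D0 = init
        l0 = _entries_from_chol(
            _safe_chol(tensor_to_vec6(np.asarray(D0))[None] * _D_SCALE,
                       lam_min=1e-4, lam_max=50.0)
        )
        theta0 = np.column_stack([[np.log(s0_0)], l0])
        theta, rss, conv = _levmar(Y, theta0, _single_model_jac(cache), max_iter=100)
        L = _chol_from_entries(theta[:, 1:])
        D6 = tensor_to_vec6(np.einsum("nij,nkj->nik", L, L)) / _D_SCALE
        s0, d6, r, c = np.exp(theta[0, 0]), D6[0], rss[0], conv[0]
    else:
        s0a, D6a, rssa, conva = _fit_single_batch(Y, scheme, max_iter=100)
        s0, d6, r, c = s0a[0], D6a[0], rssa[0], conva[0]
    if not c:
        s0_lin, D_lin = fit_single_loglinear(np.asarray(signals, float), scheme)
        pred = predict_single(s0_lin, D_lin, scheme)
        if np.sum((signals - pred) ** 2) < r:
            return s0_lin, D_lin, float(np.sum((signals - pred) ** 2)), False
    return float(s0), vec6_to_tensor(d6), float(r), bool(c)


def fit_dual_nls(
    signals: np.ndarray,
    scheme: GradientScheme,
    init_grid=_DEFAULT_INIT_GRID,
) -> DualFitVoxel:
    """Constrained dual-compartment fit of one voxel (multi-start NLS)."""
    Y = np.asarray(signals, dtype=float)[None, :]
    s0, f, D6, rss, conv = _fit_dual_batch(Y, scheme, init_grid=init_grid,
                                           max_iter=150)
    return DualFitVoxel(
        s0=float(s0[0]),
        f_par=float(f[0]),
        d_par=vec6_to_tensor(D6[0]),
        rss=float(rss[0]),
        converged=bool(conv[0]),
    )


# --------------------------------------------------------------------------
# whole-volume fitting


def fit_volume(
    dwi: np.ndarray,
    scheme: GradientScheme,
    mask: np.ndarray,
    model: str = "dual",
    init_grid=_DEFAULT_INIT_GRID,
    chunk: int = 4096,
) -> FitResult:
    """Fit every voxel inside ``mask`` and assemble scalar maps.

    ``model='single'`` produces FA and MD; ``model='dual'`` produces pFA,
    pMD (from D_par) and pVF (= f_par). Signals are floored at 1e-6 of the
    per-voxel b0 mean to protect the log-linear initialiser; voxels outside
    the mask are zero in every output and flagged unconverged.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4 or dwi.shape[-1] != scheme.n_volumes:
        raise ValueError(
            f"DWI last axis ({dwi.shape[-1] if dwi.ndim == 4 else 'n/a'}) must "
            f"match the scheme's {scheme.n_volumes} volumes"
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.shape[:3]:
        raise ValueError("mask shape must match the DWI grid")
    shape = dwi.shape[:3]
    n_vox = int(mask.sum())

    s0_out = np.zeros(shape)
    f_out = np.zeros(shape)
    d6_out = np.zeros(shape + (6,))
    rss_out = np.zeros(shape)
    conv_out = np.zeros(shape, dtype=bool)

    if n_vox:
        Y = dwi[mask]
        s0_est = Y[:, scheme.b0_mask].mean(axis=1)
        Y = np.maximum(Y, 1e-6 * np.maximum(s0_est, 1e-12)[:, None])
        s0_all = np.empty(n_vox)
        f_all = np.ones(n_vox)
        d6_all = np.empty((n_vox, 6))
        rss_all = np.empty(n_vox)
        conv_all = np.empty(n_vox, dtype=bool)
        for lo in range(0, n_vox, chunk):
            sl = slice(lo, min(lo + chunk, n_vox))
            if model == "dual":
                s0, f, D6, rss, conv = _fit_dual_batch(
                    Y[sl], scheme, init_grid=init_grid
                )
                f_all[sl] = f
            elif model == "single":
                s0, D6, rss, conv = _fit_single_batch(Y[sl], scheme)
            else:
                raise ValueError(f"unknown model {model!r}")
            s0_all[sl], d6_all[sl] = s0, D6
            rss_all[sl], conv_all[sl] = rss, conv
        s0_out[mask] = s0_all
        d6_out[mask] = d6_all
        rss_out[mask] = rss_all
        conv_out[mask] = conv_all
        f_out[mask] = f_all

    fa_map = np.zeros(shape)
    md_map = np.zeros(shape)
    if n_vox:
        fa_v, md_v = _fa_md_batch(d6_out[mask])
        fa_map[mask] = fa_v
        md_map[mask] = md_v
    if model == "dual":
        maps = {"pFA": fa_map, "pMD": md_map, "pVF": f_out}
    else:
        maps = {"FA": fa_map, "MD": md_map}
    return FitResult(
        maps=maps,
        s0=s0_out,
        tensors=d6_out,
        rss=rss_out,
        converged=conv_out,
        mask=mask,
        model=model,
        f_par=f_out if model == "dual" else None,
    )
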