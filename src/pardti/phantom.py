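"""Synthetic multi-shell DWI cohorts with known ground truth.

The phantom is a schematic "brain" of nested shapes on a shared grid: an
ellipsoidal cerebrum with a white-matter core and a central thalamus, a
posterior-inferior cerebellar sphere with its own WM core, and a brainstem
cylinder, all surrounded by CSF. The geometry is deliberately not
anatomical; each compartment exists so that a specific contrast of the
analysis (focal vs diffuse effects, WM vs GM, CSF-adjacent vs deep tissue)
has a dedicated region.

Ground truth assigns each tissue a parenchymal volume fraction and a
diffusion tensor (anisotropic in WM, near-isotropic in GM, pure free water
in CSF). Patient subjects receive three effects on top of between-subject
jitter: a focal parenchymal-volume drop restricted to CSF-adjacent
cerebellar/brainstem voxels, a diffuse diffusivity (pMD) increase, and a
diffuse WM anisotropy (pFA) decrease. Atrophy is encoded separately as a
smooth radial contraction warp centred on the cerebellum and brainstem.
Signals follow the dual-compartment forward model with Rician noise, the
magnitude-MRI noise distribution; SNR is defined as S0/sigma at b=0 in WM.

The clinical score (SARA, 0-40) is generated from the *truth* cerebellar
CSF-adjacent parenchymal fraction -- not from fitted values -- so that
correlation tests downstream are not circular.

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .gradients import GradientScheme, ImageGrid, build_default_scheme, \
    write_bvalbvec, write_table, write_volume, write_field
from .morphometry import jacobian_determinant
from .tensors import D_CSF, EIG_MAX, tensor_to_vec6, vec6_to_tensor

__all__ = [
    "LABEL_IDS",
    "PhantomLabels",
    "GroundTruth",
    "TissueParams",
    "EffectSpec",
    "CohortConfig",
    "SubjectRecord",
    "CohortDataset",
    "make_phantom_labels",
    "assign_tissue_truth",
    "apply_group_effect",
    "make_atrophy_warp",
    "simulate_dwi",
    "simulate_cohort",
]

LABEL_IDS = {
    "csf": 0,
    "cerebrum-wm": 1,
    "cerebrum-gm": 2,
    "cerebellum-gm": 3,
    "cerebellum-wm": 4,
    "brainstem": 5,
    "thalamus": 6,
}
_WM_REGIONS = ("cerebrum-wm", "cerebellum-wm", "brainstem")
_FOCAL_REGIONS = ("cerebellum-gm", "cerebellum-wm", "brainstem")


@dataclass(frozen=True)
class PhantomLabels:
    """Tissue label map plus the CSF-adjacent ring (6-connectivity)."""

    labels: np.ndarray
    csf_adjacent: np.ndarray
    grid: ImageGrid
    names: dict[str, int] = field(default_factory=lambda: dict(LABEL_IDS))

    def region_mask(self, name: str) -> np.ndarray:
        return self.labels == self.names[name]

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class GroundTruth:
    """Per-voxel generative parameters of the dual-compartment model."""

    f_par: np.ndarray  # (X, Y, Z)
    d_par: np.ndarray  # (X, Y, Z, 6) Voigt, mm^2/s
    labels: PhantomLabels
    n_clipped: int = 0  # voxels clipped into bounds when effects were applied


@dataclass(frozen=True)
class TissueParams:
    """Nominal eigenvalues (mm^2/s), volume fraction, and principal axis."""

    eigvals: tuple[float, float, float]
    f_par: float
    axis: int = 0  # principal diffusion direction: 0=x, 1=y, 2=z


DEFAULT_TISSUE_PARAMS: dict[str, TissueParams] = {
    "csf": TissueParams((1.0e-3, 1.0e-3, 1.0e-3), 0.0),
    "cerebrum-wm": TissueParams((1.5e-3, 0.35e-3, 0.35e-3), 0.95, axis=0),
    "cerebrum-gm": TissueParams((0.8e-3, 0.8e-3, 0.8e-3), 0.90),
    "cerebellum-gm": TissueParams((0.8e-3, 0.8e-3, 0.8e-3), 0.90),
    "cerebellum-wm": TissueParams((1.5e-3, 0.35e-3, 0.35e-3), 0.95, axis=1),
    "brainstem": TissueParams((1.5e-3, 0.35e-3, 0.35e-3), 0.95, axis=2),
    "thalamus": TissueParams((0.8e-3, 0.8e-3, 0.8e-3), 0.90),
}


def make_phantom_labels(shape=(32, 32, 32), seed: int = 0) -> PhantomLabels:
    """Deterministic nested-shapes brain surrounded by CSF.

    All seven regions are guaranteed non-empty at the default 32^3 shape;
    shapes below 24^3 cannot contain them all and raise.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 24:
        raise ValueError(f"phantom shape must be >= 24 per axis, got {shape}")
    nx, ny, nz = shape
    nmin = min(shape)
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )

    def ellipsoid(center, radii):
        cx, cy, cz = center
        rx, ry, rz = radii
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0

    labels = np.zeros(shape, dtype=np.int16)
    cerebrum_c = (0.5 * nx, 0.40 * ny, 0.62 * nz)
    cerebrum_r = (0.38 * nx, 0.33 * ny, 0.30 * nz)
    labels[ellipsoid(cerebrum_c, cerebrum_r)] = LABEL_IDS["cerebrum-gm"]
    labels[ellipsoid(cerebrum_c, tuple(0.62 * r for r in cerebrum_r))] = \
        LABEL_IDS["cerebrum-wm"]
    thal_c = (0.5 * nx, 0.42 * ny, 0.52 * nz)
    labels[ellipsoid(thal_c, (0.09 * nmin,) * 3)] = LABEL_IDS["thalamus"]
    cb_c = (0.5 * nx, 0.76 * ny, 0.30 * nz)
    labels[ellipsoid(cb_c, (0.18 * nmin,) * 3)] = LABEL_IDS["cerebellum-gm"]
    labels[ellipsoid(cb_c, (0.09 * nmin,) * 3)] = LABEL_IDS["cerebellum-wm"]
    stem = (
        ((x - 0.5 * nx) ** 2 + (y - 0.56 * ny) ** 2 <= (0.08 * nmin) ** 2)
        & (z >= 0.08 * nz)
        & (z <= 0.50 * nz)
    )
    labels[stem & (labels == 0)] = LABEL_IDS["brainstem"]

    for name, lid in LABEL_IDS.items():
        if name != "csf" and not np.any(labels == lid):
            raise ValueError(f"phantom region {name!r} is empty at shape {shape}")

    # CSF-adjacent ring: tissue voxels with >=1 face neighbour in CSF
    # (the grid boundary counts as CSF)
    tissue = labels > 0
    struct = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(tissue, structure=struct, border_value=0)
    csf_adjacent = tissue & ~interior
    return PhantomLabels(labels=labels, csf_adjacent=csf_adjacent,
                         grid=ImageGrid(shape))


def _smooth_noise(shape, rng, sigma=2.0):
    """Smooth zero-mean unit-variance random field."""
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    return (raw - raw.mean()) / max(raw.std(), 1e-12)


def _axis_tensor(eigvals, axis) -> np.ndarray:
    """Diagonal tensor with the largest eigenvalue along the given axis."""
    order = np.roll([0, 1, 2], axis)
    lam = np.empty(3)
    lam[order] = eigvals
    return np.diag(lam)


def assign_tissue_truth(
    labels: PhantomLabels,
    tissue_params: dict[str, TissueParams] | None = None,
    jitter: float = 0.05,
    seed: int = 0,
) -> GroundTruth:
    """Per-voxel truth fields from per-tissue nominal parameters.

    A smooth multiplicative jitter field (bounded by ``jitter``) scales the
    eigenvalues (shared across the triple, preserving FA) and perturbs
    f_par; ``jitter=0`` reproduces the nominal values exactly.
    """
    params = dict(DEFAULT_TISSUE_PARAMS)
    if tissue_params:
        params.update(tissue_params)
    for name, tp in params.items():
        if max(tp.eigvals) * (1.0 + jitter) >= EIG_MAX and name != "csf":
            raise ValueError(
                f"tissue {name!r}: eigenvalues with jitter reach the "
                f"{EIG_MAX} mm^2/s parenchymal cap"
            )
    shape = labels.labels.shape
    rng = np.random.default_rng(seed)
    f_par = np.zeros(shape)
    d6 = np.zeros(shape + (6,))
    for name, lid in labels.names.items():
        m = labels.labels == lid
        if not m.any():
            continue
        tp = params[name]
        f_par[m] = tp.f_par
        d6[m] = tensor_to_vec6(_axis_tensor(tp.eigvals, tp.axis))
    if jitter > 0:
        scale = 1.0 + np.clip(jitter * _smooth_noise(shape, rng), -jitter, jitter)
        d6 *= scale[..., None]
        fj = 1.0 + np.clip(jitter * _smooth_noise(shape, rng), -jitter, jitter)
        f_par = np.clip(f_par * fj, 0.0, 1.0)
        f_par[labels.labels == 0] = 0.0
    return GroundTruth(f_par=f_par, d_par=d6, labels=labels)


@dataclass(frozen=True)
class EffectSpec:
    """Group-effect magnitudes (means and between-subject s.d.).

    ``pvf_drop`` applies only at CSF-adjacent cerebellar/brainstem voxels;
    ``pmd_scale`` multiplies diffusivities brain-wide; ``pfa_drop`` lowers
    WM anisotropy brain-wide at preserved MD.
    """

    pvf_drop: float = -0.25
    pvf_drop_sd: float = 0.05
    pmd_scale: float = 0.10
    pmd_scale_sd: float = 0.03
    pfa_drop: float = 0.08
    pfa_drop_sd: float = 0.02


def _reduce_fa(d6: np.ndarray, fa_drop: float) -> np.ndarray:
    """Shrink the deviatoric part of (N, 6) tensors so FA falls by fa_drop
    while MD is preserved."""
    D = vec6_to_tensor(d6)
    w, V = np.linalg.eigh(D)
    m = w.mean(axis=-1)
    dev = w - m[:, None]
    d = np.linalg.norm(dev, axis=-1)
    fa = np.sqrt(1.5) * d / np.sqrt(np.sum(w**2, axis=-1))
    target = np.clip(fa - fa_drop, 0.02, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.sqrt(3.0) * target * m / (d * np.sqrt(1.5 - target**2))
    c = np.where(d > 0, np.minimum(c, 1.0), 1.0)
    w_new = m[:, None] + c[:, None] * dev
    return tensor_to_vec6(np.einsum("nij,nj,nkj->nik", V, w_new, V))


def apply_group_effect(
    truth: GroundTruth, effect_spec: EffectSpec | None = None, seed: int = 0
) -> GroundTruth:
    """Patient truth: focal pVF loss plus diffuse pMD/pFA shifts.

    Per-subject effect sizes are drawn around the spec means; out-of-bound
    parameters are clipped and counted in ``n_clipped``.
    """
    spec = effect_spec or EffectSpec()
    rng = np.random.default_rng(seed)
    labels = truth.labels
    f_par = truth.f_par.copy()
    d6 = truth.d_par.copy()

    d_pvf = rng.normal(spec.pvf_drop, spec.pvf_drop_sd)
    m_scale = 1.0 + rng.normal(spec.pmd_scale, spec.pmd_scale_sd)
    fa_drop = rng.normal(spec.pfa_drop, spec.pfa_drop_sd)

    focal = labels.csf_adjacent & np.isin(
        labels.labels, [labels.names[r] for r in _FOCAL_REGIONS]
    )
    new_f = f_par[focal] + d_pvf
    n_clipped = int(np.sum((new_f < 0) | (new_f > 1)))
    f_par[focal] = np.clip(new_f, 0.0, 1.0)

    wm = np.isin(labels.labels, [labels.names[r] for r in _WM_REGIONS])
    if fa_drop != 0 and wm.any():
        d6[wm] = _reduce_fa(d6[wm], fa_drop)
    tissue = labels.tissue_mask
    d6[tissue] *= max(m_scale, 0.0)
    # keep parenchymal eigenvalues under the free-water cap
    lam = np.linalg.eigvalsh(vec6_to_tensor(d6[tissue]))
    over = lam[:, -1] >= EIG_MAX
    if over.any():
        n_clipped += int(over.sum())
        idx = np.where(tissue)
        sel = tuple(a[over] for a in idx)
        d6[sel] *= (0.999 * EIG_MAX / lam[over, -1])[:, None]
    return GroundTruth(f_par=f_par, d_par=d6, labels=labels,
                       n_clipped=truth.n_clipped + n_clipped)


def make_atrophy_warp(
    labels: PhantomLabels,
    contraction: float = 0.15,
    seed: int = 0,
    jitter: float = 0.0,
    taper_factor: float = 1.5,
) -> np.ndarray:
    """Smooth radial contraction warp centred on cerebellum + brainstem.

    The displacement is ``u(x) = -contraction * (x - c) * w(r) * t(d)``:
    a radial pull toward the region centroid with the compact taper
    ``w(r) = (1 - (r/R)^2)^2`` vanishing at the stated radius
    ``R = taper_factor * r_max`` (r_max = farthest region voxel from the
    centre), further modulated by ``t(d) = (1 - d/d0)^2`` in the distance
    ``d`` to the nearest cerebellar/brainstem voxel (d0 = 4 voxels). The
    proximity factor keeps both the contraction and its compensating
    expansion shell confined to the atrophic region and the CSF around
    it, so distant (deep cerebral) tissue is genuinely untouched.
    ``jitter`` adds a smooth seeded random displacement of that amplitude
    (voxels). The returned field is validated to be invertible (all
    Jacobian determinants positive).
    """
    if not -0.2 <= contraction <= 0.5:
        raise ValueError("contraction must lie in [-0.2, 0.5]")
    region = np.isin(
        labels.labels, [labels.names[r] for r in _FOCAL_REGIONS]
    )
    coords = np.argwhere(region)
    center = coords.mean(axis=0)
    r_max = np.max(np.linalg.norm(coords - center, axis=1))
    R = taper_factor * r_max
    shape = labels.labels.shape
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    dx = np.stack(grids, axis=-1) - center
    r = np.linalg.norm(dx, axis=-1)
    w = np.where(r < R, (1.0 - (r / R) ** 2) ** 2, 0.0)
    d0 = 4.0
    dist = ndimage.distance_transform_edt(~region)
    prox = np.where(dist < d0, (1.0 - dist / d0) ** 2, 0.0)
    u = -contraction * dx * (w * prox)[..., None]
    if jitter > 0:
        rng = np.random.default_rng(seed)
        for i in range(3):
            u[..., i] += jitter * _smooth_noise(shape, rng, sigma=3.0)
    det = jacobian_determinant(u)
    if np.any(det <= 0):
        raise ValueError(
            f"generated warp is not invertible "
            f"({int(np.sum(det <= 0))} voxels with det <= 0)"
        )
    return u


def simulate_dwi(
    truth: GroundTruth,
    scheme: GradientScheme,
    snr: float = 40.0,
    seed: int = 0,
    s0: float = 1000.0,
) -> np.ndarray:
    """Forward-model DWI with Rician noise.

    Noiseless signals come from the dual-compartment model evaluated at the
    truth fields; noise is ``S' = sqrt((S + n1)^2 + n2^2)`` with
    independent N(0, sigma^2) draws, sigma = s0 / snr. ``snr=inf`` returns
    the exact noiseless signal.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    D = vec6_to_tensor(truth.d_par)
    q = np.einsum("vij,...ij->...v", scheme.bmats, D)
    csf_decay = np.exp(-D_CSF * scheme.bvals)
    f = truth.f_par[..., None]
    signal = s0 * (f * np.exp(-q) + (1.0 - f) * csf_decay)
    if np.isinf(snr):
        return signal
    rng = np.random.default_rng(seed)
    sigma = s0 / snr
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the default synthetic cohort."""

    n_hv: int = 14
    n_patients: int = 13
    shape: tuple[int, int, int] = (32, 32, 32)
    snr: float = 40.0
    s0: float = 1000.0
    jitter: float = 0.05
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    contraction: float = 0.15
    contraction_sd: float = 0.03
    hv_contraction_sd: float = 0.02
    sara_intercept: float = 66.0
    sara_slope: float = -80.0  # per unit cerebellar CSF-adjacent mean f_par
    sara_noise_sd: float = 4.7  # tuned for a population r of about -0.65
    age_range: tuple[float, float] = (16.0, 64.0)
    ticv_mean: float = 1.5e6  # mm^3
    ticv_sd: float = 1.2e5
    confounded_age: bool = False  # optional mode: older patients, for
    # covariate-adjustment tests


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "HV" or "SCA7"
    truth: GroundTruth
    warp: np.ndarray
    dwi: np.ndarray


@dataclass
class CohortDataset:
    labels: PhantomLabels
    scheme: GradientScheme
    table: pd.DataFrame
    subjects: list[SubjectRecord]


def _cerebellar_adjacent_mean_fpar(truth: GroundTruth) -> float:
    lab = truth.labels
    m = lab.csf_adjacent & (
        lab.region_mask("cerebellum-gm") | lab.region_mask("cerebellum-wm")
    )
    return float(truth.f_par[m].mean())


def simulate_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    keep_dwi: bool = True,
) -> CohortDataset:
    """Generate the full synthetic cohort: DWI + warp + truth per subject,
    shared labels/scheme, and the clinical table.

    The SARA score of each patient is a noisy negative linear function of
    that subject's *truth* cerebellar CSF-adjacent mean f_par, floored at
    0.5 (symptomatic patients only, matching the exclusion of SARA = 0).
    With ``out_dir`` the dataset is also written to disk (NIfTI + TSV).
    """
    cfg = config or CohortConfig()
    if cfg.n_hv < 3 or cfg.n_patients < 3:
        raise ValueError("need at least 3 subjects per group")
    root = np.random.SeedSequence(seed)
    labels = make_phantom_labels(cfg.shape, seed=seed)
    scheme = build_default_scheme(seed=seed)
    groups = ["HV"] * cfg.n_hv + ["SCA7"] * cfg.n_patients
    n_total = len(groups)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   root.spawn(n_total + 1)]
    meta_rng = np.random.default_rng(child_seeds[-1])

    subjects: list[SubjectRecord] = []
    rows = []
    n_hv_seen = n_pat_seen = 0
    for i, group in enumerate(groups):
        s = child_seeds[i]
        rng = np.random.default_rng(s)
        truth = assign_tissue_truth(labels, jitter=cfg.jitter, seed=s)
        if group == "SCA7":
            n_pat_seen += 1
            sid = f"SCA7{n_pat_seen:02d}"
            truth = apply_group_effect(truth, cfg.effect_spec, seed=s + 1)
            contraction = rng.normal(cfg.contraction, cfg.contraction_sd)
        else:
            n_hv_seen += 1
            sid = f"HV{n_hv_seen:02d}"
            contraction = rng.normal(0.0, cfg.hv_contraction_sd)
        contraction = float(np.clip(contraction, -0.1, 0.45))
        warp = make_atrophy_warp(labels, contraction=contraction, seed=s + 2)
        dwi = simulate_dwi(truth, scheme, snr=cfg.snr, seed=s + 3, s0=cfg.s0)
        dwi = dwi.astype(np.float32)

        age = float(meta_rng.uniform(*cfg.age_range))
        if cfg.confounded_age and group == "SCA7":
            age = float(np.clip(age + 10.0, *cfg.age_range))
        ticv = float(meta_rng.normal(cfg.ticv_mean, cfg.ticv_sd))
        if group == "SCA7":
            cb_fpar = _cerebellar_adjacent_mean_fpar(truth)
            sara = (cfg.sara_intercept + cfg.sara_slope * cb_fpar
                    + meta_rng.normal(0.0, cfg.sara_noise_sd))
            sara = float(np.clip(sara, 0.5, 40.0))
        else:
            sara = np.nan
        rows.append(dict(subject_id=sid, group=group, age=age,
                         ticv=ticv, sara=sara))
        subjects.append(SubjectRecord(
            subject_id=sid, group=group, truth=truth, warp=warp,
            dwi=dwi if keep_dwi else None,
        ))
    table = pd.DataFrame(rows)
    dataset = CohortDataset(labels=labels, scheme=scheme, table=table,
                            subjects=subjects)
    if out_dir is not None:
        _write_cohort(dataset, Path(out_dir))
    return dataset


def _write_cohort(dataset: CohortDataset, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = dataset.labels.grid
    write_volume(out_dir / "labels.nii.gz",
                 dataset.labels.labels.astype(np.int16), grid)
    write_bvalbvec(dataset.scheme, out_dir / "scheme.bval",
                   out_dir / "scheme.bvec")
    write_table(out_dir / "cohort.tsv", dataset.table)
    for rec in dataset.subjects:
        sdir = out_dir / rec.subject_id
        sdir.mkdir(exist_ok=True)
        if rec.dwi is not None:
            write_volume(sdir / "dwi.nii.gz", rec.dwi, grid)
        write_field(sdir / "warp.nii.gz", rec.warp, grid)
        write_volume(sdir / "truth_fpar.nii.gz", rec.truth.f_par, grid)
        write_volume(sdir / "truth_dpar.nii.gz", rec.truth.d_par, grid)
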