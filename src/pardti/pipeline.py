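"""End-to-end group analysis over a (synthetic) cohort.

Order of operations mirrors the analysis design: per-subject dual- and
single-compartment fits produce the scalar maps (pVF, pMD, pFA, FA, MD) on
the shared grid; each subject's warp yields a logJ map; voxel-wise
permutation tests with TFCE compare groups (logJ adjusted for age and
TICV, diffusion metrics for age; anisotropy metrics restricted to the
WM mask, the rest to the whole brain); results are tabulated per atlas
region and, in patients, region means are correlated with SARA under one
FDR family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import run_correlation_analysis
from .morphometry import log_jacobian
from .phantom import CohortDataset
from .reporting import AtlasLabelMap, roi_table, whole_brain_mask, wm_mask
from .stats import StatMapBundle, build_design, permutation_fwe
from .tensors import fit_volume

__all__ = ["GroupAnalysisResult", "compute_subject_maps", "run_group_analysis"]

#: metrics restricted to white matter (template FA > 0.2)
WM_METRICS = ("pFA", "FA")
#: metrics whose group model includes TICV in addition to age
TICV_METRICS = ("logJ",)


@dataclass
class GroupAnalysisResult:
    metric_stacks: dict[str, np.ndarray]
    bundles: dict[str, StatMapBundle]
    tables: dict[str, pd.DataFrame]
    tables_full: dict[str, pd.DataFrame]
    correlations: pd.DataFrame
    brain_mask: np.ndarray
    wm: np.ndarray
    fa_template: np.ndarray


def compute_subject_maps(dataset: CohortDataset) -> dict[str, np.ndarray]:
    """Fit both models and the warp for every subject; stack per metric."""
    labels = dataset.labels
    mask = whole_brain_mask(labels)
    stacks: dict[str, list[np.ndarray]] = {
        m: [] for m in ("pVF", "pMD", "pFA", "FA", "MD", "logJ")
    }
    for rec in dataset.subjects:
        dual = fit_volume(rec.dwi, dataset.scheme, mask, model="dual")
        single = fit_volume(rec.dwi, dataset.scheme, mask, model="single")
        stacks["pVF"].append(dual.maps["pVF"])
        stacks["pMD"].append(dual.maps["pMD"])
        stacks["pFA"].append(dual.maps["pFA"])
        stacks["FA"].append(single.maps["FA"])
        stacks["MD"].append(single.maps["MD"])
        stacks["logJ"].append(log_jacobian(rec.warp))
    return {m: np.stack(v) for m, v in stacks.items()}


def run_group_analysis(
    dataset: CohortDataset,
    n_perm: int = 250,
    alpha: float = 0.05,
    seed: int = 0,
    metrics: tuple[str, ...] = ("pVF", "pMD", "pFA", "FA", "MD", "logJ"),
    min_qvoxels: float = 0.1,
) -> GroupAnalysisResult:
    """Full voxel-wise + ROI + correlation analysis of a cohort."""
    stacks = compute_subject_maps(dataset)
    labels = dataset.labels
    table = dataset.table
    is_hv = (table["group"] == "HV").to_numpy()
    group = (~is_hv).astype(float)
    brain = whole_brain_mask(labels)
    fa_template = stacks["FA"][is_hv].mean(axis=0)
    wm = wm_mask(fa_template, 0.2) & brain

    age = table["age"].to_numpy(dtype=float)
    ticv = table["ticv"].to_numpy(dtype=float)
    atlas = AtlasLabelMap.from_phantom(labels)

    bundles: dict[str, StatMapBundle] = {}
    tables: dict[str, pd.DataFrame] = {}
    tables_full: dict[str, pd.DataFrame] = {}
    for k, metric in enumerate(metrics):
        cov = {"age": age}
        if metric in TICV_METRICS:
            cov["ticv"] = ticv
        design = build_design(group, cov)
        mask = wm if metric in WM_METRICS else brain
        bundle = permutation_fwe(
            stacks[metric], design, mask=mask, n_perm=n_perm, alpha=alpha,
            seed=seed + 17 * (k + 1),
        )
        bundles[metric] = bundle
        sig = bundle.sig_mask | bundle.sig_neg
        tables[metric] = roi_table(
            sig, bundle.t_map, bundle.g_map, atlas,
            min_qvoxels=min_qvoxels, analysis_mask=mask,
        )
        tables_full[metric] = roi_table(
            sig, bundle.t_map, bundle.g_map, atlas,
            min_qvoxels=0.0, analysis_mask=mask,
        )

    region_masks = {
        "brainstem": labels.region_mask("brainstem"),
        "cerebellum": labels.region_mask("cerebellum-gm")
        | labels.region_mask("cerebellum-wm"),
        "cerebrum": labels.region_mask("cerebrum-gm")
        | labels.region_mask("cerebrum-wm")
        | labels.region_mask("thalamus"),
    }
    pat_idx = np.where(~is_hv)[0]
    pat_table = table.iloc[pat_idx].reset_index(drop=True)
    metric_maps = {
        m: stacks[m][pat_idx] for m in ("pMD", "pFA", "pVF", "logJ")
    }
    correlations = run_correlation_analysis(
        metric_maps, region_masks, wm, pat_table,
        include_whole_brain_pfa=True,
    )
    return GroupAnalysisResult(
        metric_stacks=stacks,
        bundles=bundles,
        tables=tables,
        tables_full=tables_full,
        correlations=correlations,
        brain_mask=brain,
        wm=wm,
        fa_template=fa_template,
    )
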