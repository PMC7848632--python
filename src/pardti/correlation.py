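"""Region-mean metric extraction and clinical-score correlation with FDR.

For each patient, each DTI metric (pMD, pFA, pVF, logJ) is averaged over
the brainstem, cerebellum, and cerebrum (pFA only over the WM portion,
FA > 0.2 of the template). Each region mean is correlated with the SARA
ataxia score by Pearson's r, with the two-sided p-value from the
equivalent simple-linear-model slope test. The family of 12 correlations
(4 metrics x 3 regions), plus the optional post-hoc whole-brain pFA
correlation (family of 13), is corrected by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "region_mean",
    "correlate_with_score",
    "fdr_adjust",
    "extract_region_means",
    "run_correlation_analysis",
    "METRICS",
    "REGIONS",
]

METRICS = ("pMD", "pFA", "pVF", "logJ")
REGIONS = ("brainstem", "cerebellum", "cerebrum")


def region_mean(
    map_3d: np.ndarray,
    region_mask: np.ndarray,
    wm_submask: np.ndarray | None = None,
) -> float:
    """Arithmetic mean over the region (optionally intersected with WM)."""
    m = np.asarray(region_mask, dtype=bool)
    if wm_submask is not None:
        m = m & np.asarray(wm_submask, dtype=bool)
    if not m.any():
        raise ValueError("region mask is empty (after WM intersection)")
    return float(np.asarray(map_3d, dtype=float)[m].mean())


def correlate_with_score(
    values: np.ndarray, scores: np.ndarray
) -> tuple[float, float]:
    """Pearson r and its two-sided p (t with n-2 df, the slope test)."""
    values = np.asarray(values, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if values.size != scores.size or values.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if np.ptp(values) == 0 or np.ptp(scores) == 0:
        raise ValueError("correlation undefined for constant input")
    res = sps.pearsonr(values, scores)
    return float(res.statistic), float(res.pvalue)


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def extract_region_means(
    metric_maps: dict[str, np.ndarray],
    region_masks: dict[str, np.ndarray],
    wm_submask: np.ndarray,
    subject_ids: list[str],
    include_whole_brain_pfa: bool = True,
) -> pd.DataFrame:
    """Per-patient table of (metric, region) means.

    ``metric_maps[metric]`` is an (n_patients, X, Y, Z) stack. pFA means
    use only the WM portion of each region; the whole-brain region is the
    union of the three anatomical regions.
    """
    n_pat = len(subject_ids)
    whole = np.zeros(next(iter(region_masks.values())).shape, dtype=bool)
    for m in region_masks.values():
        whole |= m.astype(bool)
    rows = {"subject_id": subject_ids}
    for metric in METRICS:
        if metric not in metric_maps:
            raise ValueError(f"missing metric maps for {metric}")
        stack = np.asarray(metric_maps[metric])
        if stack.shape[0] != n_pat:
            raise ValueError(f"{metric}: subject axis mismatch")
        sub = wm_submask if metric == "pFA" else None
        for region in REGIONS:
            try:
                rows[f"{metric}:{region}"] = [
                    region_mean(stack[i], region_masks[region], sub)
                    for i in range(n_pat)
                ]
            except ValueError as err:
                raise ValueError(f"{metric}:{region}: {err}") from err
        if metric == "pFA" and include_whole_brain_pfa:
            rows["pFA:whole-brain"] = [
                region_mean(stack[i], whole, wm_submask) for i in range(n_pat)
            ]
    return pd.DataFrame(rows)


def run_correlation_analysis(
    metric_maps: dict[str, np.ndarray],
    region_masks: dict[str, np.ndarray],
    wm_submask: np.ndarray,
    cohort: pd.DataFrame,
    include_whole_brain_pfa: bool = True,
    include_asymptomatic: bool = False,
) -> pd.DataFrame:
    """Correlate each (metric, region) mean with SARA across patients.

    ``cohort`` must contain patient rows with a SARA score; metric stacks
    are ordered like those rows. All submitted tests form one FDR family
    (12, or 13 with the whole-brain pFA test), and the family size is
    recorded per row. ``include_asymptomatic`` is the sensitivity mode
    that keeps patients with SARA at the floor instead of excluding them.
    """
    pat = cohort[cohort["group"] != "HV"].reset_index(drop=True)
    if "sara" not in pat.columns:
        raise ValueError("cohort table is missing the 'sara' column")
    if not include_asymptomatic:
        keep = pat["sara"] > 0
    else:
        keep = pat["sara"].notna()
    pat = pat[keep.values].reset_index(drop=True)
    idx = np.where(keep.values)[0]
    maps = {m: np.asarray(v)[idx] for m, v in metric_maps.items()}
    means = extract_region_means(
        maps, region_masks, wm_submask, list(pat["subject_id"]),
        include_whole_brain_pfa=include_whole_brain_pfa,
    )
    sara = pat["sara"].to_numpy(dtype=float)
    tests = [(m, r) for m in METRICS for r in REGIONS]
    if include_whole_brain_pfa:
        tests.append(("pFA", "whole-brain"))
    rows = []
    for metric, region in tests:
        r, p = correlate_with_score(means[f"{metric}:{region}"], sara)
        rows.append(dict(metric=metric, region=region, r=r, p_raw=p,
                         n=len(sara)))
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_adjust(out["p_raw"].to_numpy())
    out["family_size"] = len(tests)
    return out
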