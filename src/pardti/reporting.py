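"""Analysis masks and per-ROI tabulation of voxel-wise results.

Anisotropy metrics (FA, pFA) are only meaningful in white matter, so their
comparisons are restricted to the template voxels with FA strictly greater
than 0.2 (the conventional WM criterion); everything else runs in the
whole-brain (all-tissue) mask. Voxel-wise results are summarised per atlas
region by Qvoxels -- the fraction of the region's voxels that are
significant -- together with the signed peak t and peak Hedge's g (the
values of maximal absolute magnitude over the whole region).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import PhantomLabels

__all__ = [
    "AtlasLabelMap",
    "whole_brain_mask",
    "wm_mask",
    "roi_table",
]


@dataclass(frozen=True)
class AtlasLabelMap:
    """Integer label map plus label -> name lookup."""

    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self):
        if len(set(self.names.values())) != len(self.names):
            raise ValueError("ROI names must be unique")

    @classmethod
    def from_phantom(cls, labels: PhantomLabels) -> "AtlasLabelMap":
        """Use the phantom's tissue regions as the reporting atlas."""
        names = {lid: name for name, lid in labels.names.items() if lid != 0}
        return cls(labels=labels.labels, names=names)


def whole_brain_mask(labels: PhantomLabels) -> np.ndarray:
    """All tissue voxels (everything that is not CSF/background)."""
    mask = labels.tissue_mask
    if not mask.any():
        raise ValueError("whole-brain mask is empty")
    return mask


def wm_mask(fa_template: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Template voxels with FA strictly above the threshold."""
    mask = np.asarray(fa_template, dtype=float) > threshold
    if not mask.any():
        raise ValueError(
            f"WM mask is empty: no template voxel has FA > {threshold}"
        )
    return mask


def _signed_peak(values: np.ndarray) -> float:
    """Signed value of maximal absolute magnitude (first in scan order on ties)."""
    if values.size == 0:
        return float("nan")
    return float(values[np.argmax(np.abs(values))])


def roi_table(
    sig_mask: np.ndarray,
    t_map: np.ndarray,
    g_map: np.ndarray,
    atlas: AtlasLabelMap,
    min_qvoxels: float = 0.1,
    analysis_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-ROI Qvoxels / peak-t / peak-g table, sorted by Qvoxels descending.

    Qvoxels is the number of significant voxels divided by the number of
    ROI voxels inside the analysis mask. Rows with Qvoxels below
    ``min_qvoxels`` are dropped (inclusive at the threshold); pass 0 for
    the complete table. Peaks are taken over the whole in-mask ROI, not
    only its significant part.
    """
    sig_mask = np.asarray(sig_mask, dtype=bool)
    for name, m in (("t_map", t_map), ("g_map", g_map)):
        if np.shape(m) != sig_mask.shape:
            raise ValueError(f"{name} grid does not match sig_mask")
    if atlas.labels.shape != sig_mask.shape:
        raise ValueError("atlas grid does not match the statistic maps")
    if analysis_mask is None:
        analysis_mask = np.ones(sig_mask.shape, dtype=bool)
    rows = []
    for lid, name in atlas.names.items():
        roi = (atlas.labels == lid) & analysis_mask
        n_vox = int(roi.sum())
        if n_vox == 0:
            continue
        n_sig = int((sig_mask & roi).sum())
        rows.append(
            dict(
                roi=name,
                qvoxels=n_sig / n_vox,
                t_peak=_signed_peak(np.asarray(t_map)[roi]),
                g_peak=_signed_peak(np.asarray(g_map)[roi]),
                n_voxels=n_vox,
            )
        )
    df = pd.DataFrame(rows, columns=["roi", "qvoxels", "t_peak", "g_peak",
                                     "n_voxels"])
    df = df.sort_values("qvoxels", ascending=False, kind="stable")
    if min_qvoxels > 0:
        df = df[df["qvoxels"] >= min_qvoxels]
    return df.reset_index(drop=True)
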