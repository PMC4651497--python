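"""Misregistration of non-white-matter tissue onto template white matter.

When a subject's brain is warped to a template, registration error can place
subject gray matter or CSF — both intrinsically low-FA — on template
white-matter voxels, where the voxelwise comparison then flags "abnormally
low FA" that is pure registration artifact. This module builds the
misregistration mask (registered GM ∪ CSF ∩ template WM), expresses it as a
percentage of the template WM volume, and measures how much of each detected
low-FA cluster falls inside it. In subject-based registration the subject is
never resampled, so its misregistration mask is empty by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .grid import GridMismatchError, TissueSegmentation, Volume
from .voxelwise import Cluster

__all__ = [
    "MisregReport",
    "misregistration_mask",
    "misregistration_percent",
    "cluster_overlap_percent",
    "round_half_away",
]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (table convention; 3.85 -> 3.9)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


@dataclass(frozen=True)
class MisregReport:
    """Misregistration counts and percentages for one analysis.

    ``pct_misreg`` = 100 · n_misreg / n_template_wm, to one decimal;
    ``cluster_overlap_pct`` is the percentage of all detected cluster voxels
    lying inside the misregistration mask (None when there are no clusters —
    the ratio is undefined); ``per_cluster_pct`` gives the same per cluster.
    """

    n_template_wm: int
    n_misreg: int
    pct_misreg: float
    cluster_overlap_pct: float | None
    per_cluster_pct: tuple[float, ...]

    def to_json(self, path=None) -> str:
        payload = {
            "n_template_wm": self.n_template_wm,
            "n_misreg": self.n_misreg,
            "pct_misreg": self.pct_misreg,
            "cluster_overlap_pct": self.cluster_overlap_pct,
            "per_cluster_pct": list(self.per_cluster_pct),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def misregistration_mask(
    registered_seg: TissueSegmentation, template_wm: Volume
) -> Volume:
    """(registered GM ∪ registered CSF) ∩ template WM."""
    if not registered_seg.wm.same_grid_as(template_wm):
        raise GridMismatchError("segmentation and template WM must share one grid")
    mis = registered_seg.non_wm.data.astype(bool) & template_wm.data.astype(bool)
    return template_wm.with_data(mis.astype(np.uint8))


def misregistration_percent(mask: Volume, template_wm: Volume) -> float:
    """100 · |mask| / |template WM|, one decimal, half away from zero.

    The denominator is the *template* WM voxel count (the analysis mask),
    not the subject's native WM volume.
    """
    if not mask.same_grid_as(template_wm):
        raise GridMismatchError("mask and template WM must share one grid")
    n_wm = int(np.count_nonzero(template_wm.data))
    if n_wm == 0:
        raise ValueError("template WM mask is empty")
    n_mis = int(np.count_nonzero(mask.data))
    return round_half_away(100.0 * n_mis / n_wm, 1)


def cluster_overlap_percent(
    clusters: list[Cluster], misreg_mask: Volume
) -> tuple[float | None, list[float]]:
    """Percent of cluster voxels inside the misregistration mask.

    Returns ``(overall, per_cluster)``; the overall value is None (undefined,
    reported as N/A) when there are no clusters. Each cluster's
    ``misreg_overlap_pct`` attribute is filled in place.
    """
    mis = misreg_mask.data.astype(bool)
    per = []
    total_vox = 0
    total_in = 0
    for c in clusters:
        inside = int(mis[tuple(c.voxel_indices.T)].sum())
        pct = round_half_away(100.0 * inside / c.size, 1)
        c.misreg_overlap_pct = pct
        per.append(pct)
        total_vox += c.size
        total_in += inside
    if total_vox == 0:
        return None, per
    return round_half_away(100.0 * total_in / total_vox, 1), per


def report(
    registered_seg: TissueSegmentation | None,
    template_wm: Volume,
    clusters: list[Cluster],
) -> MisregReport:
    """Full misregistration report for one analysis.

    ``registered_seg`` is None for the subject of a subject-based analysis
    (never resampled): the mask is empty by construction and every overlap
    percentage is zero.
    """
    n_wm = int(np.count_nonzero(template_wm.data))
    if registered_seg is None:
        mask = template_wm.with_data(np.zeros(template_wm.shape, dtype=np.uint8))
    else:
        mask = misregistration_mask(registered_seg, template_wm)
    overall, per = cluster_overlap_percent(clusters, mask)
    return MisregReport(
        n_template_wm=n_wm,
        n_misreg=int(np.count_nonzero(mask.data)),
        pct_misreg=misregistration_percent(mask, template_wm),
        cluster_overlap_pct=overall,
        per_cluster_pct=tuple(per),
    )
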