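"""Single-subject vs control-group voxelwise testing and cluster extraction.

At every white-matter voxel the subject's FA value ``x`` is compared to the
control sample (mean ``x̄_c``, sd ``s_c``, size ``n``) with the single-case
t statistic

    t = (x − x̄_c) / (s_c · sqrt(1 + 1/n)),   df = n − 1,

the Crawford–Howell form, algebraically the two-sample t with one group of
size one. The test is one-tailed in the low-FA direction (p is the lower
tail of t), because the analysis asks for abnormally *low* anisotropy.
Suprathreshold voxels (p below a voxelwise alpha) are grouped into
connected components, and only components of at least a minimum extent are
reported as clusters. Defaults: alpha 0.005, minimum 100 voxels,
26-connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .grid import GridMismatchError, Volume

__all__ = [
    "StatMap",
    "Cluster",
    "AnalysisParams",
    "defaults",
    "single_case_t_map",
    "extract_clusters",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True, eq=False)
class StatMap:
    """Voxelwise t and one-tailed (lower: low FA) p maps.

    Outside the analysis mask — and at voxels with zero control variance —
    both maps hold NaN and ``valid`` is False; such voxels never enter
    clustering.
    """

    t: Volume
    p: Volume
    valid: np.ndarray
    n_controls: int

    @property
    def df(self) -> int:
        return self.n_controls - 1

    def save(self, prefix) -> None:
        """Write ``<prefix>_tmap.nii.gz`` and ``<prefix>_pmap.nii.gz``."""
        self.t.save(f"{prefix}_tmap.nii.gz")
        self.p.save(f"{prefix}_pmap.nii.gz")


@dataclass(eq=False)
class Cluster:
    """A suprathreshold connected component of the statistic map."""

    voxel_indices: np.ndarray  # (k, 3) int array
    size: int
    peak_t: float  # most negative t in the cluster
    centroid_mm: tuple[float, float, float]
    misreg_overlap_pct: float | None = None  # filled by the misreg module

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.voxel_indices.T)] = True
        return m


@dataclass(frozen=True)
class AnalysisParams:
    """Voxelwise threshold and cluster-extent settings."""

    alpha: float = 0.005
    min_size: int = 100
    connectivity: int = 26

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be one of 6, 18, 26")


def defaults() -> AnalysisParams:
    """Default analysis parameters: alpha 0.005 (one-tailed, low-FA),
    minimum cluster extent 100 voxels, 26-connectivity."""
    return AnalysisParams()


def single_case_t_map(
    subject_fa: Volume, control_fas: list[Volume], mask: Volume
) -> StatMap:
    """Compute the single-case t/p maps inside ``mask``.

    Voxels where the controls have zero variance are flagged invalid rather
    than raising (they occur on synthetic mask borders where every control
    holds the fill value).
    """
    if len(control_fas) < 2:
        raise ValueError("need at least 2 controls")
    for v in (*control_fas, mask):
        if not subject_fa.same_grid_as(v):
            raise GridMismatchError("subject, controls and mask must share one grid")
    m = mask.data.astype(bool)
    if not m.any():
        raise ValueError("analysis mask is empty")
    n = len(control_fas)
    stack = np.stack([np.asarray(v.data, dtype=float)[m] for v in control_fas])
    cmean = stack.mean(axis=0)
    csd = stack.std(axis=0, ddof=1)
    x = np.asarray(subject_fa.data, dtype=float)[m]

    ok = csd > 0
    tvals = np.full(x.shape, np.nan)
    tvals[ok] = (x[ok] - cmean[ok]) / (csd[ok] * np.sqrt(1.0 + 1.0 / n))
    pvals = np.full(x.shape, np.nan)
    pvals[ok] = sps.t.cdf(tvals[ok], df=n - 1)

    t_map = np.full(subject_fa.shape, np.nan, dtype=np.float32)
    p_map = np.full(subject_fa.shape, np.nan, dtype=np.float32)
    valid = np.zeros(subject_fa.shape, dtype=bool)
    t_map[m] = tvals
    p_map[m] = pvals
    valid[m] = ok
    return StatMap(
        t=subject_fa.with_data(t_map),
        p=subject_fa.with_data(p_map),
        valid=valid,
        n_controls=n,
    )


def extract_clusters(
    stat: StatMap,
    mask: Volume,
    alpha: float = 0.005,
    min_size: int = 100,
    connectivity: int = 26,
) -> list[Cluster]:
    """Connected suprathreshold components of at least ``min_size`` voxels.

    Components are built from {valid voxels in mask with p < alpha} under
    the chosen connectivity, retained when size >= min_size ("at least"
    semantics), and sorted by size descending, ties broken by most negative
    peak t and then by lexicographically first voxel.
    """
    params = AnalysisParams(alpha=alpha, min_size=min_size, connectivity=connectivity)
    if stat.p.shape != mask.shape:
        raise GridMismatchError("stat map and mask must share one grid")
    supra = (
        mask.data.astype(bool)
        & stat.valid
        & (np.nan_to_num(stat.p.data, nan=1.0) < params.alpha)
    )
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n_comp = ndimage.label(supra, structure=structure)
    clusters = []
    for lab in range(1, n_comp + 1):
        idx = np.argwhere(labels == lab)
        if idx.shape[0] < params.min_size:
            continue
        tvals = stat.t.data[tuple(idx.T)]
        centroid = stat.t.voxel_to_world(idx.mean(axis=0))
        clusters.append(
            Cluster(
                voxel_indices=idx[np.lexsort(idx.T[::-1])],
                size=int(idx.shape[0]),
                peak_t=float(np.min(tvals)),
                centroid_mm=tuple(float(c) for c in centroid),
            )
        )
    clusters.sort(
        key=lambda c: (-c.size, c.peak_t, tuple(c.voxel_indices[0]))
    )
    return clusters


def clusters_to_label_volume(clusters: list[Cluster], like: Volume) -> Volume:
    """Labelled-cluster image: voxel value = 1-based cluster rank."""
    lab = np.zeros(like.shape, dtype=np.int16)
    for i, c in enumerate(clusters, start=1):
        lab[tuple(c.voxel_indices.T)] = i
    return like.with_data(lab)


def clusters_to_frame(clusters: list[Cluster]):
    """Cluster table with the TSV export columns."""
    import pandas as pd

    rows = [
        dict(
            cluster_id=i,
            size=c.size,
            peak_t=c.peak_t,
            centroid_x=c.centroid_mm[0],
            centroid_y=c.centroid_mm[1],
            centroid_z=c.centroid_mm[2],
            misreg_overlap_pct=(
                float("nan") if c.misreg_overlap_pct is None else c.misreg_overlap_pct
            ),
        )
        for i, c in enumerate(clusters, start=1)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "size", "peak_t",
            "centroid_x", "centroid_y", "centroid_z", "misreg_overlap_pct",
        ],
    )
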