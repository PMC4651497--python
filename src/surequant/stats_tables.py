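"""Paired Wilcoxon signed-rank testing and the packaged cohort tables.

The package ships the original study's four per-patient result tables
(20 mTBI patients, three registration schemes) as TSV fixtures and
recomputes every derived summary from them: cluster-count sums and excesses,
cluster-recovery fractions, voxel-count ratios, misregistration percentages
and cluster/misregistration overlaps. The Wilcoxon signed-rank statistic W
is defined as the sum of the ranks of positive differences after dropping
zero pairs; with all 18 nonzero differences positive this gives
W = 18·19/2 = 171 for the subject-based vs atlas-based cluster-count
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .misreg import round_half_away

__all__ = [
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "load_table",
    "summarize_table1",
    "summarize_table2",
    "summarize_table3",
    "summarize_table4",
    "MNI_TEMPLATE_WM_VOXELS",
    "JHU_TEMPLATE_WM_VOXELS",
]

# Template white-matter voxel counts printed under the misregistration table.
MNI_TEMPLATE_WM_VOXELS = 607633
JHU_TEMPLATE_WM_VOXELS = 567402


@dataclass(frozen=True)
class WilcoxonResult:
    """W = sum of positive-difference ranks; N = nonzero pairs."""

    W: float
    N: int
    p_one_tailed: float
    method: str  # "exact" | "normal-approx-with-tie-correction"

    def __post_init__(self):
        if not (0.0 <= self.W <= self.N * (self.N + 1) / 2):
            raise ValueError("W outside [0, N(N+1)/2]")


def _exact_sf(N: int, w: float) -> float:
    """P(W >= w) for the null signed-rank distribution, integer ranks 1..N.

    Dynamic program over achievable rank sums; valid only without ties.
    """
    counts = np.zeros(N * (N + 1) // 2 + 1)
    counts[0] = 1.0
    for r in range(1, N + 1):
        counts[r:] += counts[:-r].copy()
    total = counts.sum()
    lo = int(np.ceil(w - 1e-9))
    return float(counts[lo:].sum() / total)


def wilcoxon_signed_rank(x, y, alternative: str = "greater") -> WilcoxonResult:
    """Paired signed-rank test of ``d = y − x``.

    Zero differences are dropped; |d| is ranked with average ranks for ties;
    W is the sum of the ranks of positive d. The p-value is exact (full
    sign-assignment enumeration via dynamic programming) when N <= 20 and
    |d| has no ties, otherwise a normal approximation with tie and
    continuity corrections. ``alternative="greater"`` asks whether y tends
    to exceed x (upper tail of W); ``"less"`` the reverse.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1D samples")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    d = y - x
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("no nonzero pairs: all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n

    if n <= 20 and not has_ties:
        p = _exact_sf(n, w) if alternative == "greater" else 1.0 - _exact_sf(n, w + 1)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
        sd = np.sqrt(var)
        # continuity correction toward the mean
        if alternative == "greater":
            p = float(sps.norm.sf((w - 0.5 - mean) / sd))
        else:
            p = float(sps.norm.cdf((w + 0.5 - mean) / sd))
        method = "normal-approx-with-tie-correction"
    return WilcoxonResult(W=w, N=n, p_one_tailed=min(max(p, 0.0), 1.0), method=method)


# ---------------------------------------------------------------------------
# Fixture tables and their derived summaries
# ---------------------------------------------------------------------------

def load_table(which: int) -> pd.DataFrame:
    """Load packaged per-patient table ``which`` in {1, 2, 3, 4}."""
    if which not in (1, 2, 3, 4):
        raise ValueError("table number must be 1, 2, 3 or 4")
    ref = resources.files("surequant.data") / f"table{which}.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", na_values=["N/A"])


def _require_columns(df: pd.DataFrame, cols, which: int) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"table {which} fixture malformed: missing columns {missing}")


def summarize_table1(t1: pd.DataFrame) -> dict:
    """Cluster-count sums, per-subject excesses, recovery fractions.

    Recovery is the percentage of subject-based clusters also found by each
    atlas-based analysis (overlap sum / subject-based sum).
    """
    cols = [
        "clusters_sbr", "clusters_abr_mni", "clusters_abr_jhu",
        "overlap_sbr_mni", "overlap_sbr_jhu", "overlap_mni_jhu",
    ]
    _require_columns(t1, cols, 1)
    n = len(t1)
    sums = {c: int(t1[c].sum()) for c in cols}
    out = {
        "n_patients": n,
        "sum_sbr": sums["clusters_sbr"],
        "sum_abr_mni": sums["clusters_abr_mni"],
        "sum_abr_jhu": sums["clusters_abr_jhu"],
        "sum_overlap_sbr_mni": sums["overlap_sbr_mni"],
        "sum_overlap_sbr_jhu": sums["overlap_sbr_jhu"],
        "sum_overlap_mni_jhu": sums["overlap_mni_jhu"],
        "mean_excess_mni": round_half_away(
            (sums["clusters_abr_mni"] - sums["clusters_sbr"]) / n, 1
        ),
        "mean_excess_jhu": round_half_away(
            (sums["clusters_abr_jhu"] - sums["clusters_sbr"]) / n, 1
        ),
        "subjects_with_sbr_clusters": int((t1["clusters_sbr"] > 0).sum()),
        "subjects_with_abr_mni_clusters": int((t1["clusters_abr_mni"] > 0).sum()),
        "subjects_with_abr_jhu_clusters": int((t1["clusters_abr_jhu"] > 0).sum()),
    }
    if sums["clusters_sbr"] > 0:
        out["recovery_pct_mni"] = round_half_away(
            100.0 * sums["overlap_sbr_mni"] / sums["clusters_sbr"], 1
        )
        out["recovery_pct_jhu"] = round_half_away(
            100.0 * sums["overlap_sbr_jhu"] / sums["clusters_sbr"], 1
        )
    else:
        out["recovery_pct_mni"] = out["recovery_pct_jhu"] = 0.0
    return out


def summarize_table2(t2: pd.DataFrame) -> dict:
    """Voxel-count increases and atlas/subject voxel ratios.

    The "percent more voxels" figure is the mean of the per-subject ratios
    100·(atlas-based voxels / subject-based voxels), restricted to subjects
    with a nonzero subject-based count (the ratio is undefined otherwise);
    note the original wording says "more", but only the plain ratio mean
    reproduces the published magnitudes.
    """
    cols = ["voxels_sbr", "voxels_abr_mni", "voxels_abr_jhu",
            "increase_abr_mni", "increase_abr_jhu"]
    _require_columns(t2, cols, 2)
    pos = t2[t2["voxels_sbr"] > 0]
    out = {
        "n_patients": len(t2),
        "n_sbr_positive": len(pos),
        "mean_increase_mni": round_half_away(float(t2["increase_abr_mni"].mean()), 0),
        "mean_increase_jhu": round_half_away(float(t2["increase_abr_jhu"].mean()), 0),
    }
    for key, col in (("ratio_mean_mni", "voxels_abr_mni"), ("ratio_mean_jhu", "voxels_abr_jhu")):
        ratios = 100.0 * pos[col] / pos["voxels_sbr"]
        out[key] = round_half_away(float(ratios.mean()), 1) if len(pos) else None
    return out


def summarize_table3(
    t3: pd.DataFrame,
    template_wm_mni: int = MNI_TEMPLATE_WM_VOXELS,
    template_wm_jhu: int = JHU_TEMPLATE_WM_VOXELS,
) -> dict:
    """Misregistration percentages: printed-column means and per-row
    recomputation from the raw counts against the template WM volume."""
    cols = ["wm_voxels_patient", "misreg_voxels_abr_mni", "misreg_voxels_abr_jhu",
            "pct_misreg_abr_mni", "pct_misreg_abr_jhu"]
    _require_columns(t3, cols, 3)
    recomputed_mni = [
        round_half_away(100.0 * v / template_wm_mni, 1) for v in t3["misreg_voxels_abr_mni"]
    ]
    recomputed_jhu = [
        round_half_away(100.0 * v / template_wm_jhu, 1) for v in t3["misreg_voxels_abr_jhu"]
    ]
    return {
        "mean_pct_mni": round_half_away(float(t3["pct_misreg_abr_mni"].mean()), 1),
        "mean_pct_jhu": round_half_away(float(t3["pct_misreg_abr_jhu"].mean()), 1),
        "recomputed_pct_mni": recomputed_mni,
        "recomputed_pct_jhu": recomputed_jhu,
        "recomputation_matches_printed": (
            list(t3["pct_misreg_abr_mni"]) == recomputed_mni
            and list(t3["pct_misreg_abr_jhu"]) == recomputed_jhu
        ),
    }


def summarize_table4(t4: pd.DataFrame) -> dict:
    """Cluster/misregistration overlap means; undefined (N/A) rows excluded.

    The subject-based column must be identically zero — the subject is never
    resampled, so none of its cluster voxels can be misregistered.
    """
    cols = ["pct_overlap_sbr", "pct_overlap_abr_mni", "pct_overlap_abr_jhu"]
    _require_columns(t4, cols, 4)
    if not (t4["pct_overlap_sbr"].fillna(-1) == 0).all():
        raise ValueError("subject-based overlap column must be identically zero")
    return {
        "mean_pct_mni": round_half_away(float(t4["pct_overlap_abr_mni"].dropna().mean()), 1),
        "mean_pct_jhu": round_half_away(float(t4["pct_overlap_abr_jhu"].dropna().mean()), 1),
        "n_valid_mni": int(t4["pct_overlap_abr_mni"].notna().sum()),
        "n_valid_jhu": int(t4["pct_overlap_abr_jhu"].notna().sum()),
        "sbr_all_zero": True,
    }


def table1_wilcoxon() -> dict[str, WilcoxonResult]:
    """Cluster-count comparisons on the packaged table: subject-based vs
    each atlas-based analysis (one-tailed, atlas-based greater)."""
    t1 = load_table(1)
    return {
        "sbr_vs_abr_mni": wilcoxon_signed_rank(
            t1["clusters_sbr"], t1["clusters_abr_mni"], "greater"
        ),
        "sbr_vs_abr_jhu": wilcoxon_signed_rank(
            t1["clusters_sbr"], t1["clusters_abr_jhu"], "greater"
        ),
    }
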