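"""Cluster statistics and batch comparisons.

Cluster area is defined as the area of the 2-D convex hull of a cluster's
localizations; clusters with fewer than three (non-collinear) points have
zero hull area, are excluded from area/density summaries, but still count
toward the number of clusters.  The relative density compares the pooled
localization density inside cluster hulls with the density of background
localizations on the remaining ROI area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import ConvexHull, QhullError

from .types import ROI, ValidationError

__all__ = [
    "ClusterStats",
    "hull_area_um2",
    "cluster_statistics",
    "batch_summary",
    "cumulative_area_distribution",
    "compare_groups",
]


def hull_area_um2(xy_nm: np.ndarray) -> float:
    """Convex-hull area of a point set, in µm²; 0 for degenerate sets."""
    if len(xy_nm) < 3:
        return 0.0
    try:
        return float(ConvexHull(xy_nm).volume) / 1e6  # 2-D: volume == area
    except QhullError:  # collinear
        return 0.0


@dataclass(frozen=True)
class ClusterStats:
    """Per-cluster table plus ROI-level summary for one labeling."""

    per_cluster: pd.DataFrame  # label, n_locs, area_um2, density_um2
    n: int
    n_clusters: int
    n_clustered: int
    n_background: int
    percent_clustered: float
    relative_density: float  # NaN when undefined (no hull area or no background)

    @property
    def areas_um2(self) -> np.ndarray:
        """Areas of clusters with a defined (positive) hull, for summaries."""
        a = self.per_cluster["area_um2"].to_numpy()
        return a[a > 0]


def cluster_statistics(table: pd.DataFrame, labels: np.ndarray, roi: ROI) -> ClusterStats:
    """Compute per-cluster and per-ROI statistics for one labeling."""
    labels = np.asarray(labels)
    n = len(table)
    if labels.shape != (n,):
        raise ValidationError("labels length does not match table")
    xy = np.column_stack([table["x_nm"].to_numpy(), table["y_nm"].to_numpy()])
    ids = np.unique(labels[labels > 0])
    rows = []
    for k in ids:
        pts = xy[labels == k]
        area = hull_area_um2(pts)
        rows.append(
            {
                "label": int(k),
                "n_locs": len(pts),
                "area_um2": area,
                "density_um2": len(pts) / area if area > 0 else np.nan,
            }
        )
    per_cluster = pd.DataFrame(rows, columns=["label", "n_locs", "area_um2", "density_um2"])
    n_clustered = int(np.count_nonzero(labels))
    n_background = n - n_clustered
    percent_clustered = 100.0 * n_clustered / n if n else 0.0

    total_area = float(per_cluster["area_um2"].sum()) if len(per_cluster) else 0.0
    free_area = roi.area_um2 - total_area
    if total_area > 0 and n_background > 0 and free_area > 0:
        rel = (n_clustered / total_area) / (n_background / free_area)
    else:
        rel = float("nan")
    return ClusterStats(
        per_cluster=per_cluster,
        n=n,
        n_clusters=len(ids),
        n_clustered=n_clustered,
        n_background=n_background,
        percent_clustered=percent_clustered,
        relative_density=rel,
    )


#: ROI-level metrics summarized across datasets
_BATCH_METRICS = (
    "n_clusters",
    "percent_clustered",
    "relative_density",
    "mean_area_um2",
    "mean_density_um2",
)


def batch_summary(stats_list: list[ClusterStats]) -> tuple[pd.DataFrame, np.ndarray]:
    """Mean ± sd of ROI-level metrics across datasets, plus pooled areas.

    Returns (summary, pooled_areas): summary has one row per metric with
    columns mean/sd/n; pooled_areas concatenates every positive cluster
    area over all datasets (the input for ECDF and violin plots).
    Standard deviations use ddof=0 (population convention; 0 for a single
    dataset).  NaN metrics (e.g. undefined relative density) are ignored.
    """
    if not stats_list:
        raise ValidationError("batch_summary requires at least one dataset")
    per_ds = pd.DataFrame(
        {
            "n_clusters": [s.n_clusters for s in stats_list],
            "percent_clustered": [s.percent_clustered for s in stats_list],
            "relative_density": [s.relative_density for s in stats_list],
            "mean_area_um2": [
                float(np.mean(s.areas_um2)) if len(s.areas_um2) else np.nan
                for s in stats_list
            ],
            "mean_density_um2": [
                float(np.nanmean(s.per_cluster["density_um2"]))
                if len(s.per_cluster) and np.any(s.per_cluster["area_um2"] > 0)
                else np.nan
                for s in stats_list
            ],
        }
    )
    rows = []
    for metric in _BATCH_METRICS:
        vals = per_ds[metric].dropna().to_numpy(dtype=float)
        rows.append(
            {
                "metric": metric,
                "mean": float(np.mean(vals)) if len(vals) else np.nan,
                "sd": float(np.std(vals, ddof=0)) if len(vals) else np.nan,
                "n": len(vals),
            }
        )
    pooled = np.concatenate([s.areas_um2 for s in stats_list]) if stats_list else np.empty(0)
    return pd.DataFrame(rows).set_index("metric"), pooled


def cumulative_area_distribution(groups: dict[str, np.ndarray]) -> dict[str, pd.DataFrame]:
    """Right-continuous ECDF of cluster areas per group.

    Each result frame has columns ``area_um2`` (sorted unique sample
    values) and ``cumulative_fraction`` (fraction of the group's areas
    <= that value; reaches exactly 1 at the maximum).
    """
    out = {}
    for name, areas in groups.items():
        a = np.asarray(areas, dtype=float)
        if a.size == 0:
            raise ValidationError(f"group {name!r} is empty")
        xs = np.unique(a)
        frac = np.searchsorted(np.sort(a), xs, side="right") / a.size
        out[name] = pd.DataFrame({"area_um2": xs, "cumulative_fraction": frac})
    return out


def compare_groups(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p-value across groups."""
    if len(groups) < 2:
        raise ValidationError("compare_groups requires at least two groups")
    samples = []
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size == 0:
            raise ValidationError(f"group {name!r} is empty")
        samples.append(v)
    try:
        h, p = sps.kruskal(*samples)
    except ValueError:
        # all values identical across groups: H = 0, no evidence of difference
        return 0.0, 1.0
    return float(h), float(p)
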