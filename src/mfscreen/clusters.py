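"""Connected-cluster statistics of flagged (H = 0.5, yellow) tiles.

Clusters are connected components of yellow tiles, by default under
8-connectivity (tiles sharing a common edge *or corner*); the
edge-only (4-connectivity) variant is available and always refines the
default partition.  Cohort-level summaries reproduce the per-breast
cluster table: total yellow count, number of clusters and sorted
cluster sizes per (patient, view, side), with column means and
standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ClusterSet",
    "find_clusters",
    "cluster_size_distribution",
    "cohort_table",
]

_STRUCTURES = {
    "edge_or_corner": np.ones((3, 3), dtype=bool),
    "edge_only": np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
}


@dataclass
class ClusterSet:
    """Disjoint connected clusters of flagged tiles (sizes sorted
    descending; their union is the full flagged set)."""

    clusters: list                        # list of frozenset((row, col))
    connectivity: str
    grid_shape: tuple[int, int]
    meta: dict = field(default_factory=dict)

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def largest_size(self) -> int:
        return self.sizes[0] if self.clusters else 0

    @property
    def total(self) -> int:
        return sum(self.sizes)

    def centroid(self, i: int = 0) -> tuple[float, float]:
        pts = np.array(sorted(self.clusters[i]))
        return tuple(pts.mean(axis=0))


def find_clusters(
    grid,
    connectivity: str = "edge_or_corner",
    label: str = "yellow",
) -> ClusterSet:
    """Connected components of flagged tiles.

    ``grid`` is a TileGrid, a class-label array, or a boolean mask.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 'edge_or_corner' or 'edge_only'")
    if hasattr(grid, "class_mask"):
        mask = grid.class_mask(label)
    else:
        arr = np.asarray(grid)
        mask = arr if arr.dtype == bool else (arr == label)
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    clusters = []
    for lab in range(1, n + 1):
        rr, cc = np.nonzero(labels == lab)
        clusters.append(frozenset(zip(rr.tolist(), cc.tolist())))
    clusters.sort(key=lambda c: (-len(c), sorted(c)))
    return ClusterSet(clusters=clusters, connectivity=connectivity, grid_shape=mask.shape)


@dataclass
class SizeDistribution:
    """Pooled cluster-size statistics over a collection of breasts."""

    sizes: np.ndarray                    # pooled, descending
    hist: dict                           # size -> count
    cdf_sizes: np.ndarray
    cdf: np.ndarray                      # P(size <= s)
    largest_per_set: list[int]
    threshold: int
    fraction_above: float                # fraction of clusters with size > threshold

    def fraction_larger_than(self, k: int) -> float:
        if self.sizes.size == 0:
            return 0.0
        return float(np.mean(self.sizes > k))


def cluster_size_distribution(sets, threshold: int = 5) -> SizeDistribution:
    """Pooled histogram/CDF of cluster sizes, the fraction of clusters
    strictly larger than ``threshold``, and each breast's largest
    cluster."""
    sets = list(sets)
    if not sets:
        raise ValueError("need at least one ClusterSet")
    pooled = np.sort(np.concatenate([np.asarray(s.sizes, dtype=int) for s in sets] or [[]]))[::-1]
    vals, cnt = (np.unique(pooled, return_counts=True) if pooled.size else (np.array([]), np.array([])))
    hist = {int(v): int(c) for v, c in zip(vals, cnt)}
    cdf = np.cumsum(cnt) / pooled.size if pooled.size else np.array([])
    frac = float(np.mean(pooled > threshold)) if pooled.size else 0.0
    return SizeDistribution(
        sizes=pooled,
        hist=hist,
        cdf_sizes=vals.astype(int),
        cdf=cdf,
        largest_per_set=[s.largest_size for s in sets],
        threshold=threshold,
        fraction_above=frac,
    )


def cohort_table(per_breast: dict | pd.DataFrame) -> pd.DataFrame:
    """Cohort cluster table with 'Average' and 'St. dev.' rows.

    ``per_breast`` maps (patient, view, side) -> ClusterSet, or is an
    already-tidy DataFrame with columns
    [patient, view, side, total, n_clusters, sizes].

    Output columns: patient, view, side, total, n_clusters, sizes
    (descending list).  Use :func:`cohort_summary` for the per-side
    mean / standard deviation rows.
    """
    if isinstance(per_breast, pd.DataFrame):
        df = per_breast.copy()
    else:
        rows = []
        for (patient, view, side), cs in per_breast.items():
            sizes = sorted(cs.sizes, reverse=True)
            rows.append(dict(patient=patient, view=view, side=side,
                             total=sum(sizes), n_clusters=len(sizes), sizes=sizes))
        df = pd.DataFrame(rows)
    for _, r in df.iterrows():
        if r["total"] != sum(r["sizes"]) or r["n_clusters"] != len(r["sizes"]):
            raise ValueError(f"inconsistent row: {r.to_dict()}")
    return df


def cohort_summary(
    df: pd.DataFrame, ddof: int = 1, exclude_empty_breasts: bool = True
) -> pd.DataFrame:
    """Mean and standard deviation of total, n_clusters and largest
    cluster size per side (CB / CUB).

    ``exclude_empty_breasts`` drops breasts — (patient, side) pairs —
    with no flagged square in *any* view before averaging; a breast
    that shows no uncorrelated squares at all contributes no cluster
    statistics (views of breasts that are empty in only one view are
    kept).
    """
    out = []
    for side, g in df.groupby("side"):
        if exclude_empty_breasts:
            nonzero = g.groupby("patient")["total"].transform("sum") > 0
            g = g[nonzero]
        largest = g["sizes"].apply(lambda s: max(s) if len(s) else 0)
        out.append(dict(
            side=side,
            mean_total=g["total"].mean(),
            sd_total=g["total"].std(ddof=ddof),
            mean_n_clusters=g["n_clusters"].mean(),
            sd_n_clusters=g["n_clusters"].std(ddof=ddof),
            mean_largest=largest.mean(),
            sd_largest=largest.std(ddof=ddof),
            n_breasts=len(g),
        ))
    return pd.DataFrame(out).set_index("side")


def pooled_sizes(df: pd.DataFrame, side: str) -> np.ndarray:
    """All cluster sizes of one side pooled (rows with no clusters
    contribute nothing)."""
    vals: list[int] = []
    for s in df.loc[df["side"] == side, "sizes"]:
        vals.extend(int(v) for v in s)
    return np.asarray(vals, dtype=int)
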