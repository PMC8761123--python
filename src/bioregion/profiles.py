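"""Cluster characterization: shared values, means, areas, dendrograms.

The *shared value* of a variable in a cluster is the cluster's value range
expressed as a percentage of the region-wide range; variables that drove
the separation of a cluster show low shared values, so ranking rows of the
shared-value table flags the locally decisive variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .raster import ClusterMap, RasterGrid, RasterStack

__all__ = [
    "Dendrogram",
    "shared_value",
    "shared_value_table",
    "cluster_means",
    "cluster_area",
    "normalize_profile",
    "hierarchical_cluster",
    "compare_dendrograms",
]

EARTH_RADIUS_KM = 6371.0088


def shared_value(layer: RasterGrid, cmap: ClusterMap, cluster_id: int) -> float:
    """Within-cluster range of a variable as % of the region-wide range.

    Returns NaN (undefined) when the region-wide range is zero; an empty
    cluster or a cluster with no valid pixel of the variable is an error.
    """
    cells = (cmap.labels == cluster_id) & ~layer.nodata_mask
    if not (cmap.labels == cluster_id).any():
        raise ValueError(f"cluster {cluster_id} is empty")
    if not cells.any():
        raise ValueError(f"variable has no valid pixel inside cluster {cluster_id}")
    region = (cmap.labels > 0) & ~layer.nodata_mask
    vals = layer.values.astype(float)
    region_range = vals[region].max() - vals[region].min()
    if region_range == 0:
        return float("nan")
    cluster_range = vals[cells].max() - vals[cells].min()
    return 100.0 * cluster_range / region_range


def shared_value_table(stack: RasterStack, cmap: ClusterMap) -> pd.DataFrame:
    """Variables × clusters table of shared values (percent)."""
    rows = {}
    for code, layer in stack.layers:
        rows[code] = {k: shared_value(layer, cmap, k) for k in cmap.cluster_ids()}
    return pd.DataFrame(rows).T[cmap.cluster_ids()]


def cluster_area(cmap: ClusterMap, geographic: bool | None = None) -> dict[int, float]:
    """Per-cluster area in km².

    For geographic (lat/long, degrees) grids each pixel's area is
    (R·Δlat)·(R·Δlon·cos(lat_center)) with R = 6371.0088 km; for projected
    grids it is pixel_width·|pixel_height| assuming km units.  When
    ``geographic`` is None it is inferred from the CRS label.
    """
    if geographic is None:
        label = cmap.crs_label.lower()
        geographic = any(t in label for t in ("4326", "wgs", "geographic", "longlat", "lat"))
    ox, oy, pw, ph = cmap.geotransform
    rows, _ = cmap.labels.shape
    if geographic:
        lat_centers = np.deg2rad(oy + (np.arange(rows) + 0.5) * ph)
        dlat = np.deg2rad(abs(ph))
        dlon = np.deg2rad(pw)
        row_area = (EARTH_RADIUS_KM * dlat) * (EARTH_RADIUS_KM * dlon * np.cos(lat_centers))
    else:
        row_area = np.full(rows, pw * abs(ph))
    out = {}
    for k in cmap.cluster_ids():
        counts = (cmap.labels == k).sum(axis=1)
        out[k] = float((counts * row_area).sum())
    return out


def cluster_means(stack: RasterStack, cmap: ClusterMap) -> pd.DataFrame:
    """Per-cluster mean of every layer plus pixel count and area (km²).

    Nodata pixels of a layer are excluded from that layer's means; the
    paper-style summary feeds the environmental dendrogram.
    """
    areas = cluster_area(cmap)
    records = []
    for k in cmap.cluster_ids():
        rec: dict = {"cluster": k}
        in_cluster = cmap.labels == k
        for code, layer in stack.layers:
            cells = in_cluster & ~layer.nodata_mask
            rec[code] = float(layer.values[cells].mean()) if cells.any() else np.nan
        rec["pixels"] = int(in_cluster.sum())
        rec["area_km2"] = areas[k]
        records.append(rec)
    return pd.DataFrame(records).set_index("cluster")


def normalize_profile(summary: pd.DataFrame) -> pd.DataFrame:
    """Z-score each variable column across clusters.

    Columns that are constant across clusters carry no contrast and are
    dropped with a warning; bookkeeping columns (pixels, area_km2) are
    ignored.
    """
    cols = [c for c in summary.columns if c not in ("pixels", "area_km2")]
    X = summary[cols].astype(float)
    sd = X.std(axis=0, ddof=0)
    constant = sd.index[sd == 0].tolist()
    if constant:
        warnings.warn(f"dropping constant variable(s) across clusters: {constant}", stacklevel=2)
        X = X.drop(columns=constant)
        sd = sd.drop(constant)
    return (X - X.mean(axis=0)) / sd


@dataclass
class Dendrogram:
    """Agglomerative merge tree with leaf labels and merge heights."""

    merges: list[tuple[int, int, float]]  # scipy convention node ids
    leaves: list[str]
    linkage_name: str
    _Z: np.ndarray | None = None

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def cophenetic_matrix(self) -> pd.DataFrame:
        d = squareform(hierarchy.cophenet(self._Z))
        return pd.DataFrame(d, index=self.leaves, columns=self.leaves)

    def to_newick(self) -> str:
        """Ultrametric Newick string (branch lengths from merge heights)."""
        n = len(self.leaves)
        height = {i: 0.0 for i in range(n)}
        label = {i: self.leaves[i] for i in range(n)}
        for m, (a, b, h) in enumerate(self.merges):
            node = n + m
            bl_a = (h - height[a]) / 2.0
            bl_b = (h - height[b]) / 2.0
            label[node] = f"({label[a]}:{bl_a:g},{label[b]}:{bl_b:g})"
            height[node] = h
        return label[n + len(self.merges) - 1] + ";"


def hierarchical_cluster(data, linkage: str = "complete", metric: str = "euclidean", labels=None) -> Dendrogram:
    """Agglomerative clustering of rows (or of a square distance matrix).

    ``data`` is either an observations × features matrix or a square
    symmetric distance matrix (detected by shape and symmetry).
    """
    if linkage not in ("complete", "average", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if isinstance(data, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in data.index]
        data = data.to_numpy(dtype=float)
    X = np.asarray(data, dtype=float)
    if labels is None:
        labels = [str(i) for i in range(X.shape[0])]
    is_distance = X.ndim == 2 and X.shape[0] == X.shape[1] and np.allclose(X, X.T) and np.allclose(np.diag(X), 0)
    condensed = squareform(X, checks=False) if is_distance else pdist(X, metric=metric)
    Z = hierarchy.linkage(condensed, method=linkage)
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    return Dendrogram(merges=merges, leaves=[str(l) for l in labels], linkage_name=linkage, _Z=Z)


def compare_dendrograms(d1: Dendrogram, d2: Dendrogram) -> float:
    """Cophenetic correlation between two dendrograms over shared leaves.

    Leaves are matched by label; identical trees (up to leaf permutation)
    score 1.0.
    """
    common = [l for l in d1.leaves if l in set(d2.leaves)]
    if len(common) < 3:
        raise ValueError("need at least 3 shared leaves to compare dendrograms")
    c1 = d1.cophenetic_matrix().loc[common, common].to_numpy()
    c2 = d2.cophenetic_matrix().loc[common, common].to_numpy()
    iu = np.triu_indices(len(common), k=1)
    v1, v2 = c1[iu], c2[iu]
    if np.std(v1) == 0 or np.std(v2) == 0:
        return 1.0 if np.allclose(v1, v2) else float("nan")
    return float(pearsonr(v1, v2)[0])
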