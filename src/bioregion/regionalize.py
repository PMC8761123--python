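"""Pixel clustering into environmental regions.

The partitioning follows the classic raster-regionalization recipe:
z-score the variables, choose K by the average silhouette width, run
k-means (Lloyd, best of several k-means++ starts), refine with a
single-observation hill-climbing pass, despeckle the label raster with a
majority filter, and split each cluster into geographically connected
subclusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .raster import ClusterMap, PixelTable

__all__ = [
    "SilhouetteProfile",
    "KmeansResult",
    "SubclusterMap",
    "standardize",
    "mean_silhouette",
    "silhouette_profile",
    "kmeans",
    "hill_climb_refine",
    "labels_to_map",
    "majority_filter",
    "split_subclusters",
]


def _matrix(table) -> np.ndarray:
    if hasattr(table, "matrix"):
        return np.asarray(table.matrix, dtype=float)
    return np.asarray(table, dtype=float)


def standardize(table):
    """Z-score each column; returns (standardized matrix, means, sds).

    Mixing °C, mm, % and W/m² in one Euclidean distance is meaningless
    without this step.  A constant column is an error.
    """
    X = _matrix(table)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(f"constant column(s) at position {bad.tolist()} cannot be standardized")
    return (X - mean) / sd, mean, sd


def mean_silhouette(table, labels) -> float:
    """Mean silhouette width s(i) = (b_i - a_i)/max(a_i, b_i), Euclidean.

    Conventions: a point in a singleton cluster scores 0, and so does a
    point with a_i = b_i = 0 (coincident clusters).  A single cluster is an
    error — the statistic contrasts at least two.
    """
    X = _matrix(table)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    n = X.shape[0]
    D = cdist(X, X)
    s = np.zeros(n)
    sums = np.stack([D[:, labels == k].sum(axis=1) for k in uniq], axis=1)
    counts = np.array([(labels == k).sum() for k in uniq])
    own = np.searchsorted(uniq, labels)
    for i in range(n):
        nk = counts[own[i]]
        if nk == 1:
            continue  # singleton: s = 0
        a = sums[i, own[i]] / (nk - 1)
        other = [sums[i, j] / counts[j] for j in range(uniq.size) if j != own[i]]
        b = min(other)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


@dataclass
class SilhouetteProfile:
    """Average silhouette width per candidate K."""

    entries: dict[int, float]
    k_range: tuple[int, int]
    n_subsample: int
    seed: int

    @property
    def argmax(self) -> int:
        best = max(self.entries.values())
        return min(k for k, v in self.entries.items() if v == best)

    @property
    def local_peaks(self) -> list[int]:
        """Interior K values strictly above both neighbours."""
        ks = sorted(self.entries)
        peaks = []
        for i in range(1, len(ks) - 1):
            v = self.entries[ks[i]]
            if v > self.entries[ks[i - 1]] and v > self.entries[ks[i + 1]]:
                peaks.append(ks[i])
        return peaks

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"k": sorted(self.entries), "mean_silhouette": [self.entries[k] for k in sorted(self.entries)]}
        )


@dataclass
class KmeansResult:
    centroids: np.ndarray
    labels: np.ndarray  # 1..K
    sse: float
    iterations: int
    seed: int
    K: int = field(init=False)

    def __post_init__(self) -> None:
        self.K = self.centroids.shape[0]

    def recompute_sse(self, X: np.ndarray) -> float:
        d = X - self.centroids[self.labels - 1]
        return float((d * d).sum())


def kmeans(table, K: int, seed: int = 0, n_init: int = 10, max_iter: int = 300, tol: float = 1e-6) -> KmeansResult:
    """Best-of-``n_init`` Lloyd runs with k-means++ seeding.

    Labels are reported 1..K; empty clusters are re-seeded internally to
    the farthest points.
    """
    X = _matrix(table)
    if K > X.shape[0]:
        raise ValueError(f"K={K} exceeds the number of observations {X.shape[0]}")
    km = KMeans(n_clusters=K, init="k-means++", n_init=n_init, max_iter=max_iter, tol=tol, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on duplicate points
        km.fit(X)
    labels = km.labels_.astype(int) + 1
    result = KmeansResult(centroids=km.cluster_centers_.copy(), labels=labels, sse=0.0, iterations=int(km.n_iter_), seed=seed)
    result.sse = result.recompute_sse(X)
    return result


def hill_climb_refine(table, result: KmeansResult, max_sweeps: int = 100) -> KmeansResult:
    """Single-observation reassignment until no move lowers the total SSE.

    A move of x from cluster s to t is accepted when the size-corrected
    change Δ = n_t/(n_t+1)·d²(x,c_t) − n_s/(n_s−1)·d²(x,c_s) is negative;
    centroids and counts are updated incrementally.  Moves that would empty
    a cluster are forbidden.  The output SSE never exceeds the input SSE.
    """
    X = _matrix(table)
    K = result.K
    if K == 1:
        return result
    labels0 = result.labels - 1
    labels = labels0.copy()
    centroids = result.centroids.copy()
    counts = np.bincount(labels, minlength=K).astype(float)

    improved = True
    sweeps = 0
    while improved and sweeps < max_sweeps:
        improved = False
        sweeps += 1
        for i in range(X.shape[0]):
            s = labels[i]
            if counts[s] <= 1:
                continue
            d2_i = ((X[i] - centroids) ** 2).sum(axis=1)
            loss_stay = counts[s] / (counts[s] - 1) * d2_i[s]
            gains = counts / (counts + 1) * d2_i
            gains[s] = np.inf
            t = int(np.argmin(gains))
            if gains[t] - loss_stay < -1e-12:
                centroids[t] = (centroids[t] * counts[t] + X[i]) / (counts[t] + 1)
                centroids[s] = (centroids[s] * counts[s] - X[i]) / (counts[s] - 1)
                counts[t] += 1
                counts[s] -= 1
                labels[i] = t
                improved = True

    refined = KmeansResult(centroids=centroids, labels=labels + 1, sse=0.0, iterations=result.iterations + sweeps, seed=result.seed)
    refined.sse = refined.recompute_sse(X)
    if refined.sse > result.sse:  # numerical safety: never accept a worse state
        return result
    return refined


def silhouette_profile(
    table,
    k_min: int = 2,
    k_max: int = 12,
    seed: int = 0,
    n_subsample: int = 10_000,
    n_init: int = 10,
) -> SilhouetteProfile:
    """Average silhouette width over K = k_min..k_max on seeded fits.

    Each K gets a seeded k-means fit on the full table and a silhouette
    evaluation on a seeded subsample (full silhouette is O(n²)).
    """
    X = _matrix(table)
    n = X.shape[0]
    if not (2 <= k_min <= k_max < n):
        raise ValueError(f"need 2 <= k_min <= k_max < n, got ({k_min}, {k_max}), n={n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=min(n_subsample, n), replace=False)
    entries: dict[int, float] = {}
    for K in range(k_min, k_max + 1):
        fit = kmeans(X, K, seed=seed, n_init=n_init)
        sub_labels = fit.labels[idx]
        if np.unique(sub_labels).size < 2:
            entries[K] = -1.0  # degenerate subsample: all one cluster
        else:
            entries[K] = mean_silhouette(X[idx], sub_labels)
    return SilhouetteProfile(entries=entries, k_range=(k_min, k_max), n_subsample=int(idx.size), seed=seed)


def labels_to_map(table: PixelTable, labels) -> ClusterMap:
    """Scatter per-pixel labels (1..K) back onto the grid; nodata stays 0."""
    labels = np.asarray(labels, dtype=np.int32)
    grid = np.zeros(table.shape, dtype=np.int32)
    grid[table.index[:, 0], table.index[:, 1]] = labels
    return ClusterMap(labels=grid, K=int(labels.max()), geotransform=table.geotransform, crs_label=table.crs_label)


def majority_filter(cmap: ClusterMap, window: int = 3, passes: int = 1) -> ClusterMap:
    """Replace each labelled cell by the modal label of its window.

    Nodata cells are excluded from the vote and never relabelled; ties
    retain the original label (and never resurrect a label that lost), so
    single-pixel artifacts disappear without eroding real boundaries.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be an odd positive integer")
    labels = cmap.labels.copy()
    kernel = np.ones((window, window))
    for _ in range(passes):
        counts = np.zeros((cmap.K + 1,) + labels.shape)
        for k in range(1, cmap.K + 1):
            counts[k] = ndimage.correlate((labels == k).astype(float), kernel, mode="constant", cval=0.0)
        counts[0] = -1  # nodata never wins a vote
        best = counts[1:].argmax(axis=0) + 1
        best_count = counts[1:].max(axis=0)
        own_count = np.take_along_axis(counts, labels[None].astype(int), axis=0)[0]
        new = np.where((labels > 0) & (own_count < best_count), best, labels)
        if np.array_equal(new, labels):
            break
        labels = new.astype(np.int32)
    # a cluster made entirely of speckle can vanish; compact surviving labels
    survivors = sorted(set(np.unique(labels)) - {0})
    if survivors != list(range(1, cmap.K + 1)):
        remap = np.zeros(cmap.K + 1, dtype=np.int32)
        for new_id, old_id in enumerate(survivors, start=1):
            remap[old_id] = new_id
        labels = remap[labels]
    return ClusterMap(labels=labels, K=len(survivors), geotransform=cmap.geotransform, crs_label=cmap.crs_label)


@dataclass
class SubclusterMap:
    """Connected components of each cluster, lettered by descending size."""

    labels: np.ndarray  # unique integer id per subcluster, 0 outside
    parent: dict[int, int]  # subcluster id -> cluster id
    names: dict[int, str]  # subcluster id -> e.g. "2a"; unlettered = "2"
    sizes: dict[int, int]
    geotransform: tuple[float, float, float, float]
    crs_label: str = "EPSG:4326"

    def unit_ids(self) -> list[str]:
        return [self.names[i] for i in sorted(self.names)]


def _letters(i: int) -> str:
    # a..z, aa, ab, ... for pathological component counts
    out = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        out = chr(ord("a") + r) + out
    return out


def split_subclusters(cmap: ClusterMap, connectivity: int = 8, min_area_pixels: int = 25) -> SubclusterMap:
    """Split each cluster into connected components ("2a", "2b", ...).

    Components are lettered by descending pixel count; components smaller
    than ``min_area_pixels`` keep their parent's id without a letter (they
    are reported as a single unlettered remainder per cluster).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    out = np.zeros_like(cmap.labels)
    parent: dict[int, int] = {}
    names: dict[int, str] = {}
    sizes: dict[int, int] = {}
    next_id = 1
    for k in cmap.cluster_ids():
        comp, n_comp = ndimage.label(cmap.labels == k, structure=structure)
        comp_sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n_comp + 1))
        order = np.argsort(-comp_sizes, kind="stable")  # descending, stable ties
        remainder_id = None
        letter = 0
        for rank, ci in enumerate(order):
            size = int(comp_sizes[ci])
            cells = comp == (ci + 1)
            if size >= min_area_pixels or n_comp == 1:
                sub = next_id
                next_id += 1
                out[cells] = sub
                parent[sub] = k
                names[sub] = f"{k}{_letters(letter)}" if n_comp > 1 else f"{k}a"
                sizes[sub] = size
                letter += 1
            else:
                if remainder_id is None:
                    remainder_id = next_id
                    next_id += 1
                    parent[remainder_id] = k
                    names[remainder_id] = str(k)
                    sizes[remainder_id] = 0
                out[cells] = remainder_id
                sizes[remainder_id] += size
    return SubclusterMap(
        labels=out,
        parent=parent,
        names=names,
        sizes=sizes,
        geotransform=cmap.geotransform,
        crs_label=cmap.crs_label,
    )
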