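"""Hierarchical clustering on principal components.

Ward agglomeration on the CA row coordinates, automatic cluster-count choice
by the relative within-inertia loss ratio, k-means consolidation initialized
at the tree-cut centroids, and enrichment-direction labelling of clusters
against the contingency table.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .datamodel import ContingencyTable, EnrichmentLabel
from .errors import ConfigurationError, LoadError, ValidationError

__all__ = [
    "ClusterAssignment",
    "ward_tree",
    "choose_k",
    "tree_cut",
    "kmeans_consolidate",
    "label_clusters",
    "hcpc",
    "write_cluster_assignment",
    "read_cluster_assignment",
]


@dataclass
class ClusterAssignment:
    """Variant -> cluster mapping with enrichment labels per cluster."""

    labels: pd.Series  # index: variant keys, values: cluster ids 1..k
    k: int
    cluster_labels: dict[int, EnrichmentLabel] = field(default_factory=dict)
    consolidation_moves: int = 0

    def __post_init__(self) -> None:
        ids = set(self.labels.unique())
        if not ids <= set(range(1, self.k + 1)):
            raise ValidationError(f"cluster ids {sorted(ids)} outside 1..{self.k}")
        if self.k < 1 or self.k > len(self.labels):
            raise ValidationError(f"cluster count {self.k} outside [1, n_points]")
        if self.cluster_labels and set(self.cluster_labels) != set(range(1, self.k + 1)):
            raise ValidationError("enrichment labels must cover every cluster")

    def members(self, cluster_id: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster_id])


def _as_array(coords: Union[pd.DataFrame, np.ndarray]) -> np.ndarray:
    arr = coords.to_numpy() if isinstance(coords, pd.DataFrame) else np.asarray(coords, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr.astype(float)


def ward_tree(coords: Union[pd.DataFrame, np.ndarray]) -> np.ndarray:
    """Full Ward agglomeration (scipy linkage matrix) on Euclidean distances."""
    arr = _as_array(coords)
    if arr.shape[0] < 2:
        raise ValueError("ward_tree needs at least two points")
    return linkage(arr, method="ward")


def _delta(tree: np.ndarray, k: int) -> float:
    """Within-inertia gain of refining k-1 clusters into k.

    Ward merge heights satisfy height^2 / 2 = increase in within-cluster sum
    of squares, so the gain of the cut separating k-1 from k clusters is the
    (n-k)-th merge height squared over two.
    """
    n = tree.shape[0] + 1
    return float(tree[n - k, 2] ** 2 / 2.0)


def choose_k(tree: np.ndarray, k_min: int = 2, k_max: Optional[int] = None) -> int:
    """Cluster count maximizing the relative loss ratio delta(k)/delta(k+1)."""
    n = tree.shape[0] + 1
    if k_max is None:
        k_max = min(10, n - 1)
    k_max = min(k_max, n - 1)
    if k_min > k_max:
        return min(k_min, n)
    if np.allclose(tree[:, 2], 0.0):
        warnings.warn("degenerate tree (all merge heights zero); returning k_min")
        return k_min
    best_k, best_ratio = k_min, -np.inf
    for k in range(k_min, k_max + 1):
        num, den = _delta(tree, k), _delta(tree, k + 1)
        if den == 0.0:
            ratio = np.inf if num > 0 else -np.inf
        else:
            ratio = num / den
        if ratio > best_ratio:
            best_k, best_ratio = k, ratio
    return best_k


def tree_cut(tree: np.ndarray, k: int) -> np.ndarray:
    """Flat cluster ids (1..k) from cutting the Ward tree."""
    return fcluster(tree, t=k, criterion="maxclust")


def _inertia(arr: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    return float(((arr - centroids[labels]) ** 2).sum())


def kmeans_consolidate(
    coords: Union[pd.DataFrame, np.ndarray],
    initial: np.ndarray,
    max_iter: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, int, list[float]]:
    """Lloyd iterations from the tree-cut partition.

    Centroids start at the means of the initial clusters; iteration stops at
    a fixed point or `max_iter`. A cluster emptied mid-iteration keeps its
    previous centroid. Returns (labels 1..k, moves vs initial, inertia trace);
    the trace is nonincreasing.
    """
    arr = _as_array(coords)
    initial = np.asarray(initial, dtype=int)
    if initial.shape[0] != arr.shape[0]:
        raise ConfigurationError("initial assignment must cover every point")
    ids = np.unique(initial)
    k = ids.size
    remap = {cid: j for j, cid in enumerate(ids)}
    labels = np.array([remap[c] for c in initial])
    centroids = np.vstack([arr[labels == j].mean(axis=0) for j in range(k)])
    trace = [_inertia(arr, labels, centroids)]
    for _ in range(max_iter):
        dists = ((arr[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = dists.argmin(axis=1)
        for j in range(k):
            members = new_labels == j
            if members.any():
                centroids[j] = arr[members].mean(axis=0)
            # empty cluster: keep the previous centroid
        trace.append(_inertia(arr, new_labels, centroids))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    moves = int((labels != np.array([remap[c] for c in initial])).sum())
    return labels + 1, moves, trace


def label_clusters(
    labels: Union[pd.Series, np.ndarray],
    table: ContingencyTable,
    consolidation_moves: int = 0,
) -> ClusterAssignment:
    """Attach enrichment directions and renumber clusters.

    Per cluster the means of the three table columns are compared: the
    strictly largest mean decides SENSITIVE_ENRICHED / RESISTANT_ENRICHED,
    ties give NEUTRAL with a warning. Clusters are renumbered by ascending
    mean resistant VAF so ids are convention-stable.
    """
    if isinstance(labels, pd.Series):
        series = labels.astype(int)
    else:
        series = pd.Series(np.asarray(labels, dtype=int), index=table.variant_keys)
    if set(series.index) != set(table.variant_keys):
        raise ConfigurationError("cluster assignment and contingency table cover different variants")
    frame = table.data.loc[series.index]
    means = frame.groupby(series).mean()
    if (series.value_counts() == 0).any():  # pragma: no cover - groupby drops empties
        raise ConfigurationError("every cluster must be nonempty")

    order = means["VAF_resistant"].sort_values(kind="stable").index
    renumber = {old: new for new, old in enumerate(order, start=1)}
    new_series = series.map(renumber)
    means = means.rename(index=renumber).sort_index()

    cluster_labels: dict[int, EnrichmentLabel] = {}
    for cid, row in means.iterrows():
        vals = row[["VAF_sensitive", "VAF_resistant", "MAF_population"]].to_numpy()
        top = vals.max()
        winners = np.flatnonzero(vals == top)
        if winners.size > 1:
            warnings.warn(f"cluster {cid}: tied column means; labelling NEUTRAL")
            cluster_labels[cid] = EnrichmentLabel.NEUTRAL
        elif winners[0] == 0:
            cluster_labels[cid] = EnrichmentLabel.SENSITIVE_ENRICHED
        elif winners[0] == 1:
            cluster_labels[cid] = EnrichmentLabel.RESISTANT_ENRICHED
        else:
            cluster_labels[cid] = EnrichmentLabel.NEUTRAL
    return ClusterAssignment(
        labels=new_series,
        k=len(means),
        cluster_labels=cluster_labels,
        consolidation_moves=consolidation_moves,
    )


def hcpc(
    coords: pd.DataFrame,
    table: ContingencyTable,
    k: Union[int, str] = "auto",
    seed: int = 0,
    max_iter: int = 100,
) -> ClusterAssignment:
    """Ward tree, automatic (or forced) cut, k-means consolidation, labelling."""
    tree = ward_tree(coords)
    k_val = choose_k(tree) if k == "auto" else int(k)
    initial = tree_cut(tree, k_val)
    final, moves, _ = kmeans_consolidate(coords, initial, max_iter=max_iter, seed=seed)
    series = pd.Series(final, index=coords.index)
    return label_clusters(series, table, consolidation_moves=moves)


def write_cluster_assignment(assignment: ClusterAssignment, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# k={assignment.k}\n")
        fh.write(f"# consolidation_moves={assignment.consolidation_moves}\n")
        writer = csv.writer(fh)
        writer.writerow(["variant", "cluster", "label"])
        for key, cid in assignment.labels.items():
            writer.writerow([key, cid, assignment.cluster_labels[cid].value])


def read_cluster_assignment(path) -> ClusterAssignment:
    meta: dict[str, int] = {}
    rows: list[tuple[str, int, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = int(val)
            else:
                reader = csv.reader([line] + fh.readlines())
                header = next(reader)
                if header != ["variant", "cluster", "label"]:
                    raise LoadError(f"{path}: unexpected cluster file header {header}")
                for row in reader:
                    if row:
                        rows.append((row[0], int(row[1]), row[2]))
                break
    labels = pd.Series({v: c for v, c, _ in rows})
    cluster_labels = {c: EnrichmentLabel(l) for _, c, l in rows}
    return ClusterAssignment(
        labels=labels,
        k=meta.get("k", int(labels.max())),
        cluster_labels=cluster_labels,
        consolidation_moves=meta.get("consolidation_moves", 0),
    )
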