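"""Density-based clustering of variants on 1 - r² distance matrices.

Variants in strong mutual LD form dense regions of the 1 - r² metric space;
DBSCAN and HDBSCAN recover them as clusters without fixing their number in
advance, leaving weakly linked variants as noise (label -1).  Cluster quality
is scored with the silhouette coefficient (precomputed distances) and the
Calinski-Harabasz index, and the two clustering parameters are tuned in two
stages: min_samples on a fixed eps, then eps on the winning min_samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import DBSCAN, HDBSCAN
from sklearn.metrics import calinski_harabasz_score, silhouette_score

# Stage-2 eps grid: 0.01 upward in steps of 0.1, with the 1.00 endpoint appended.
EPS_GRID = tuple(np.round(np.arange(0.01, 1.0, 0.1), 2)) + (1.0,)
MIN_SAMPLES_GRID = tuple(range(2, 11))


class SNPClusterer(ClusterMixin, BaseEstimator):
    """Cluster variants from a precomputed 1 - r² distance matrix.

    Parameters
    ----------
    algorithm : {"dbscan", "hdbscan"}
    eps : float
        DBSCAN neighborhood radius, or the HDBSCAN cluster_selection_epsilon
        (distance below which adjacent clusters are merged).  Must be in [0, 1]
        for the 1 - r² metric.
    min_samples : int
        Core-point neighbor threshold (self included).
    min_cluster_size : int or None
        HDBSCAN minimum cluster size; defaults to ``min_samples`` (the two are
        kept equal in this workflow's tuning protocol).

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster label per variant; -1 marks noise.
    """

    def __init__(self, algorithm: str = "dbscan", eps: float = 0.41,
                 min_samples: int = 5, min_cluster_size: int | None = None):
        self.algorithm = algorithm
        self.eps = eps
        self.min_samples = min_samples
        self.min_cluster_size = min_cluster_size

    def fit(self, X, y=None):
        D = np.asarray(X, dtype=np.float64)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("X must be a square precomputed distance matrix")
        if not (0.0 <= self.eps <= 1.0):
            raise ValueError("eps must lie in [0, 1] for 1 - r² distances")
        if self.algorithm == "dbscan":
            if self.min_samples < 2:
                raise ValueError("min_samples must be >= 2")
            model = DBSCAN(eps=self.eps, min_samples=self.min_samples,
                           metric="precomputed")
            self.labels_ = model.fit_predict(D)
        elif self.algorithm == "hdbscan":
            mcs = self.min_cluster_size if self.min_cluster_size is not None else self.min_samples
            if mcs < 2:
                raise ValueError("min_cluster_size must be >= 2")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FutureWarning)
                model = HDBSCAN(min_cluster_size=mcs, min_samples=self.min_samples,
                                metric="precomputed", copy=True)
                labels = model.fit_predict(D)
            # cluster_selection_epsilon semantics: merge clusters whose
            # separation (minimum inter-cluster distance) falls below eps
            if self.eps > 0:
                labels = _merge_close_clusters(D, labels, self.eps)
            self.labels_ = labels
        else:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        return self


def _merge_close_clusters(D: np.ndarray, labels: np.ndarray, eps: float) -> np.ndarray:
    """Single-linkage merge of clusters separated by less than ``eps``."""
    ids = [c for c in np.unique(labels) if c != -1]
    if len(ids) < 2:
        return labels
    parent = {c: c for c in ids}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    members = {c: np.flatnonzero(labels == c) for c in ids}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if find(a) == find(b):
                continue
            if D[np.ix_(members[a], members[b])].min() < eps:
                parent[find(b)] = find(a)
    out = labels.copy()
    remap = {}
    for c in ids:
        root = find(c)
        remap.setdefault(root, len(remap))
        out[labels == c] = remap[root]
    return out


def run_dbscan(dist: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """DBSCAN labels on a precomputed 1 - r² distance matrix (-1 = noise)."""
    return SNPClusterer("dbscan", eps=eps, min_samples=min_samples).fit(dist).labels_


def run_hdbscan(dist: np.ndarray, cluster_selection_epsilon: float,
                min_samples: int, min_cluster_size: int | None = None) -> np.ndarray:
    """HDBSCAN labels on a precomputed distance matrix (-1 = noise)."""
    return SNPClusterer("hdbscan", eps=cluster_selection_epsilon,
                        min_samples=min_samples,
                        min_cluster_size=min_cluster_size).fit(dist).labels_


@dataclass
class ClusterQuality:
    """Internal quality metrics for one clustering of one partition."""

    silhouette: float
    calinski_harabasz: float
    n_clusters: int
    n_clustered: int
    n_noise: int
    valid: bool = True

    @property
    def efficiency(self) -> float:
        """Fraction of variants assigned to any cluster."""
        total = self.n_clustered + self.n_noise
        return self.n_clustered / total if total else 0.0


def evaluate_quality(dist: np.ndarray, labels: np.ndarray) -> ClusterQuality:
    """Silhouette, Calinski-Harabasz, cluster count and clusterization efficiency.

    Noise points are excluded from both metric computations; the
    Calinski-Harabasz index treats each non-noise variant's row of the
    (noise-free) distance matrix as its coordinate vector.  With fewer than
    two clusters the metrics are undefined and the result is flagged invalid.
    """
    labels = np.asarray(labels)
    keep = labels != -1
    n_clustered = int(keep.sum())
    n_noise = int((~keep).sum())
    ids = np.unique(labels[keep])
    if len(ids) < 2:
        return ClusterQuality(np.nan, np.nan, len(ids), n_clustered, n_noise, valid=False)
    sub = dist[np.ix_(keep, keep)]
    sil = silhouette_score(sub, labels[keep], metric="precomputed")
    ch = calinski_harabasz_score(sub, labels[keep])
    return ClusterQuality(float(sil), float(ch), len(ids), n_clustered, n_noise)


def tune_parameters(dist: np.ndarray, algorithm: str = "dbscan"):
    """Two-stage grid tuning of the clustering parameters for one partition.

    Stage 1 fixes eps (or cluster_selection_epsilon) at 0.5 and scans
    min_samples over 2..10; stage 2 fixes the stage-1 winner and scans eps
    over {0.01, 0.11, ..., 0.91, 1.00}.  At each grid point the silhouette
    coefficient is the objective, Calinski-Harabasz the tie-break.  Returns
    ``(best_params, trajectory)`` where trajectory is a DataFrame with one
    row per evaluated grid point (both stages).
    """
    rows = []

    def evaluate(eps, min_samples):
        labels = SNPClusterer(algorithm, eps=eps, min_samples=min_samples).fit(dist).labels_
        q = evaluate_quality(dist, labels)
        rows.append({"stage": len(rows) < len(MIN_SAMPLES_GRID) and 1 or 2,
                     "eps": eps, "min_samples": min_samples,
                     "silhouette": q.silhouette, "calinski_harabasz": q.calinski_harabasz,
                     "n_clusters": q.n_clusters, "efficiency": q.efficiency,
                     "valid": q.valid})
        return q

    def pick(candidates):
        valid = [(p, q) for p, q in candidates if q.valid]
        if not valid:
            return None
        return max(valid, key=lambda pq: (pq[1].silhouette, pq[1].calinski_harabasz))[0]

    stage1 = [((0.5, ms), evaluate(0.5, ms)) for ms in MIN_SAMPLES_GRID]
    best1 = pick([((e, m), q) for (e, m), q in stage1])
    if best1 is None:
        raise RuntimeError("parameter tuning failed: every stage-1 grid point "
                           "produced fewer than two clusters")
    best_ms = best1[1]
    stage2 = [((eps, best_ms), evaluate(eps, best_ms)) for eps in EPS_GRID]
    best2 = pick(stage2)
    if best2 is None:
        raise RuntimeError("parameter tuning failed: every stage-2 grid point "
                           "produced fewer than two clusters")
    traj = pd.DataFrame(rows)
    traj["stage"] = [1] * len(MIN_SAMPLES_GRID) + [2] * len(EPS_GRID)
    params = {"algorithm": algorithm, "eps": float(best2[0]), "min_samples": int(best_ms)}
    if algorithm == "hdbscan":
        params["min_cluster_size"] = int(best_ms)
    return params, traj


def consensus_params(per_partition_params: list[dict]) -> dict:
    """Across-partition best parameters: the most frequent (eps, min_samples)
    pair, ties broken toward smaller eps (denser clusters)."""
    pairs = [(p["eps"], p["min_samples"]) for p in per_partition_params]
    counts = pd.Series(pairs).value_counts()
    top = counts.max()
    winners = sorted([pair for pair, c in counts.items() if c == top])
    eps, ms = winners[0]
    out = dict(per_partition_params[0])
    out["eps"], out["min_samples"] = float(eps), int(ms)
    if "min_cluster_size" in out:
        out["min_cluster_size"] = int(ms)
    return out


def summarize_partitions(qualities: list[ClusterQuality],
                         variant_counts: list[int]) -> pd.DataFrame:
    """Cross-partition z-scores of per-variant-normalized quality metrics.

    Each metric (cluster count, silhouette, Calinski-Harabasz) is first
    divided by the partition's variant count, then standardized across
    partitions as z = (x - mean) / sd with the population (ddof=0) standard
    deviation.  A zero sd yields all-zero z-scores, flagged in ``degenerate``.
    """
    if len(qualities) < 2:
        raise ValueError("z-scores need at least two partitions")
    if len(qualities) != len(variant_counts):
        raise ValueError("qualities and variant_counts length mismatch")
    data = {
        "n_clusters": [q.n_clusters for q in qualities],
        "silhouette": [q.silhouette for q in qualities],
        "calinski_harabasz": [q.calinski_harabasz for q in qualities],
    }
    out = {}
    degenerate = {}
    nvar = np.asarray(variant_counts, dtype=float)
    for name, vals in data.items():
        x = np.asarray(vals, dtype=float) / nvar
        mu, sd = np.nanmean(x), np.nanstd(x)
        if sd == 0 or np.isnan(sd):
            out[f"z_{name}"] = np.zeros_like(x)
            degenerate[name] = True
        else:
            out[f"z_{name}"] = (x - mu) / sd
            degenerate[name] = False
    df = pd.DataFrame(out)
    df.attrs["degenerate"] = degenerate
    return df


def assignment_table(variants: pd.DataFrame, labels: np.ndarray,
                     algorithm: str) -> pd.DataFrame:
    """Exportable per-variant cluster assignment table."""
    return pd.DataFrame({
        "variant_id": variants["id"], "chrom": variants["chrom"],
        "pos": variants["pos"], "algorithm": algorithm, "cluster": labels,
    })
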