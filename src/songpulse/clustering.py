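"""Clustering of per-chunk pulse frequencies.

Best-fit pulse frequencies of one bird's chunks scatter around a handful of
tempi. Agglomerative hierarchical clustering with group-average (UPGMA)
linkage on log10-transformed frequencies groups them; the dominant cluster
defines the bird's characteristic pulse. The log10 transform is chosen via
a regression diagnostic: on the raw Hz scale cluster standard deviation
grows with cluster mean, while on the log10 scale that dependence vanishes,
making one dissimilarity threshold comparable across tempi.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy import stats as sps

__all__ = [
    "FrequencyCluster",
    "cluster_frequencies",
    "largest_cluster",
    "std_vs_mean_regression",
    "clusters_table",
    "TRANSFORMS",
]

TRANSFORMS = {
    "log10": np.log10,
    "loge": np.log,
    "sqrt": np.sqrt,
    "none": lambda x: x,
}


@dataclass(frozen=True)
class FrequencyCluster:
    """One cluster of per-chunk pulse frequencies (reported in Hz)."""

    member_chunks: tuple
    frequencies: tuple[float, ...]
    mean_hz: float
    std_hz: float
    fraction: float

    @property
    def n_members(self) -> int:
        return len(self.frequencies)


def cluster_frequencies(
    freqs: Sequence[float],
    threshold: float = 0.025,
    transform: str = "log10",
    chunk_refs: Sequence | None = None,
) -> list[FrequencyCluster]:
    """Agglomerative UPGMA clustering of pulse frequencies.

    Frequencies are transformed (default log10), merged bottom-up by
    group-average linkage on absolute transformed differences, and the
    dendrogram is cut so that only merges strictly below ``threshold``
    survive. Cluster means and standard deviations are reported in
    untransformed Hz; ``fraction`` is the share of all input frequencies in
    the cluster. Clusters are returned sorted by descending size, then
    ascending mean.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("no frequencies to cluster")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    if transform in ("log10", "loge", "sqrt") and np.any(freqs <= 0):
        raise ValueError(f"non-positive frequency with transform {transform!r}")
    if chunk_refs is None:
        chunk_refs = list(range(freqs.size))
    if len(chunk_refs) != freqs.size:
        raise ValueError("chunk_refs length mismatch")

    x = TRANSFORMS[transform](freqs)
    if freqs.size == 1:
        labels = np.array([1])
    else:
        Z = linkage(x.reshape(-1, 1), method="average", metric="euclidean")
        # fcluster merges at distance <= t; the cut rule is strictly below.
        labels = fcluster(Z, t=np.nextafter(threshold, 0), criterion="distance")

    clusters: list[FrequencyCluster] = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        members = freqs[idx]
        clusters.append(
            FrequencyCluster(
                member_chunks=tuple(chunk_refs[i] for i in idx),
                frequencies=tuple(float(v) for v in members),
                mean_hz=float(np.mean(members)),
                std_hz=float(np.std(members, ddof=1)) if idx.size > 1 else 0.0,
                fraction=idx.size / freqs.size,
            )
        )
    clusters.sort(key=lambda c: (-c.n_members, c.mean_hz))
    return clusters


def largest_cluster(clusters: Sequence[FrequencyCluster]) -> FrequencyCluster:
    """The cluster with the most members; ties go to the lower mean frequency."""
    if not clusters:
        raise ValueError("empty cluster list")
    return min(clusters, key=lambda c: (-c.n_members, c.mean_hz))


def std_vs_mean_regression(
    clusters: Sequence[FrequencyCluster], transform: str = "log10"
) -> tuple[float, float, float, int]:
    """OLS of cluster standard deviation on cluster mean, on the transform scale.

    The diagnostic used to pick the pre-clustering transform: a transform is
    adequate when cluster spread no longer depends on cluster tempo (slope
    near zero, negligible R^2). Only clusters with >= 2 members enter (std
    undefined otherwise). Returns ``(slope, r_squared, p_value, n)`` with the
    standard F-test p-value and ``n`` the number of clusters regressed.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    f = TRANSFORMS[transform]
    means, stds = [], []
    for c in clusters:
        if c.n_members < 2:
            continue
        xs = f(np.asarray(c.frequencies))
        means.append(float(np.mean(xs)))
        stds.append(float(np.std(xs, ddof=1)))
    n = len(means)
    if n < 3:
        raise ValueError(f"need >= 3 clusters with >= 2 members, got {n}")
    res = sps.linregress(means, stds)
    return float(res.slope), float(res.rvalue**2), float(res.pvalue), n


def clusters_table(
    clusters_by_bird: dict[str, Sequence[FrequencyCluster]]
) -> pd.DataFrame:
    """Flatten per-bird clusters into the standard output table."""
    rows = []
    for bird_id, clusters in clusters_by_bird.items():
        for k, c in enumerate(clusters):
            rows.append(
                {
                    "bird_id": bird_id,
                    "cluster_id": k,
                    "n_members": c.n_members,
                    "fraction": c.fraction,
                    "mean_hz": c.mean_hz,
                    "std_hz": c.std_hz,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["bird_id", "cluster_id", "n_members", "fraction", "mean_hz", "std_hz"],
    )
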