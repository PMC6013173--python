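"""k-means partition of transcripts in the (architecture size, BoE) plane.

Three clusters separate tissue-specific transcripts (small architectures,
low BoE), housekeeping transcripts (large architectures, broad expression)
and an atypical group of transcripts with large architectures but low BoE.
Clustering runs on the raw coordinates with Forgy initialization (random
data points as starting centroids) and Lloyd iterations, best of several
restarts by within-cluster sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

SEMANTIC = ("tissue-specific", "housekeeping", "atypical")


@dataclass
class ClusterResult:
    labels: np.ndarray  # semantic label per transcript
    raw_labels: np.ndarray  # 0/1/2
    centroids: np.ndarray  # (3, 2): size, boe
    label_map: dict[int, str]
    inertia: float


def kmeans3(
    size: np.ndarray,
    boe: np.ndarray,
    restarts: int = 10,
    seed: int = 0,
    standardize: bool = False,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Forgy-initialized Lloyd k-means with k = 3, best of ``restarts``.

    Returns (raw labels, centroids in original units, within-cluster SS).
    """
    size = np.asarray(size, dtype=float)
    boe = np.asarray(boe, dtype=float)
    if size.shape != boe.shape or size.ndim != 1 or len(size) < 3:
        raise ValueError("need aligned vectors of length >= 3")
    pts = np.column_stack([size, boe])
    if len(np.unique(pts, axis=0)) < 3:
        raise ValueError("need at least 3 distinct points")
    scale = pts.std(axis=0) if standardize else np.ones(2)
    scale[scale == 0] = 1.0
    km = KMeans(
        n_clusters=3,
        init="random",  # Forgy: centroids start at random data points
        n_init=restarts,
        algorithm="lloyd",
        random_state=np.random.RandomState(seed),
    ).fit(pts / scale)
    centroids = km.cluster_centers_ * scale
    return km.labels_, centroids, float(km.inertia_)


def semantic_labels(
    centroids: np.ndarray, raw_labels: np.ndarray
) -> dict[int, str]:
    """Name the three clusters from their centroids.

    Housekeeping has the highest mean BoE; of the remaining two,
    tissue-specific has the smaller mean architecture size and atypical
    (large architectures without broad expression) is the remainder.
    Ties resolve by cluster index.
    """
    if centroids.shape != (3, 2):
        raise ValueError("expected 3 centroids in 2 dimensions")
    order_boe = np.argsort(-centroids[:, 1], kind="stable")
    housekeeping = int(order_boe[0])
    rest = sorted(set(range(3)) - {housekeeping})
    tissue = min(rest, key=lambda c: (centroids[c, 0], c))
    atypical = (set(rest) - {tissue}).pop()
    return {tissue: "tissue-specific", housekeeping: "housekeeping",
            atypical: "atypical"}


def cluster_transcripts(
    size: np.ndarray,
    boe: np.ndarray,
    restarts: int = 10,
    seed: int = 0,
    standardize: bool = False,
) -> ClusterResult:
    raw, centroids, inertia = kmeans3(size, boe, restarts, seed, standardize)
    label_map = semantic_labels(centroids, raw)
    labels = np.array([label_map[c] for c in raw])
    return ClusterResult(labels, raw, centroids, label_map, inertia)


def anova_f(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """One-way fixed-effects ANOVA F statistic and p-value.

    Zero within-group variance with distinct means yields an infinite F.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 members each")
    if all(np.ptp(g) == 0 for g in groups):
        means = [g.mean() for g in groups]
        if np.ptp(means) > 0:
            return float("inf"), 0.0
        return 0.0, 1.0
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def cluster_summary(
    result: ClusterResult,
    boe: np.ndarray,
    size_variants: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Per-cluster mean and variance of BoE and each architecture-size
    variant, with the one-way ANOVA F per variable."""
    rows = {}
    variables = {"boe": np.asarray(boe, dtype=float)}
    variables.update({k: np.asarray(v, dtype=float)
                      for k, v in size_variants.items()})
    for name, vals in variables.items():
        f_stat, p = anova_f(vals, result.labels)
        for cl in SEMANTIC:
            sel = vals[result.labels == cl]
            rows.setdefault(cl, {})[f"{name}_mean"] = sel.mean()
            rows[cl][f"{name}_var"] = sel.var(ddof=1)
            rows[cl][f"{name}_F"] = f_stat
            rows[cl][f"{name}_p"] = p
        for cl in SEMANTIC:
            rows[cl]["n"] = int((result.labels == cl).sum())
    return pd.DataFrame(rows).T.loc[list(SEMANTIC)]
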