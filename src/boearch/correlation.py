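"""Pairwise TF correlation structure, permutation null, VIF pruning.

Rank correlations between TF columns expose antibody pairs targeting the
same protein and co-binding factors.  Because genomic count data are not a
sample from a population, significance is judged against an empirical null
built by shuffling every TF column across transcripts and pooling all
pairwise correlations; the 2.5 % / 97.5 % order statistics of that pool are
the rejection thresholds.  Variance inflation factors diagnose the
multicollinearity that those correlated pairs induce in regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .types import CountMatrix


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input: rank correlation undefined")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass
class CorrelationTable:
    """All pairwise TF rank correlations with asymptotic p-values and,
    once a permutation null has been attached, significance flags."""

    table: pd.DataFrame  # columns: tf_a, tf_b, rho, p_value [, significant]
    rho_matrix: pd.DataFrame
    constant_columns: list[str]


def _rank_matrix(X: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 0, X)


def _pairwise_rho(X: np.ndarray) -> np.ndarray:
    """Spearman rho matrix via Pearson correlation of mid-ranks."""
    return np.corrcoef(_rank_matrix(X), rowvar=False)


def pairwise_tf_correlations(P: CountMatrix) -> CorrelationTable:
    """Spearman rho and asymptotic two-sided p for every TF pair.

    p-values use the t approximation t = rho * sqrt((M-2)/(1-rho^2)) with
    M-2 degrees of freedom.  Constant columns are excluded and reported.
    """
    if P.shape[1] < 2:
        raise ValueError("need at least two TF columns")
    variances = P.var(axis=0)
    constant = list(P.columns[variances == 0])
    Q = P.drop(columns=constant)
    if Q.shape[1] < 2:
        raise ValueError("fewer than two non-constant columns")
    M = len(Q)
    rho = _pairwise_rho(Q.to_numpy(dtype=float))
    labels = list(Q.columns)
    ii, jj = np.triu_indices(len(labels), k=1)
    r = rho[ii, jj]
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((M - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=M - 2)
    table = pd.DataFrame(
        {"tf_a": [labels[i] for i in ii],
         "tf_b": [labels[j] for j in jj],
         "rho": r,
         "p_value": np.clip(p, np.nextafter(0, 1), 1.0)}
    ).sort_values("rho", ascending=False, ignore_index=True)
    rho_df = pd.DataFrame(rho, index=labels, columns=labels)
    return CorrelationTable(table, rho_df, constant)


@dataclass
class PermutationNull:
    """Pooled null rank correlations from column-wise permutations and the
    empirical two-sided rejection thresholds derived from them."""

    n_permutations: int
    level: float
    null_rhos: np.ndarray
    lower: float
    upper: float
    seed: int


def _nearest_rank_quantile(sorted_values: np.ndarray, q: float) -> float:
    """Deterministic empirical quantile (nearest-rank order statistic)."""
    n = len(sorted_values)
    idx = max(int(np.ceil(q * n)) - 1, 0)
    return float(sorted_values[idx])


def permutation_null(
    P: CountMatrix,
    n_perm: int = 10,
    level: float = 0.05,
    seed: int = 0,
) -> PermutationNull:
    """Null distribution of pairwise rho under transcriptome-wide shuffling.

    Each permutation shuffles every TF column independently across
    transcripts (destroying co-binding but preserving each TF's marginal
    count distribution); all pairwise correlations from all permutations
    are pooled and the level/2 and 1-level/2 nearest-rank quantiles become
    the rejection thresholds.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    X = P.to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    X = X[:, keep]
    M, N = X.shape
    pooled = []
    iu = np.triu_indices(N, k=1)
    for _ in range(n_perm):
        perm = np.empty_like(X)
        for j in range(N):
            perm[:, j] = X[rng.permutation(M), j]
        rho = _pairwise_rho(perm)
        pooled.append(rho[iu])
    null = np.sort(np.concatenate(pooled))
    lower = _nearest_rank_quantile(null, level / 2)
    upper = _nearest_rank_quantile(null, 1 - level / 2)
    return PermutationNull(n_perm, level, null, lower, upper, seed)


def flag_significant(
    corr: CorrelationTable, null: PermutationNull
) -> CorrelationTable:
    """Mark pairs whose rho falls outside the permutation thresholds."""
    t = corr.table.copy()
    t["significant"] = (t["rho"] < null.lower) | (t["rho"] > null.upper)
    return CorrelationTable(t, corr.rho_matrix, corr.constant_columns)


def correlogram_order(rho_matrix: pd.DataFrame) -> list[str]:
    """Leaf order from complete-linkage clustering on distance 1 - rho."""
    R = rho_matrix.to_numpy(dtype=float)
    if R.shape[0] != R.shape[1] or not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("rho matrix must be square and symmetric")
    dist = 1.0 - R
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="complete")
    order = leaves_list(Z)
    return [rho_matrix.columns[i] for i in order]


def vif(P: CountMatrix) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R^2_j) from OLS of
    column j on all other columns plus an intercept.  Exact collinearity is
    reported as +inf."""
    X = P.to_numpy(dtype=float)
    M, N = X.shape
    if M <= N:
        raise ValueError("need more rows than columns")
    if (X.std(axis=0) == 0).any():
        raise ValueError("constant columns have undefined VIF")
    out = np.empty(N)
    ones = np.ones((M, 1))
    for j in range(N):
        y = X[:, j]
        Z = np.hstack([ones, np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, index=P.columns, name="vif")


@dataclass
class VifReport:
    initial: pd.Series
    removal_sequence: list[str]
    final: pd.Series


def prune_collinear(
    P: CountMatrix,
    cutoff: float = 10.0,
    manual_list: list[str] | None = None,
) -> tuple[CountMatrix, VifReport]:
    """Remove collinear columns until every VIF is below the cutoff.

    With ``manual_list`` exactly those columns are removed (the hand-picked
    one-per-correlated-pair mode); otherwise the column with the highest
    VIF is removed greedily and VIFs are recomputed.
    """
    initial = vif(P)
    if manual_list is not None:
        unknown = set(manual_list) - set(P.columns)
        if unknown:
            raise ValueError(f"unknown columns: {sorted(unknown)}")
        pruned = P.drop(columns=list(manual_list))
        return pruned, VifReport(initial, list(manual_list), vif(pruned))
    removed: list[str] = []
    current = P
    vifs = initial
    while (vifs >= cutoff).any():
        if current.shape[1] <= 2:
            raise ValueError("pruning would leave fewer than 2 columns")
        worst = vifs.idxmax()
        removed.append(worst)
        current = current.drop(columns=[worst])
        vifs = vif(current)
    return current, VifReport(initial, removed, vifs)
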