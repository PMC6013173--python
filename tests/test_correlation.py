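"""Correlation statistics: rho, permutation null, correlogram, VIF."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from boearch.correlation import (
    correlogram_order,
    flag_significant,
    pairwise_tf_correlations,
    permutation_null,
    prune_collinear,
    spearman_rho,
    vif,
)


def midrank_oracle(v):
    """Brute-force mid-ranks by sorting (average rank over ties)."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


class TestSpearman:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=50)
        assert spearman_rho(x, x) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        x = np.arange(20.0)
        assert spearman_rho(x, x[::-1]) == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_oracle(self, rng):
        x = rng.integers(0, 4, size=60).astype(float)
        y = rng.integers(0, 4, size=60).astype(float)
        expected = np.corrcoef(midrank_oracle(x), midrank_oracle(y))[0, 1]
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho(np.ones(10), np.arange(10.0))
        with pytest.raises(ValueError):
            spearman_rho(np.arange(2.0), np.arange(2.0))


class TestPairwise:
    def test_duplicated_column(self, rng):
        x = rng.integers(0, 5, size=200)
        P = pd.DataFrame({"A": x, "B": x, "C": rng.integers(0, 5, 200)})
        res = pairwise_tf_correlations(P)
        row = res.table.set_index(["tf_a", "tf_b"]).loc[("A", "B")]
        assert row["rho"] == pytest.approx(1.0)
        assert row["p_value"] < 1e-100

    def test_independent_columns_small_rho(self, rng):
        P = pd.DataFrame(rng.integers(0, 3, size=(5000, 6)),
                         columns=list("ABCDEF"))
        res = pairwise_tf_correlations(P)
        assert (res.table["rho"].abs() < 0.05).all()

    def test_p_value_is_t_approximation(self, rng):
        x = rng.normal(size=100)
        y = x + rng.normal(scale=2.0, size=100)
        P = pd.DataFrame({"A": x, "B": y})
        res = pairwise_tf_correlations(P)
        rho = res.table["rho"].iloc[0]
        t = rho * np.sqrt((100 - 2) / (1 - rho**2))
        expected = 2 * stats.t.sf(abs(t), df=98)
        assert res.table["p_value"].iloc[0] == pytest.approx(expected)

    def test_constant_columns_excluded(self, rng):
        P = pd.DataFrame({"A": rng.integers(0, 3, 50),
                          "B": np.zeros(50, dtype=int),
                          "C": rng.integers(0, 3, 50)})
        res = pairwise_tf_correlations(P)
        assert res.constant_columns == ["B"]
        assert set(res.table["tf_a"]) | set(res.table["tf_b"]) == {"A", "C"}


class TestPermutationNull:
    def test_thresholds_match_normal_approximation_tie_free(self, rng):
        M = 2000
        P = pd.DataFrame(rng.normal(size=(M, 30)),
                         columns=[f"T{j}" for j in range(30)])
        null = permutation_null(P, n_perm=10, seed=0)
        ref = 1.96 / np.sqrt(M - 1)
        assert null.upper == pytest.approx(ref, rel=0.15)
        assert null.lower == pytest.approx(-ref, rel=0.15)
        assert null.lower < 0 < null.upper

    def test_rejection_rate_calibrated(self, rng):
        M = 2000
        P = pd.DataFrame(rng.integers(0, 3, size=(M, 30)),
                         columns=[f"T{j}" for j in range(30)])
        null = permutation_null(P, n_perm=10, seed=1)
        outside = ((null.null_rhos < null.lower)
                   | (null.null_rhos > null.upper)).mean()
        assert abs(outside - 0.05) < 0.02

    def test_planted_pair_flagged(self, rng):
        x = rng.integers(0, 4, size=1000)
        P = pd.DataFrame({"A": x, "B": x,
                          "C": rng.integers(0, 4, 1000),
                          "D": rng.integers(0, 4, 1000)})
        corr = pairwise_tf_correlations(P)
        null = permutation_null(P, n_perm=5, seed=2)
        flagged = flag_significant(corr, null).table.set_index(["tf_a", "tf_b"])
        assert bool(flagged.loc[("A", "B"), "significant"])

    def test_same_seed_identical_thresholds(self, rng):
        P = pd.DataFrame(rng.integers(0, 3, size=(300, 5)))
        P.columns = [f"T{j}" for j in range(5)]
        a = permutation_null(P, n_perm=3, seed=9)
        b = permutation_null(P, n_perm=3, seed=9)
        assert (a.lower, a.upper) == (b.lower, b.upper)


class TestCorrelogram:
    def test_correlated_blocks_are_contiguous(self):
        labels = ["A1", "A2", "B1", "B2"]
        R = np.array([[1.0, 0.9, 0.0, 0.1],
                      [0.9, 1.0, 0.1, 0.0],
                      [0.0, 0.1, 1.0, 0.8],
                      [0.1, 0.0, 0.8, 1.0]])
        order = correlogram_order(pd.DataFrame(R, index=labels, columns=labels))
        pos = {lab: i for i, lab in enumerate(order)}
        assert abs(pos["A1"] - pos["A2"]) == 1
        assert abs(pos["B1"] - pos["B2"]) == 1

    def test_merge_heights_match_manual_complete_linkage(self):
        # manual trace on a 4x4 instance: d = 1 - rho
        R = np.array([[1.0, 0.8, 0.3, 0.2],
                      [0.8, 1.0, 0.4, 0.1],
                      [0.3, 0.4, 1.0, 0.6],
                      [0.2, 0.1, 0.6, 1.0]])
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        D = 1 - R
        np.fill_diagonal(D, 0)
        Z = linkage(squareform(D), method="complete")
        # manual: merge (0,1) at 0.2; merge (2,3) at 0.4;
        # final merge at max cross-distance = 1 - 0.1 = 0.9
        assert Z[0, 2] == pytest.approx(0.2)
        assert Z[1, 2] == pytest.approx(0.4)
        assert Z[2, 2] == pytest.approx(0.9)
        labels = list("abcd")
        order = correlogram_order(pd.DataFrame(R, index=labels, columns=labels))
        assert set(order[:2]) in ({"a", "b"}, {"c", "d"})

    def test_asymmetric_rejected(self):
        R = pd.DataFrame([[1.0, 0.5], [0.4, 1.0]], columns=["a", "b"],
                         index=["a", "b"])
        with pytest.raises(ValueError):
            correlogram_order(R)


class TestVif:
    def test_independent_columns_near_one(self, rng):
        P = pd.DataFrame(rng.normal(size=(2000, 5)),
                         columns=list("ABCDE"))
        assert (vif(P) < 1.05).all()

    def test_near_duplicate_column_explodes(self, rng):
        x = rng.normal(size=500)
        P = pd.DataFrame({"A": x, "B": x + rng.normal(scale=0.05, size=500),
                          "C": rng.normal(size=500)})
        v = vif(P)
        assert v["A"] > 10 and v["B"] > 10 and v["C"] < 2

    def test_matches_normal_equations_oracle(self, rng):
        P = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("ABCDE"))
        P["B"] += 0.5 * P["A"]
        v = vif(P)
        X = P.to_numpy()
        for j, col in enumerate(P.columns):
            y = X[:, j]
            Z = np.hstack([np.ones((200, 1)), np.delete(X, j, axis=1)])
            beta = np.linalg.solve(Z.T @ Z, Z.T @ y)  # normal equations
            r2 = 1 - ((y - Z @ beta) ** 2).sum() / ((y - y.mean()) ** 2).sum()
            assert v[col] == pytest.approx(1 / (1 - r2), rel=1e-9)

    def test_scale_invariance(self, rng):
        P = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("ABCD"))
        scaled = P * np.array([1.0, 10.0, 0.1, 100.0])
        pd.testing.assert_series_equal(vif(P), vif(scaled), atol=1e-8)

    def test_exact_collinearity_is_infinite(self, rng):
        x = rng.normal(size=100)
        P = pd.DataFrame({"A": x, "B": 2 * x, "C": rng.normal(size=100)})
        v = vif(P)
        assert np.isinf(v["A"]) and np.isinf(v["B"])


class TestPrune:
    def test_no_collinearity_identity(self, rng):
        P = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("ABCD"))
        pruned, report = prune_collinear(P, cutoff=10)
        assert list(pruned.columns) == list("ABCD")
        assert report.removal_sequence == []

    def test_duplicated_pair_one_removal(self, rng):
        x = rng.normal(size=500)
        P = pd.DataFrame({"A": x, "B": x + rng.normal(scale=0.02, size=500),
                          "C": rng.normal(size=500),
                          "D": rng.normal(size=500)})
        pruned, report = prune_collinear(P, cutoff=10)
        assert len(report.removal_sequence) == 1
        assert report.removal_sequence[0] in {"A", "B"}
        assert (report.final < 10).all()

    def test_manual_list_mode(self, rng):
        P = pd.DataFrame(rng.normal(size=(300, 5)), columns=list("ABCDE"))
        pruned, report = prune_collinear(P, manual_list=["B", "D"])
        assert list(pruned.columns) == ["A", "C", "E"]
        assert report.removal_sequence == ["B", "D"]

    def test_termination_strictly_reduces_columns(self, rng):
        x = rng.normal(size=400)
        P = pd.DataFrame({"A": x,
                          "B": x + rng.normal(scale=0.01, size=400),
                          "C": x + rng.normal(scale=0.01, size=400),
                          "D": rng.normal(size=400),
                          "E": rng.normal(size=400)})
        pruned, report = prune_collinear(P, cutoff=10)
        assert len(report.removal_sequence) == len(P.columns) - len(pruned.columns)
        assert (report.final < 10).all()
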