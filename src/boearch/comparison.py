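"""Cross-model summaries, random-forest importance, enrichment tests.

The model family (quasibinomial GLM, lasso/ridge/elastic net, Bayesian
GLM, interaction and binary-recode variants) is compared through the
shape of its coefficient vectors (sign fractions, min/max/span), their
pairwise rank correlations, and cross-validated prediction error on the
BoE proportions.  A random forest provides a fully non-linear benchmark
with out-of-bag permutation importance, and a 2x2 Fisher test quantifies
the Pol II enrichment of dual-polymerase promoters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

from .correlation import spearman_rho
from .glm import ZERO_TOL, fit_quasibinomial
from .types import BoEResponse, CountMatrix


def _coef_vector(fit) -> pd.Series:
    if isinstance(fit, pd.Series):
        return fit
    if hasattr(fit, "coefficients"):
        return fit.coefficients
    return pd.Series(np.asarray(fit, dtype=float))


@dataclass
class ModelSummary:
    """Sign fractions and range of one model's coefficient vector
    (intercept excluded)."""

    model_id: str
    frac_positive: float
    frac_negative: float
    frac_zero: float
    minimum: float
    maximum: float

    @property
    def span(self) -> float:
        return self.maximum - self.minimum


def summarize_coefficients(fit, model_id: str = "") -> ModelSummary:
    coefs = _coef_vector(fit).to_numpy(dtype=float)
    if coefs.size == 0:
        raise ValueError("empty coefficient vector")
    zero = np.abs(coefs) < ZERO_TOL
    return ModelSummary(
        model_id=model_id,
        frac_positive=float(((coefs > 0) & ~zero).mean()),
        frac_negative=float(((coefs < 0) & ~zero).mean()),
        frac_zero=float(zero.mean()),
        minimum=float(coefs.min()),
        maximum=float(coefs.max()),
    )


def coefficient_correlations(fits: Mapping[str, object]) -> pd.DataFrame:
    """Pairwise Spearman correlation of coefficient vectors across models,
    computed on the intersection of their term sets."""
    vectors = {name: _coef_vector(f) for name, f in fits.items()}
    shared = None
    for v in vectors.values():
        shared = set(v.index) if shared is None else shared & set(v.index)
    shared = sorted(shared)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared coefficient terms")
    names = list(vectors)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rho = spearman_rho(vectors[a][shared].to_numpy(),
                               vectors[b][shared].to_numpy())
            out.loc[a, b] = out.loc[b, a] = rho
    return out


def cross_validate(
    fit_fn: Callable[[CountMatrix, BoEResponse], object],
    P: CountMatrix,
    response: BoEResponse,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Seeded k-fold MSE of predicted vs observed BoE proportions.

    Fold assignment is stratified by BoE decile so every fold sees the
    full response range; the returned error averages over all transcripts.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    prop = response.boe
    deciles = np.clip((prop * 10).astype(int), 0, 9)
    fold_of = np.empty(len(P), dtype=int)
    for d in np.unique(deciles):
        idx = np.nonzero(deciles == d)[0]
        fold_of[idx] = rng.permutation(len(idx)) % folds
    sq_err = np.empty(len(P))
    for f in range(folds):
        test = fold_of == f
        train = ~test
        fit = fit_fn(P.loc[train], response.subset(np.nonzero(train)[0]))
        pred = fit.predict_proportion(P.loc[test])
        sq_err[test] = (pred - prop[test]) ** 2
    return float(sq_err.mean())


def intercept_only_model(P: CountMatrix, response: BoEResponse):
    """Baseline predictor: the training-set mean proportion everywhere."""

    class _Mean:
        def __init__(self, p):
            self.p = p

        def predict_proportion(self, Q):
            return np.full(len(Q), self.p)

    return _Mean(response.successes.sum() / (response.trials * len(response)))


def random_forest_importance(
    P: CountMatrix,
    boe: np.ndarray,
    n_trees: int = 200,
    seed: int = 0,
    max_features: float = 1 / 3,
) -> pd.Series:
    """Out-of-bag permutation importance, in percent increase of MSE.

    An ensemble of bootstrap regression trees with per-split feature
    subsampling is grown; for each variable, its out-of-bag values are
    permuted and the resulting increase in out-of-bag MSE, relative to the
    unpermuted out-of-bag MSE, is reported (x100).  Uninformative
    variables may come out slightly negative.
    """
    y = np.asarray(boe, dtype=float)
    X = P.to_numpy(dtype=float)
    M, N = X.shape
    rng = np.random.default_rng(seed)
    baseline_sum = 0.0
    delta_sum = np.zeros(N)
    n_oob_trees = 0
    for t in range(n_trees):
        boot = rng.integers(M, size=M)
        oob = np.setdiff1d(np.arange(M), boot, assume_unique=False)
        if len(oob) == 0:
            continue
        tree = DecisionTreeRegressor(
            max_features=max_features,
            random_state=int(rng.integers(2**31)),
        ).fit(X[boot], y[boot])
        X_oob = X[oob]
        y_oob = y[oob]
        mse = float(((tree.predict(X_oob) - y_oob) ** 2).mean())
        baseline_sum += mse
        n_oob_trees += 1
        for j in range(N):
            perm = X_oob.copy()
            perm[:, j] = rng.permutation(perm[:, j])
            mse_perm = float(((tree.predict(perm) - y_oob) ** 2).mean())
            delta_sum[j] += mse_perm - mse
    baseline = baseline_sum / n_oob_trees
    importance = 100.0 * (delta_sum / n_oob_trees) / baseline
    return pd.Series(importance, index=P.columns, name="pct_inc_mse")


@dataclass(frozen=True)
class Contingency2x2:
    """2x2 table: rows = group membership, columns = trait presence."""

    a: int  # group 1, trait present
    b: int  # group 1, trait absent
    c: int  # group 2, trait present
    d: int  # group 2, trait absent

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("counts must be non-negative")
        if all(x == 0 for x in cells):
            raise ValueError("table must not be all zero")


@dataclass
class EnrichmentResult:
    odds_ratio: float
    p_value: float
    method: str


def fisher_enrichment(
    t: Contingency2x2, mc_replicates: int = 0, seed: int = 0
) -> EnrichmentResult:
    """Cross-product odds ratio ad/(bc) with an exact or Monte Carlo
    two-sided independence p-value.

    With ``mc_replicates`` > 0 the p-value is estimated over random tables
    with fixed margins (hypergeometric draws of the top-left cell), the
    standard simulated variant of the exact test.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if b * c == 0:
        odds = float("inf") if a * d > 0 else 0.0
    else:
        odds = (a * d) / (b * c)
    if mc_replicates <= 0:
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        return EnrichmentResult(odds, float(p), "exact")
    rng = np.random.default_rng(seed)
    total = a + b + c + d
    row1, col1 = a + b, a + c
    hg = stats.hypergeom(total, col1, row1)
    obs_pmf = hg.pmf(a)
    draws = rng.hypergeometric(col1, total - col1, row1, size=mc_replicates)
    extreme = hg.pmf(draws) <= obs_pmf * (1 + 1e-7)
    p = (1 + int(extreme.sum())) / (mc_replicates + 1)
    return EnrichmentResult(odds, float(p), "monte-carlo")


@dataclass
class ExpressionControlReport:
    """Coefficient stability after controlling for expression level."""

    rho_vs_default: dict[str, float]
    augmented_fits: dict[str, object]
    default_fit: object


def expression_level_control(
    P: CountMatrix,
    expr: pd.DataFrame,
    response: BoEResponse,
) -> ExpressionControlReport:
    """Refit the quasibinomial GLM with per-transcript mean, median and max
    expression as added covariates; report the Spearman correlation of
    each augmented coefficient vector with the default one."""
    expr = expr.loc[P.index]
    default = fit_quasibinomial(P, response)
    covs = {
        "mean": expr.mean(axis=1),
        "median": expr.median(axis=1),
        "max": expr.max(axis=1),
    }
    rhos: dict[str, float] = {}
    fits: dict[str, object] = {}
    for name, cov in covs.items():
        Q = P.copy()
        Q[f"expr_{name}"] = cov.to_numpy()
        fit = fit_quasibinomial(Q, response)
        fits[name] = fit
        shared = list(P.columns)
        rhos[name] = spearman_rho(default.coefficients[shared].to_numpy(),
                                  fit.coefficients[shared].to_numpy())
    return ExpressionControlReport(rhos, fits, default)
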