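"""Binomial-response models of BoE: quasibinomial GLM and penalized paths.

The response is (successes, trials) per transcript with a logit link; the
linear predictor is built from per-promoter TF site counts.  Dispersion is
left free (quasi-likelihood): the Pearson chi-squared estimate scales the
standard errors, compensating for the overdispersion genomic proportion
data show relative to a pure binomial.  Penalized variants (lasso, ridge,
elastic net) trace a coefficient path over a decreasing lambda grid and
pick lambda by cross-validated mean squared error on the BoE proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .types import BoEResponse, CountMatrix

INTERCEPT = "(Intercept)"
ZERO_TOL = 1e-8


def inverse_logit(x):
    """1 / (1 + exp(-x)), numerically stable for large |x|."""
    return expit(x)


@dataclass
class GlmFit:
    """Quasibinomial fit: coefficients on the logit scale, dispersion-scaled
    standard errors and t-reference p-values, plus deviances."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    dispersion: float
    null_deviance: float
    deviance: float
    df_resid: int
    converged: bool
    separation_terms: list[str] = field(default_factory=list)

    @property
    def intercept(self) -> float:
        return float(self.params[INTERCEPT])

    @property
    def coefficients(self) -> pd.Series:
        return self.params.drop(INTERCEPT)

    def predict_proportion(self, P: CountMatrix) -> np.ndarray:
        X = P[self.coefficients.index].to_numpy(dtype=float)
        return expit(self.intercept + X @ self.coefficients.to_numpy())


def _align(P: CountMatrix, response: BoEResponse) -> None:
    if len(P) != len(response):
        raise ValueError("matrix rows and response length differ")


def _endog(response: BoEResponse) -> np.ndarray:
    k = response.successes
    return np.column_stack([k, response.trials - k])


def _design(P: CountMatrix) -> tuple[np.ndarray, list[str]]:
    X = P.to_numpy(dtype=float)
    exog = np.hstack([np.ones((len(P), 1)), X])
    return exog, [INTERCEPT] + list(P.columns)


# |coefficient| beyond which a logit-scale estimate is treated as evidence
# of separation (probabilities pinned at 0/1)
_SEPARATION_BOUND = 15.0


def fit_quasibinomial(
    P: CountMatrix,
    response: BoEResponse,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> GlmFit:
    """IRLS fit of the binomial-logit model with free dispersion.

    phi = Pearson chi2 / (M - N - 1); standard errors are scaled by
    sqrt(phi) and p-values use the t reference with M - N - 1 df.
    """
    _align(P, response)
    if P.shape[1] >= len(P):
        raise ValueError("need more transcripts than TF columns")
    exog, names = _design(P)
    model = sm.GLM(_endog(response), exog, family=sm.families.Binomial())
    base = model.fit(maxiter=maxiter, tol=tol)
    phi = float(base.pearson_chi2 / base.df_resid)
    res = model.fit(maxiter=maxiter, tol=tol, scale=phi, use_t=True)
    params = pd.Series(res.params, index=names)
    separated = list(params.index[np.abs(params) > _SEPARATION_BOUND])
    if not res.converged:
        separated = separated or names
    return GlmFit(
        params=params,
        bse=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        dispersion=phi,
        null_deviance=float(res.null_deviance),
        deviance=float(res.deviance),
        df_resid=int(res.df_resid),
        converged=bool(res.converged),
        separation_terms=separated,
    )


@dataclass
class RegularizedFit:
    """A lasso/ridge/elastic-net path with its cross-validation curve."""

    alpha: float
    lambdas: np.ndarray  # strictly decreasing
    coef_path: pd.DataFrame  # rows: lambdas, columns: (Intercept) + TFs
    lambda_min: float
    params: pd.Series  # coefficients at lambda_min, original scale
    cv_errors: np.ndarray | None
    seed: int

    @property
    def intercept(self) -> float:
        return float(self.params[INTERCEPT])

    @property
    def coefficients(self) -> pd.Series:
        return self.params.drop(INTERCEPT)

    def predict_proportion(self, P: CountMatrix) -> np.ndarray:
        X = P[self.coefficients.index].to_numpy(dtype=float)
        return expit(self.intercept + X @ self.coefficients.to_numpy())

    @property
    def nonzero(self) -> int:
        return int((np.abs(self.coefficients) > ZERO_TOL).sum())


def _lambda_grid(
    X_std: np.ndarray, response: BoEResponse, alpha: float, n_lambda: int
) -> np.ndarray:
    """Log-spaced grid from lambda_max (all penalized coefficients zero)
    down four orders of magnitude.  lambda_max follows from the score of
    the mean-deviance objective at the intercept-only fit."""
    k, n = response.successes, response.trials
    p_bar = k.sum() / (n * len(k))
    score = X_std.T @ (k - n * p_bar) / len(k)
    alpha_eff = max(alpha, 1e-3)  # ridge has no finite lambda_max
    lam_max = np.abs(score).max() / alpha_eff
    lam_max = max(lam_max, 1e-6) * 1.05
    return np.geomspace(lam_max, lam_max * 1e-4, n_lambda)


def _fit_path(
    endog: np.ndarray,
    exog_std: np.ndarray,
    lambdas: np.ndarray,
    alpha: float,
) -> np.ndarray:
    """Warm-started elastic-net path; the intercept is never penalized."""
    n_params = exog_std.shape[1]
    pen = np.ones(n_params)
    pen[0] = 0.0
    model = sm.GLM(endog, exog_std, family=sm.families.Binomial())
    path = np.empty((len(lambdas), n_params))
    start = None
    with warnings.catch_warnings():
        # the coordinate-descent backend warns on residual gradients far
        # below any tolerance that matters here
        warnings.filterwarnings("ignore",
                                message="GLM ridge optimization may have failed")
        for i, lam in enumerate(lambdas):
            res = model.fit_regularized(
                method="elastic_net",
                alpha=lam * pen,
                L1_wt=alpha,
                start_params=start,
                cnvrg_tol=1e-7,
                maxiter=200,
            )
            path[i] = res.params
            start = res.params
    return path


def fit_penalized(
    P: CountMatrix,
    response: BoEResponse,
    alpha: float = 1.0,
    n_lambda: int = 50,
    cv_folds: int = 10,
    seed: int = 0,
) -> RegularizedFit:
    """Penalized binomial fit along a decreasing lambda grid.

    alpha = 1 is the lasso, 0 the ridge, 0.5 the elastic net.  Columns are
    standardized to unit variance internally; coefficients are reported on
    the original count scale.  lambda_min minimizes the fold-averaged mean
    squared prediction error on BoE proportions.
    """
    _align(P, response)
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    k = response.successes
    if k.sum() == 0 or k.sum() == response.trials * len(k):
        raise ValueError("degenerate response: all zero or all trials")
    sd = P.to_numpy(dtype=float).std(axis=0)
    if (sd == 0).any():
        raise ValueError("constant columns cannot be standardized")

    X_std = P.to_numpy(dtype=float) / sd
    exog = np.hstack([np.ones((len(P), 1)), X_std])
    endog = _endog(response)
    lambdas = _lambda_grid(X_std, response, alpha, n_lambda)

    cv_errors = None
    if cv_folds and cv_folds >= 2:
        rng = np.random.default_rng(seed)
        fold_of = rng.permutation(len(P)) % cv_folds
        prop = response.boe
        sq_err = np.zeros((cv_folds, len(lambdas)))
        for f in range(cv_folds):
            train = fold_of != f
            test = ~train
            path_f = _fit_path(endog[train], exog[train], lambdas, alpha)
            pred = expit(exog[test] @ path_f.T)  # n_test x n_lambda
            sq_err[f] = ((pred - prop[test, None]) ** 2).mean(axis=0)
        cv_errors = sq_err.mean(axis=0)
        lam_min = float(lambdas[int(np.argmin(cv_errors))])
    else:
        lam_min = float(lambdas[-1])

    path_std = _fit_path(endog, exog, lambdas, alpha)
    path = path_std.copy()
    path[:, 1:] /= sd  # back to original count scale
    names = [INTERCEPT] + list(P.columns)
    coef_path = pd.DataFrame(path, index=lambdas, columns=names)
    params = coef_path.loc[lam_min]
    if isinstance(params, pd.DataFrame):  # duplicated lambda, take first
        params = params.iloc[0]
    return RegularizedFit(
        alpha=alpha,
        lambdas=lambdas,
        coef_path=coef_path,
        lambda_min=lam_min,
        params=params.rename(None),
        cv_errors=cv_errors,
        seed=seed,
    )


@dataclass
class InteractionTable:
    """Significant pairwise-interaction terms from a joint quasibinomial
    fit, with the first-order coefficients of each pair."""

    table: pd.DataFrame  # tf_a, tf_b, coef, p_value, coef_a, coef_b
    fit: GlmFit
    dropped_pairs: list[tuple[str, str]]
    tested_pairs: int


def fit_interactions(
    P: CountMatrix,
    response: BoEResponse,
    p_cutoff: float = 0.05,
    min_cooccurrence: int = 10,
) -> InteractionTable:
    """Add x_a * x_b product terms for every TF pair co-occurring in at
    least ``min_cooccurrence`` promoters and fit one joint quasibinomial
    model; report interactions with p below the cutoff.

    Product columns that are linearly dependent on the columns already in
    the design are dropped (and reported) rather than fit.
    """
    _align(P, response)
    X = P.to_numpy(dtype=float)
    present = X > 0
    labels = list(P.columns)
    candidates = []
    for a in range(len(labels)):
        co = (present[:, a][:, None] & present[:, a + 1:]).sum(axis=0)
        for off, c in enumerate(co):
            if c >= min_cooccurrence:
                candidates.append((a, a + 1 + off))

    dropped: list[tuple[str, str]] = []
    kept: list[tuple[str, str]] = []
    base = np.hstack([np.ones((len(P), 1)), X])
    cols = [base]
    rank = np.linalg.matrix_rank(base)
    products: dict[str, np.ndarray] = {}
    for a, b in candidates:
        prod = (X[:, a] * X[:, b]).reshape(-1, 1)
        trial = np.hstack(cols + [prod])
        new_rank = np.linalg.matrix_rank(trial)
        if new_rank <= rank:
            dropped.append((labels[a], labels[b]))
            continue
        rank = new_rank
        cols.append(prod)
        kept.append((labels[a], labels[b]))
        products[f"{labels[a]}:{labels[b]}"] = prod.ravel()

    design = pd.concat([P, pd.DataFrame(products, index=P.index)], axis=1)
    fit = fit_quasibinomial(design, response)
    rows = []
    for a, b in kept:
        term = f"{a}:{b}"
        if fit.pvalues[term] < p_cutoff:
            rows.append({
                "tf_a": a, "tf_b": b,
                "coef": fit.params[term],
                "p_value": fit.pvalues[term],
                "coef_a": fit.params[a],
                "coef_b": fit.params[b],
            })
    table = pd.DataFrame(rows, columns=["tf_a", "tf_b", "coef", "p_value",
                                        "coef_a", "coef_b"])
    return InteractionTable(table, fit, dropped, len(kept))


def fit_binary_recode(
    P: CountMatrix,
    labels: pd.Series | np.ndarray,
    positive: str = "housekeeping",
    alpha: float = 1.0,
    n_lambda: int = 50,
    cv_folds: int = 10,
    seed: int = 0,
) -> RegularizedFit:
    """Penalized fit of housekeeping-cluster membership (one cluster versus
    the other two), the binary recoding of the three-class response."""
    labels = pd.Series(np.asarray(labels), index=P.index)
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("every cluster needs at least 2 members")
    if positive not in counts.index:
        raise ValueError(f"no cluster labelled {positive!r}")
    y = (labels == positive).astype(int).to_numpy()
    response = BoEResponse(list(P.index), y, 1)
    return fit_penalized(P, response, alpha=alpha, n_lambda=n_lambda,
                         cv_folds=cv_folds, seed=seed)
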