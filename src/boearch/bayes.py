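"""Bayesian binomial-logit GLM via adaptive random-walk Metropolis.

The posterior combines the binomial-logit likelihood on (successes,
trials) with independent weak Gaussian priors N(0, prior_sd) on the
intercept and every coefficient.  Chains are preconditioned with the
Laplace approximation (proposals drawn from a scaled Cholesky factor of
the inverse Fisher information at the mode), with the global step size
adapted during warm-up towards a standard random-walk acceptance rate.
Convergence is summarized by the split-chain potential scale reduction
factor R-hat, which approaches one at convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .glm import INTERCEPT, _align, _design, _endog
from .types import BoEResponse, CountMatrix

_TARGET_ACCEPT = 0.3


@dataclass
class BayesFit:
    """Posterior draws and summaries for the Bayesian GLM."""

    params: pd.Series  # posterior medians
    draws: np.ndarray  # (chains, kept iterations, n_params)
    rhat: pd.Series
    chains: int
    iterations: int
    prior_sd: float
    accept_rate: float

    @property
    def intercept(self) -> float:
        return float(self.params[INTERCEPT])

    @property
    def coefficients(self) -> pd.Series:
        return self.params.drop(INTERCEPT)


def _log_posterior(theta, X, k, nk, prior_var):
    eta = X @ theta
    # binomial loglike up to a constant, stable via logaddexp
    log_p = -np.logaddexp(0.0, -eta)
    log_q = -np.logaddexp(0.0, eta)
    ll = float(k @ log_p + nk @ log_q)
    return ll - 0.5 * float(theta @ theta) / prior_var


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-chain R-hat per parameter; falls back to a direct computation
    if arviz is unavailable."""
    try:
        import arviz as az

        ds = az.convert_to_dataset({"theta": chains})
        return az.rhat(ds)["theta"].to_numpy()
    except Exception:  # pragma: no cover - arviz is a declared dependency
        c, n, d = chains.shape
        half = n // 2
        split = chains[:, : 2 * half].reshape(2 * c, half, d)
        m = split.mean(axis=1)
        w = split.var(axis=1, ddof=1).mean(axis=0)
        b = half * m.var(axis=0, ddof=1)
        var_hat = (half - 1) / half * w + b / half
        return np.sqrt(var_hat / w)


def fit_bayesian(
    P: CountMatrix,
    response: BoEResponse,
    prior_sd: float = 10.0,
    chains: int = 4,
    iterations: int = 1000,
    seed: int = 0,
) -> BayesFit:
    """Sample the posterior of the binomial-logit GLM.

    Each chain runs ``iterations`` steps split evenly between warm-up
    (with step-size adaptation) and sampling.  Point estimates are the
    posterior medians.  A convergence warning is emitted if any R-hat
    exceeds 1.1; the fit is still returned.
    """
    _align(P, response)
    X, names = _design(P)
    k = response.successes.astype(float)
    nk = response.trials - k
    prior_var = prior_sd**2
    d = X.shape[1]

    # Laplace preconditioning at the posterior mode (MAP)
    from scipy.optimize import minimize

    n_tot = float(response.trials)

    def neg_log_post(theta):
        return -_log_posterior(theta, X, k, nk, prior_var)

    def grad(theta):
        p = 1.0 / (1.0 + np.exp(-(X @ theta)))
        return X.T @ (n_tot * p - k) + theta / prior_var

    start = sm.GLM(_endog(response), X,
                   family=sm.families.Binomial()).fit_regularized(
        method="elastic_net", alpha=1.0 / (prior_var * len(k)), L1_wt=0.0
    ).params
    opt = minimize(neg_log_post, start, jac=grad, method="L-BFGS-B")
    mode = opt.x
    p_hat = 1.0 / (1.0 + np.exp(-(X @ mode)))
    w = n_tot * p_hat * (1 - p_hat)
    hess = X.T @ (X * w[:, None]) + np.eye(d) / prior_var
    chol = np.linalg.cholesky(np.linalg.inv(hess))

    warmup = iterations // 2
    keep = iterations - warmup
    rng_master = np.random.default_rng(seed)
    chain_seeds = rng_master.integers(2**31, size=chains)

    draws = np.empty((chains, keep, d))
    accepted = 0
    total = 0
    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        theta = mode + 0.5 * chol @ rng.standard_normal(d)
        lp = _log_posterior(theta, X, k, nk, prior_var)
        log_scale = np.log(2.38 / np.sqrt(d))
        for it in range(iterations):
            prop = theta + np.exp(log_scale) * (chol @ rng.standard_normal(d))
            lp_prop = _log_posterior(prop, X, k, nk, prior_var)
            accept = np.log(rng.random()) < lp_prop - lp
            if accept:
                theta, lp = prop, lp_prop
            if it < warmup:
                # Robbins-Monro drift towards the target acceptance rate
                log_scale += (float(accept) - _TARGET_ACCEPT) / np.sqrt(it + 1)
            else:
                draws[c, it - warmup] = theta
                accepted += int(accept)
                total += 1

    rhat = pd.Series(_split_rhat(draws), index=names, name="rhat")
    if (rhat > 1.1).any():
        worst = rhat.idxmax()
        warnings.warn(
            f"MCMC convergence warning: max R-hat {rhat.max():.3f} "
            f"({worst}); consider more iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    medians = pd.Series(np.median(draws.reshape(-1, d), axis=0), index=names)
    return BayesFit(
        params=medians,
        draws=draws,
        rhat=rhat,
        chains=chains,
        iterations=iterations,
        prior_sd=prior_sd,
        accept_rate=accepted / max(total, 1),
    )
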