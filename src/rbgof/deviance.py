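"""Classical deviance goodness-of-fit test for the logistic model.

The baseline frequentist check reported alongside every relative belief
assessment: twice the gap between the saturated log-likelihood (cell MLEs
s_i/n_i, with 0 log 0 = 0) and the logistic MLE log-likelihood, referred to a
chi-square with m - k degrees of freedom.  The p-value is asymptotic; a flag
warns when any cell has fewer than 5 trials, where the approximation is
doubtful.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, xlogy
from scipy.stats import chi2

from ._newton import fit_logistic_batch
from .data import GroupedBinomialData
from .exceptions import ConvergenceError, DesignRankError

#: |x_i' beta_hat| beyond this is treated as (quasi-)complete separation.
SEPARATION_ETA = 30.0


@dataclass(frozen=True)
class MLEFit:
    """Maximum likelihood fit of the logistic model to grouped counts."""

    beta_hat: np.ndarray
    fitted_probs: np.ndarray
    deviance: float
    df: int
    p_value: float
    converged: bool
    iterations: int
    separation: bool
    small_counts: bool  # any n_i < 5: asymptotic p-value doubtful


def _saturated_loglik(data: GroupedBinomialData) -> float:
    ybar = data.s / data.n
    return float(((xlogy(ybar, ybar) + xlogy(1.0 - ybar, 1.0 - ybar)) * data.n).sum())


def fit_mle(data: GroupedBinomialData, tol: float = 1e-10, max_iter: int = 100) -> MLEFit:
    """Logistic MLE by IRLS (Newton) on the grouped counts.

    Under separation the likelihood has no finite maximizer; the fit then
    stops at a large but finite beta, the deviance approaches its infimum,
    and ``separation`` is flagged instead of raising.

    Raises
    ------
    DesignRankError
        If ``m <= k`` (saturated design: the deviance test is undefined).
    ConvergenceError
        If the optimizer stalls without evidence of separation.
    """
    if data.m <= data.k:
        raise DesignRankError(
            f"deviance test undefined for a saturated design (m={data.m} <= k={data.k})"
        )
    ybar = data.s / data.n
    w = data.n.astype(float)
    beta, ll, converged, n_iter = fit_logistic_batch(
        data.X, ybar[None, :], weights=w, tol=tol, max_iter=max_iter, fallback=False
    )
    beta, ll = beta[0], float(ll[0])
    eta = data.X @ beta
    separation = bool(np.max(np.abs(eta)) > SEPARATION_ETA)
    if not converged[0] and not separation:
        raise ConvergenceError(
            "logistic MLE did not converge",
            diagnostics={"iterations": n_iter, "beta": beta.tolist(), "max_abs_eta": float(np.max(np.abs(eta)))},
        )
    dev = max(2.0 * (_saturated_loglik(data) - ll), 0.0)
    df = data.m - data.k
    return MLEFit(
        beta_hat=beta,
        fitted_probs=expit(eta),
        deviance=dev,
        df=df,
        p_value=float(chi2.sf(dev, df)),
        converged=bool(converged[0]) or separation,
        iterations=n_iter,
        separation=separation,
        small_counts=bool(np.any(data.n < 5)),
    )


def deviance_test(data: GroupedBinomialData) -> MLEFit:
    """Deviance goodness-of-fit test (an :class:`MLEFit` with its p-value)."""
    return fit_mle(data)
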