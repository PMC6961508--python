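"""Batched Newton / IRLS solver for weighted logistic fits with fractional responses.

Maximizes, independently for each row ``theta`` of an (N, m) response matrix,

    l(beta) = sum_i w_i * [theta_i * eta_i - log(1 + exp(eta_i))],   eta = X beta.

With fractional responses strictly inside (0, 1) the objective is strictly
concave for full-rank X and the maximizer exists and is finite, so Newton with
step halving converges quadratically; the same core serves the per-draw KL
projection (unit weights, theta a sampled probability vector) and the grouped
MLE behind the deviance test (weights n_i, theta the observed proportions,
where separation is possible and flagged by the caller).
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

# Objective decrease greater than this is treated as a genuine ascent failure
# during step halving (guards against float noise near the optimum).
_ASCENT_SLACK = 1e-13


def batch_loglik(X: np.ndarray, theta: np.ndarray, w: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Weighted Bernoulli log-likelihood for each (theta row, beta row) pair."""
    eta = beta @ X.T
    return ((theta * eta - np.logaddexp(0.0, eta)) * w).sum(axis=-1)


def fit_logistic_batch(
    X: np.ndarray,
    theta: np.ndarray,
    weights: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
    fallback: bool = True,
):
    """Fit all N logistic regressions at once.

    Parameters
    ----------
    X : (m, k) full-rank design matrix.
    theta : (N, m) fractional responses in (0, 1) (clamped upstream).
    weights : (m,) nonnegative per-row weights; default all ones.
    tol : convergence threshold on the change in log-likelihood.
    max_iter : Newton iteration cap per draw.
    fallback : when True, draws that have not converged after ``max_iter``
        are restarted with a derivative-free Nelder-Mead search.

    Returns
    -------
    beta : (N, k) maximizers.
    loglik : (N,) maximized objective values.
    converged : (N,) bool flags.
    n_iter : int, Newton sweeps used.
    """
    X = np.asarray(X, dtype=float)
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    N, m = theta.shape
    k = X.shape[1]
    w = np.ones(m) if weights is None else np.asarray(weights, dtype=float)

    # Start from the weighted least-squares fit to the (clamped) logits: exact
    # when theta already lies on the logistic surface, close otherwise.
    mu = logit(np.clip(theta, 1e-12, 1.0 - 1e-12))
    XtW = (X * w[:, None]).T
    beta = np.linalg.solve(XtW @ X, XtW @ mu.T).T
    ll = batch_loglik(X, theta, w, beta)

    converged = np.zeros(N, dtype=bool)
    it = 0
    for it in range(1, max_iter + 1):
        idx = np.flatnonzero(~converged)
        if idx.size == 0:
            break
        b = beta[idx]
        th = theta[idx]
        eta = b @ X.T
        p = expit(eta)
        grad = ((th - p) * w) @ X  # (n_active, k)
        W = p * (1.0 - p) * w  # (n_active, m)
        H = np.einsum("nm,mi,mj->nij", W, X, X)
        try:
            step = np.linalg.solve(H, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            H = H + 1e-12 * np.trace(H, axis1=-2, axis2=-1)[..., None, None] * np.eye(k)
            step = np.linalg.solve(H, grad[..., None])[..., 0]

        ll_old = ll[idx]
        new_b = b + step
        new_ll = batch_loglik(X, th, w, new_b)
        for _ in range(50):
            bad = ~(new_ll >= ll_old - _ASCENT_SLACK)
            if not bad.any():
                break
            step[bad] *= 0.5
            new_b[bad] = b[bad] + step[bad]
            new_ll[bad] = batch_loglik(X, th[bad], w, new_b[bad])
        else:  # pragma: no cover - cannot ascend at all: keep the old point
            stuck = ~(new_ll >= ll_old - _ASCENT_SLACK)
            new_b[stuck] = b[stuck]
            new_ll[stuck] = ll_old[stuck]

        beta[idx] = new_b
        ll[idx] = new_ll
        converged[idx] = np.abs(new_ll - ll_old) < tol

    if fallback and not converged.all():
        for i in np.flatnonzero(~converged):
            beta[i], ll[i], converged[i] = _simplex_restart(X, theta[i], w, beta[i], ll[i], tol)
    return beta, ll, converged, it


def _simplex_restart(X, theta_i, w, beta_i, ll_i, tol):
    """Derivative-free rescue for a single draw that Newton failed to settle."""

    def neg(b):
        return -batch_loglik(X, theta_i[None, :], w, b[None, :])[0]

    best_b, best_ll = beta_i, ll_i
    # restart both from the current iterate and from the least-squares logits fit
    mu = logit(np.clip(theta_i, 1e-12, 1.0 - 1e-12))
    XtW = (X * w[:, None]).T
    ls = np.linalg.solve(XtW @ X, XtW @ mu)
    for b0 in (beta_i, ls):
        res = minimize(neg, b0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": tol, "maxiter": 5000})
        if -res.fun > best_ll:
            best_b, best_ll = res.x, -res.fun
    # accept if the rescue is a stationary-enough point
    p = expit(X @ best_b)
    grad = ((theta_i - p) * w) @ X
    ok = bool(np.max(np.abs(grad)) < 1e-6 * max(1.0, float(np.abs(w).sum())))
    return best_b, best_ll, ok
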