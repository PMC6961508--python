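"""Monte Carlo sampling of the cell probabilities theta(X).

The noninformative prior on ``theta(X)`` is uniform on ``[0,1]^m``.  It is
noninformative in the prior-data-conflict sense: the prior predictive of each
count ``s_i`` is uniform on ``{0, ..., n_i}`` (mass ``1/(n_i+1)`` everywhere),
so the tail probability of the predictive check equals 1 for every possible
observation and prior-data conflict can never arise.  The posterior is the
conjugate product of betas, ``theta_i | s_i ~ Beta(s_i + 1, n_i - s_i + 1)``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import PROB_CLAMP, GroupedBinomialData


@dataclass(frozen=True)
class ThetaSample:
    """N Monte Carlo draws of the m-vector of cell probabilities."""

    draws: np.ndarray  # (N, m), every entry in (0, 1)
    source: str  # "prior" | "posterior"
    seed: int

    @property
    def N(self) -> int:
        return self.draws.shape[0]

    @property
    def m(self) -> int:
        return self.draws.shape[1]


def _check_sizes(m: int, N: int) -> None:
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")


def sample_prior(m: int, N: int, seed: int) -> ThetaSample:
    """Draw ``N`` iid points from the uniform prior on ``[0,1]^m``."""
    _check_sizes(m, N)
    rng = np.random.default_rng(seed)
    draws = rng.uniform(size=(N, m))
    np.clip(draws, PROB_CLAMP, 1.0 - PROB_CLAMP, out=draws)
    return ThetaSample(draws=draws, source="prior", seed=seed)


def sample_posterior(data: GroupedBinomialData, N: int, seed: int) -> ThetaSample:
    """Draw ``N`` iid points from the product-beta posterior.

    Column i is ``Beta(s_i + 1, n_i - s_i + 1)``; columns are independent.
    """
    _check_sizes(data.m, N)
    rng = np.random.default_rng(seed)
    a = data.s.astype(float) + 1.0
    b = (data.n - data.s).astype(float) + 1.0
    draws = rng.beta(a, b, size=(N, data.m))
    np.clip(draws, PROB_CLAMP, 1.0 - PROB_CLAMP, out=draws)
    return ThetaSample(draws=draws, source="posterior", seed=seed)


def prior_predictive_pmf(n: int) -> np.ndarray:
    """Prior predictive pmf of a count with ``n`` trials: uniform on {0,...,n}.

    Integrating the Binomial(n, theta) likelihood against the uniform prior
    gives mass ``1/(n+1)`` on every value, which is why the uniform prior can
    never be in conflict with the data: the predictive check
    ``M_T(m_T(t) <= m_T(T(x)))`` is identically 1.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return np.full(n + 1, 1.0 / (n + 1))
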