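"""Scikit-learn style estimators wrapping the assessment pipeline.

Both estimators consume the grouped data as ``fit(X, y)`` where ``X`` is the
(m, k) design matrix and ``y`` is either

* an (m, 2) array whose columns are successes and trials ``(s, n)``, or
* a 1-D 0/1 response vector (one Bernoulli row per observation), in which
  case rows of X with identical predictor values are pooled first.

They carry their configuration as constructor parameters (so they compose
with ``sklearn`` model selection and cloning) and expose the results as
fitted attributes with trailing underscores.
"""
from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .data import aggregate_replicates, build_data
from .deviance import deviance_test
from .relative_belief import assess


def _coerce_grouped(X, y):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if y.ndim == 1:
        return aggregate_replicates([(row, int(v)) for row, v in zip(X, y)])
    if y.ndim == 2 and y.shape[1] == 2:
        return build_data(X, n=y[:, 1], s=y[:, 0])
    raise ValueError("y must be 1-D binary responses or an (m, 2) array of (successes, trials)")


def _seed_from(random_state) -> int:
    if random_state is None:
        return int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
    if isinstance(random_state, numbers.Integral):
        return int(random_state)
    if isinstance(random_state, np.random.Generator):
        return int(random_state.integers(2**31))
    raise ValueError("random_state must be None, an int, or a numpy Generator")


class RelativeBeliefGoodnessOfFit(BaseEstimator):
    """Bayesian goodness-of-fit assessment of a logistic regression.

    Compares the concentration of the product-beta posterior with that of the
    uniform prior around the logistic hypothesis, through the distribution of
    a distance-to-surface statistic.  ``relative_belief_ > 1`` is evidence in
    favor of the logistic model, ``< 1`` against; ``strength_`` calibrates
    the verdict as a posterior probability.

    Parameters
    ----------
    measure : {"euclid", "kl"}
        Concentration measure: squared logit-scale Euclidean distance, or the
        minimized average Kullback-Leibler divergence.
    delta : float
        The practically meaningful deviation from the hypothesis; distances
        below delta count as "the model holds".  For "euclid" this is a
        squared absolute error on logits (approximately on probabilities, for
        small delta); for "kl" an average relative error on probabilities.
    delta_star : float, optional
        Discretization bin width; defaults to ``delta`` under the "equal"
        policy, ``delta/m`` under "per-coordinate".
    delta_star_policy : {"equal", "per-coordinate"}
    n_draws : int
        Monte Carlo sample size per distribution (prior and posterior).
    binning : {"width", "prior_quantile"}
        Partition of the distance axis; see :mod:`rbgof.relative_belief`.
    random_state : int, Generator or None
        Seed for the prior stream; the posterior stream uses seed + 1.

    Attributes
    ----------
    relative_belief_ : float
        RB([0, delta*)), the evidence for the logistic hypothesis.
    strength_ : float
        Posterior probability calibrating the evidence, in [0, 1].
    result_ : AssessmentResult
        The full record, including the per-bin table.
    data_ : GroupedBinomialData
        The validated grouped data the assessment used.

    Examples
    --------
    >>> import numpy as np
    >>> from rbgof import RelativeBeliefGoodnessOfFit
    >>> X = np.column_stack([np.ones(4), [-0.86, -0.30, -0.05, 0.73]])
    >>> y = np.column_stack([[0, 1, 3, 5], [5, 5, 5, 5]])  # (successes, trials)
    >>> gof = RelativeBeliefGoodnessOfFit(measure="euclid", delta=0.01,
    ...                                   random_state=1).fit(X, y)
    >>> bool(gof.relative_belief_ > 1)
    True
    """

    def __init__(
        self,
        measure: str = "euclid",
        delta: float = 0.01,
        delta_star: float | None = None,
        delta_star_policy: str = "equal",
        n_draws: int = 100_000,
        binning: str = "width",
        random_state=None,
    ):
        self.measure = measure
        self.delta = delta
        self.delta_star = delta_star
        self.delta_star_policy = delta_star_policy
        self.n_draws = n_draws
        self.binning = binning
        self.random_state = random_state

    def fit(self, X, y):
        """Run the assessment on grouped data (X, y)."""
        data = _coerce_grouped(X, y)
        seed = _seed_from(self.random_state)
        result = assess(
            data,
            measure=self.measure,
            delta=self.delta,
            delta_star=self.delta_star,
            delta_star_policy=self.delta_star_policy,
            N=self.n_draws,
            seed=seed,
            binning=self.binning,
        )
        self.data_ = data
        self.result_ = result
        self.relative_belief_ = result.rb0
        self.strength_ = result.strength
        self.effective_range_upper_ = result.effective_range_upper
        self.n_features_in_ = data.k
        return self

    def evidence_in_favor(self) -> bool:
        """True when the posterior concentrates more than the prior (RB > 1)."""
        check_is_fitted(self, "relative_belief_")
        return bool(self.relative_belief_ > 1.0)


class DevianceGoodnessOfFit(BaseEstimator):
    """Classical deviance goodness-of-fit test, as a baseline companion.

    Fits the logistic MLE by IRLS and refers the deviance to chi-square with
    m - k degrees of freedom.  The p-value is asymptotic; ``small_counts_``
    flags cells with fewer than 5 trials where the approximation is doubtful.

    Attributes
    ----------
    coef_ : (k,) array — the MLE of the logistic coefficients.
    fitted_probs_ : (m,) array — fitted cell probabilities (increasing in the
        dose for monotone dose-response data).
    deviance_ : float
    df_ : int
    p_value_ : float
    separation_ : bool — the likelihood had no finite maximizer.
    """

    def fit(self, X, y):
        data = _coerce_grouped(X, y)
        fit = deviance_test(data)
        self.data_ = data
        self.mle_ = fit
        self.coef_ = fit.beta_hat
        self.fitted_probs_ = fit.fitted_probs
        self.deviance_ = fit.deviance
        self.df_ = fit.df
        self.p_value_ = fit.p_value
        self.separation_ = fit.separation
        self.small_counts_ = fit.small_counts
        self.n_features_in_ = data.k
        return self
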