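"""Grouped binomial data and the logistic/logit maps.

The unrestricted model is a product of independent binomials: at each of the
``m`` predictor settings ``x_i`` (the rows of the design matrix ``X``),
``s_i ~ Binomial(n_i, theta_i)``.  The logistic hypothesis H0 is the subset of
``[0, 1]^m`` where the logit vector ``mu = logit(theta)`` lies in the column
space of ``X``.  Everything downstream (sampling, distances, the relative
belief assessment, the deviance baseline) consumes the validated container
defined here.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit as _logit

from .exceptions import (
    CountError,
    DesignRankError,
    DomainError,
    EmptyDataError,
    TrialsError,
)

#: Probabilities are clamped to this open interval before taking logits, so
#: distances stay finite.  Beta draws with integer shape parameters >= 1 are
#: almost surely interior; the clamp only guards floating-point underflow.
PROB_CLAMP = 1e-12

#: Column rank is judged from singular values relative to the largest one.
RANK_RTOL = 1e-10


@dataclass(frozen=True)
class GroupedBinomialData:
    """Design matrix with per-row trial and success counts.

    Attributes
    ----------
    X : (m, k) float array
        Predictor values; an intercept must be an explicit column of ones.
    n : (m,) int array
        Trials per row, each >= 1.
    s : (m,) int array
        Successes per row, 0 <= s_i <= n_i.
    row_labels : tuple of str, optional
        Free-text identifiers for the rows.
    rank : int
        Numerical column rank of ``X`` (equals ``k`` for valid data).
    """

    X: np.ndarray
    n: np.ndarray
    s: np.ndarray
    row_labels: tuple[str, ...] | None = None
    rank: int = field(default=-1)

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def __repr__(self) -> str:  # keep reprs short for m=20 fixtures
        return f"GroupedBinomialData(m={self.m}, k={self.k}, total_trials={int(self.n.sum())})"


def matrix_rank(X: np.ndarray, rtol: float = RANK_RTOL) -> int:
    """Column rank of ``X`` judged by singular values relative to the largest."""
    sv = np.linalg.svd(X, compute_uv=False)
    if sv.size == 0 or sv[0] == 0.0:
        return 0
    return int(np.sum(sv > rtol * sv[0]))


def build_data(
    X,
    n,
    s,
    row_labels=None,
    check_rank: bool = True,
) -> GroupedBinomialData:
    """Validate and assemble a :class:`GroupedBinomialData`.

    Raises
    ------
    DesignRankError
        If ``X`` is rank deficient or ``k > m``.
    CountError
        If any ``s_i`` falls outside ``[0, n_i]``.
    TrialsError
        If any ``n_i < 1``.
    EmptyDataError
        If there are no rows.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = np.asarray(n, dtype=np.int64).ravel()
    s = np.asarray(s, dtype=np.int64).ravel()
    m, k = X.shape
    if m == 0:
        raise EmptyDataError("no observations supplied")
    if n.shape != (m,) or s.shape != (m,):
        raise ValueError(f"n and s must have length m={m}; got {n.shape}, {s.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite entries")
    if np.any(n < 1):
        raise TrialsError(f"all trial counts must be >= 1; offending rows {np.flatnonzero(n < 1).tolist()}")
    if np.any((s < 0) | (s > n)):
        raise CountError(
            f"success counts must satisfy 0 <= s_i <= n_i; offending rows "
            f"{np.flatnonzero((s < 0) | (s > n)).tolist()}"
        )
    rank = matrix_rank(X)
    if check_rank:
        if k > m:
            raise DesignRankError(f"more predictors than rows (k={k} > m={m})")
        if rank < k:
            raise DesignRankError(f"design matrix is rank deficient (rank {rank} < k={k})")
    if row_labels is not None:
        row_labels = tuple(str(r) for r in row_labels)
        if len(row_labels) != m:
            raise ValueError("row_labels length must equal m")
    return GroupedBinomialData(X=X, n=n, s=s, row_labels=row_labels, rank=rank)


def clamp_probabilities(theta, eps: float = PROB_CLAMP) -> np.ndarray:
    """Clamp probabilities into the open interval (eps, 1-eps).

    Entries outside [0, 1] (or non-finite) are rejected rather than clamped.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise DomainError("probability vector contains non-finite entries")
    if np.any((theta < 0.0) | (theta > 1.0)):
        raise DomainError("probability vector has entries outside [0, 1]")
    return np.clip(theta, eps, 1.0 - eps)


def logistic_prob(X, beta) -> np.ndarray:
    """Cell probabilities ``expit(X @ beta)`` of the logistic model.

    ``X`` may be a single predictor vector of length k or an (m, k) matrix;
    computed overflow-safely for large ``|x'beta|``.
    """
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    # clamp so the output is strictly interior even when expit underflows
    return np.clip(expit(X @ beta), PROB_CLAMP, 1.0 - PROB_CLAMP)


def logit_map(theta, eps: float = PROB_CLAMP) -> np.ndarray:
    """Elementwise log-odds ``log(theta / (1 - theta))`` after clamping.

    Mutual inverse of :func:`logistic_prob` on interior probabilities.
    """
    return _logit(clamp_probabilities(theta, eps))


def aggregate_replicates(rows) -> GroupedBinomialData:
    """Pool Bernoulli rows ``(predictor vector, 0/1 response)`` into grouped form.

    Rows with exactly equal predictor vectors are merged (grouping is by exact
    floating equality: inputs are data, not computed, and silent merging of
    nearly-equal settings would be worse than none).  Row order follows first
    appearance.
    """
    rows = list(rows)
    if not rows:
        raise EmptyDataError("aggregate_replicates received no rows")
    k = len(rows[0][0])
    groups: dict[tuple, list[int]] = {}
    for x, y in rows:
        x = tuple(float(v) for v in x)
        if len(x) != k:
            raise ValueError("all predictor vectors must have the same length")
        y = int(y)
        if y not in (0, 1):
            raise ValueError("responses must be 0 or 1")
        groups.setdefault(x, [0, 0])
        groups[x][0] += 1
        groups[x][1] += y
    X = np.array([list(x) for x in groups], dtype=float)
    n = np.array([v[0] for v in groups.values()], dtype=np.int64)
    s = np.array([v[1] for v in groups.values()], dtype=np.int64)
    # pooling can leave fewer distinct settings than predictors; that only
    # becomes an error once a full-rank design is actually required
    return build_data(X, n, s, check_rank=False)


def read_table(path, intercept: bool = False) -> GroupedBinomialData:
    """Read a delimited table with predictor columns followed by ``n`` and ``s``.

    A header row is required.  The delimiter is sniffed (comma or tab).  Pass
    ``intercept=True`` to prepend a column of ones.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if "n" not in df.columns or "s" not in df.columns:
        raise ValueError("table must contain 'n' and 's' columns after the predictors")
    pred_cols = [c for c in df.columns if c not in ("n", "s")]
    if not pred_cols and not intercept:
        raise ValueError("no predictor columns found (and intercept not requested)")
    X = df[pred_cols].to_numpy(dtype=float) if pred_cols else np.empty((len(df), 0))
    if intercept:
        X = np.column_stack([np.ones(len(df)), X])
    return build_data(X, df["n"].to_numpy(), df["s"].to_numpy())


def write_table(data: GroupedBinomialData, path, sep: str = "\t") -> None:
    """Write ``data`` in the delimited format accepted by :func:`read_table`."""
    cols = {f"x{j + 1}": data.X[:, j] for j in range(data.k)}
    cols["n"] = data.n
    cols["s"] = data.s
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)
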