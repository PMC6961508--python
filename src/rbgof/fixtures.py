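"""Built-in datasets and the synthetic product-binomial generator.

Every dataset used in the reported simulation studies and the bioassay
application ships here as a named fixture, exactly as printed, together with
the generating truth vector where one exists:

* ``ex5_m3_*`` — m=3 design, x2 in {0,1,2}, truth on the logistic surface
  with beta = (0.5, -1.0) (true probabilities ~ (0.62, 0.38, 0.18));
* ``ex5_m20_*`` — m=20 design on an irregular x2 grid, truth on the surface.
  The printed slope/intercept (0.5, 1.0) is inconsistent with the printed
  probability vector, which equals expit(0 + 1*x2); the fixture stores the
  printed probabilities as truth and notes the discrepancy;
* ``ex6_m5_*`` — m=5 design, x2 in {1,...,9}, truth off the surface,
  theta = (0.875, 0.327, 0.107, 0.198, 0.908);
* ``ex6_m20_*`` — m=20 design, truth from a quadratic-logistic curve,
  theta = expit(1 - 5*x2^2), which matches the printed 4-decimal vector and,
  unlike the printed copy, has no exact zeros (the printed 0.0000 entries are
  rounded values around 2e-7 and 5e-9);
* ``bioassay`` — the m=4 dose-response experiment (x2 = log dose in g/ml,
  5 animals per dose, deaths (0, 1, 3, 5)).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data import GroupedBinomialData, build_data, logistic_prob

_X2_M3 = np.array([0.0, 1.0, 2.0])
_X2_M5 = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
_X2_M20 = np.array([
    -1.35, -1.32, -0.87, -0.77, -0.59, -0.56, -0.44, -0.34, -0.23, -0.15,
    -0.02, 0.016, 0.05, 0.17, 0.42, 0.68, 1.10, 1.15, 1.80, 2.01,
])
_X2_BIOASSAY = np.array([-0.86, -0.30, -0.05, 0.73])


def _design(x2: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(x2), x2])


# truths
_TRUTH_M3 = logistic_prob(_design(_X2_M3), [0.5, -1.0])
#: printed probabilities; equal expit(x2), not expit(0.5 + x2) — see module docstring
_TRUTH_M20_TRUE = np.array([
    0.206, 0.210, 0.296, 0.316, 0.356, 0.364, 0.392, 0.417, 0.443, 0.463,
    0.494, 0.504, 0.513, 0.543, 0.604, 0.663, 0.750, 0.760, 0.858, 0.882,
])
_TRUTH_M5_FALSE = np.array([0.875, 0.327, 0.107, 0.198, 0.908])
_TRUTH_M20_FALSE = expit(1.0 - 5.0 * _X2_M20**2)  # quadratic-logistic truth

_S = {
    ("ex5_m3", 1): (1, 0, 0),
    ("ex5_m3", 5): (4, 2, 1),
    ("ex5_m3", 10): (7, 6, 1),
    ("ex5_m20", 1): (0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 1, 0, 0, 1, 0, 1, 1, 0, 1, 1),
    ("ex5_m20", 5): (0, 0, 3, 2, 3, 2, 3, 1, 3, 2, 1, 3, 1, 1, 4, 3, 2, 3, 3, 5),
    ("ex5_m20", 10): (1, 3, 4, 3, 2, 6, 4, 5, 3, 0, 7, 7, 8, 7, 6, 3, 8, 8, 8, 7),
    ("ex6_m5", 1): (1, 0, 0, 0, 1),
    ("ex6_m5", 5): (5, 2, 0, 1, 5),
    ("ex6_m5", 10): (9, 3, 1, 2, 9),
    ("ex6_m20", 1): (1, 1, 0, 0, 0, 0, 0, 1, 1, 0, 0, 1, 1, 0, 1, 1, 1, 0, 1, 1),
    ("ex6_m20", 5): (5, 4, 5, 1, 1, 3, 0, 1, 2, 1, 1, 0, 2, 4, 5, 3, 4, 4, 5, 4),
    ("ex6_m20", 10): (8, 7, 10, 1, 2, 2, 4, 5, 1, 1, 1, 0, 6, 8, 7, 7, 6, 10, 10, 10),
}


@dataclass(frozen=True)
class Fixture:
    """A named dataset with its generating truth (when known)."""

    name: str
    data: GroupedBinomialData
    truth: np.ndarray | None
    notes: str


def _registry() -> dict[str, Fixture]:
    reg: dict[str, Fixture] = {}
    specs = {
        "ex5_m3": (_X2_M3, _TRUTH_M3, "m=3 simulation, truth on the surface, beta=(0.5,-1.0)"),
        "ex5_m20": (
            _X2_M20,
            _TRUTH_M20_TRUE,
            "m=20 simulation, truth on the surface; printed probabilities equal "
            "expit(x2), inconsistent with the printed beta=(0.5,1.0)",
        ),
        "ex6_m5": (_X2_M5, _TRUTH_M5_FALSE, "m=5 simulation, truth off the surface"),
        "ex6_m20": (
            _X2_M20,
            _TRUTH_M20_FALSE,
            "m=20 simulation, truth expit(1 - 5*x2^2), off the linear-logistic surface",
        ),
    }
    for base, (x2, truth, note) in specs.items():
        for n in (1, 5, 10):
            s = _S[(base, n)]
            name = f"{base}_n{n}"
            data = build_data(_design(x2), [n] * len(x2), s)
            reg[name] = Fixture(name=name, data=data, truth=truth.copy(), notes=f"{note}; n={n} per cell")
    reg["bioassay"] = Fixture(
        name="bioassay",
        data=build_data(_design(_X2_BIOASSAY), [5] * 4, (0, 1, 3, 5)),
        truth=None,
        notes="acute toxicity bioassay; x2 = log dose (g/ml), 5 animals per dose",
    )
    return reg


_FIXTURES = _registry()


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def load_fixture(name: str) -> Fixture:
    """Look up a built-in dataset by name."""
    try:
        return _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        ) from None


def generate_data(X, truth=None, beta=None, n=10, seed: int = 0) -> GroupedBinomialData:
    """Simulate grouped binomial counts ``s_i ~ Binomial(n_i, truth_i)``.

    Exactly one of ``truth`` (a probability vector) or ``beta`` (logistic
    coefficients, giving ``truth = expit(X beta)``) must be supplied.  ``n``
    may be a scalar (common cell size) or a per-row vector.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if (truth is None) == (beta is None):
        raise ValueError("supply exactly one of truth or beta")
    if beta is not None:
        truth = logistic_prob(X, beta)
    truth = np.asarray(truth, dtype=float).ravel()
    if truth.shape[0] != X.shape[0]:
        raise ValueError(f"truth has length {truth.shape[0]} but X has {X.shape[0]} rows")
    if np.any((truth <= 0) | (truth >= 1)):
        raise ValueError("truth probabilities must be strictly inside (0, 1)")
    n_vec = np.broadcast_to(np.asarray(n, dtype=np.int64), truth.shape).copy()
    rng = np.random.default_rng(seed)
    s = rng.binomial(n_vec, truth)
    return build_data(X, n_vec, s)
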