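# Methods

## Model and hypothesis

At each of m predictor settings `x_i ∈ R^k` (rows of a full-column-rank
design matrix X, intercept as an explicit column of ones) we observe
`s_i ~ Binomial(n_i, θ_i)`, independently.  The unrestricted parameter is
`θ = (θ_1, …, θ_m) ∈ [0,1]^m`; the logistic hypothesis H0 is the k-dimensional
surface `θ_i = expit(x_i'β)`.  H0 holds iff the logit vector `μ = logit(θ)`
lies in col(X).

The prior on θ is uniform on `[0,1]^m`.  It is noninformative in the
prior-data-conflict sense: the prior predictive of each count is uniform on
`{0,…,n_i}` (mass `1/(n_i+1)`), so the predictive tail probability used to
detect prior-data conflict equals 1 for every conceivable dataset
(`rbgof.prior_predictive_pmf` documents and tests this).  The posterior is
the product of `Beta(s_i+1, n_i−s_i+1)` laws.  Prior and posterior draws use
independent seeded streams (`seed` and `seed+1`), mirroring the independent
Monte Carlo approximations of the two distance distributions.

## Distance statistics

Since H0 has prior probability zero, evidence about it is channelled through
a distance-to-surface statistic `d(θ) ≥ 0` with `d(θ) = 0` iff θ ∈ H0:

* **Euclidean (logit scale)** — `d(θ) = inf_β ‖μ − Xβ‖²/m = μ'Pμ/m` with
  `P = I − X(X'X)⁻¹X'`.  P is held as an orthonormal basis Q of col(X) (one
  QR factorization per assessment), so evaluating 10^5 draws is two matrix
  products.  δ is interpreted as a squared absolute logit error that is
  practically immaterial; for small δ this transfers to roughly the same
  squared error on the probabilities.
* **Kullback–Leibler** — `d(θ) = inf_β Σ_i KL(θ_i, expit(x_i'β))/m`.
  Minimizing over β is equivalent to maximizing the logistic log-likelihood
  with fractional responses θ_i (unit weights), a strictly concave problem
  for full-rank X and interior θ.  δ is an average relative error on the
  probabilities.  The choice between measures is a choice between absolute
  and relative error as the accuracy criterion; probabilities near 0 or 1
  favor KL.

The KL inner optimization runs as a *batched* Newton/IRLS sweep over all
draws simultaneously (`rbgof._newton`): starting from the least-squares fit
to the clamped logits, each iteration solves the N k×k Newton systems with
one einsum and one batched solve, with per-draw step halving; draws that
have converged (log-likelihood change < 1e-10, max 100 sweeps) drop out of
the active set.  Draws that still fail get a Nelder-Mead restart and a
gradient check; a draw failing both raises a ConvergenceError with
diagnostics rather than silently contaminating the distance sample.  In
practice no uniform or beta draw needs the fallback.  Probabilities are
clamped to `[1e-12, 1−1e-12]` before logits are taken; beta draws with
integer shape parameters ≥ 1 are almost surely interior, so the clamp only
guards underflow and does not measurably distort the distance laws.

### Descriptive probability-scale misfit

`prob_misfit(θ, X)` reports `(1/m) Σ_i (θ_i − expit(x_i'β*))²` for a
best-fitting β*, used to say *how* false H0 is for a known truth vector.
"Best fitting" is genuinely ambiguous and the two readings differ when θ is
far from the surface, so both are implemented:

* `fit="logit_projection"` (default): β* is the least-squares projection of
  the logits onto col(X) — the same β* that realizes the Euclidean distance —
  and the probability-scale gap is evaluated there.  For the two off-surface
  simulation truths this gives 0.117 (m=5) and 0.231 (m=20).
* `fit="direct"`: β* minimizes the probability-scale objective itself
  (multistart Nelder-Mead seeded from the KL and projection fits; the
  objective is non-convex).  This true infimum is 0.116 for the m=5 truth
  but only 0.088 for the m=20 truth — the projection β* is a poor
  probability-scale fit when the truth bends far from every logistic curve.

The default is the projection reading because it keeps the descriptive
statistic tied to the geometry the assessment actually uses (and it is the
reading under which both reference values above are reproduced together).

The m=20 off-surface truth is stored as the exact quadratic-logistic curve
`θ = expit(1 − 5 x2²)`; the widely quoted 4-decimal vector is its rounding
(two entries print as 0.0000 but are ≈ 2e-7 and 5e-9 — using literal zeros
would corrupt any logit-scale computation).

## Discretization, RB, strength

RB at the point 0 is a ratio of densities that both vanish there, so it is
defined through shrinking intervals and estimated on a partition.  Two
partitions are implemented:

* **`binning="width"`** (default): `{[0,δ*), [δ*,2δ*), …}` with
  `k_bins = floor(max sampled distance/δ*) + 1`, capped at 10^6 with an
  overflow lump.  δ* defaults to δ (`policy="equal"`); `"per-coordinate"`
  gives δ/m, under which a first-bin distance bounds every coordinate's
  error rather than the average.  If the first bin catches no prior draws
  the assessment raises `UndefinedRBError` — loudly, because RB([0,δ*)) is
  then 0/0 and any number returned would be noise.
* **`binning="prior_quantile"`**: bins holding equal prior mass δ* each, the
  first bin being `[0, prior δ*-quantile)`.  When m − k is small both
  distance laws behave as `c·t^((m−k)/2)` near 0, both schemes' first-bin
  RBs estimate the same limiting ratio of constants, and the two give
  numerically indistinguishable answers.  When m − k is large (e.g. m=20,
  k=2) the prior mass below any practically relevant δ is far below 1/N for
  any feasible N, the width scheme is undefined, and the quantile scheme is
  the estimator that remains meaningful: its first bin always contains
  prior mass δ* exactly.  This is the scheme used for the m=20 reference
  tables.

Per-bin RB is posterior content / prior content; bins with posterior but no
prior mass count as RB = +∞ and bins empty under both laws are skipped.
The strength is the posterior probability of the bins with RB ≤ RB([0,δ*)),
with ≤ as the tie rule.  Reported tables round RB and strength to two
decimals; full precision is kept in the result object.  The "effective
range" reported is the upper edge of the last prior-occupied bin (the
reference captions' endpoints are not reproducible because their definition
of effective range is not stated).

Consistency (proved elsewhere for relative belief inference generally) is
checked empirically: on data simulated from a true logistic model the RB
exceeds 1 and its strength approaches 1 as cell counts grow to 200, and on
an off-surface truth the RB collapses below 0.05; the test suite runs 20
replicates of each at N = 2·10^4.

## Deviance baseline

`fit_mle` maximizes the grouped logistic likelihood with the same Newton
core (weights n_i, responses s_i/n_i, tolerance 1e-10, max 100 iterations).
Separation — possible with binary cells, e.g. a monotone 0/1 pattern — is
detected as `max |x_i'β̂| > 30` and flagged rather than raised: the deviance
then sits at its infimum and the test remains usable.  The deviance is
`2(l_saturated − l_fitted)` with saturated cell MLEs s_i/n_i and
`0·log 0 = 0`; the p-value is the upper χ²(m−k) tail.  It is asymptotic and
is reported with a `small_counts` flag whenever any `n_i < 5`.  statsmodels'
GLM is used in the test suite as an independent oracle for β̂ and the
deviance; it is deliberately not the implementation, so the oracle and the
implementation stay distinct routes.

## Synthetic data generator

`generate_data(X, truth | beta, n, seed)` draws `s_i ~ Binomial(n_i, θ_i)`
independently — exactly the mechanism assumed by the model, which is also
its limitation: it emulates no overdispersion, no within-cell dependence,
no covariate measurement error.  Passing tests therefore certify the
inferential machinery under a correctly specified sampling model, not
robustness to violations of the binomial assumption itself (which should be
screened separately, e.g. with runs tests on replicated cells).  Default
Monte Carlo size for assessments is N = 10^5 per distribution, the size at
which the reference tables were produced; the consistency simulations in
the tests use N = 2·10^4 and 20 replicates, enough to pin medians while
keeping the suite fast.

## Known limitations

* The uniform prior is the method's definition, not a choice; informative
  priors would require re-deriving the predictive-uniformity argument.
* Only the logit link is implemented (probit/cloglog would need their own
  projection steps).
* First-bin RB estimates inherit Monte Carlo noise of order
  `RB·sqrt(1/count_prior + 1/count_posterior)`; at δ = 0.001 with N = 10^5
  the bin counts can be small and two-decimal table values should be read
  with that noise in mind.
* The width and quantile partitions agree only in the small-codimension
  regime; for large m − k the width partition is undefined at practical δ
  and results there are estimator-dependent.
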