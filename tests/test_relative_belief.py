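import numpy as np
import pytest

from rbgof import (
    UndefinedRBError,
    assess,
    assess_grid,
    delta_star_default,
    discretize,
    rb_first_bin,
    strength,
)
from rbgof.distances import DistanceSample


def ds(values, measure="euclid", m=3):
    return DistanceSample(values=np.asarray(values, float), measure=measure, divisor_m=m)


def naive_recount(prior, post, delta_star):
    """Two-pass recount oracle: bin contents, first-bin RB and strength."""
    top = max(prior.max(), post.max())
    n_bins = int(np.floor(top / delta_star)) + 1
    cp = np.zeros(n_bins + 1)
    cq = np.zeros(n_bins + 1)
    for v in prior:
        cp[min(int(v // delta_star), n_bins)] += 1
    for v in post:
        cq[min(int(v // delta_star), n_bins)] += 1
    cp /= len(prior)
    cq /= len(post)
    rb0 = cq[0] / cp[0]
    st = 0.0
    for j in range(n_bins + 1):
        if cp[j] == 0 and cq[j] == 0:
            continue
        rb_j = cq[j] / cp[j] if cp[j] > 0 else np.inf
        if rb_j <= rb0:
            st += cq[j]
    return rb0, st


class TestDiscretize:
    def test_contents_sum_to_one(self):
        rng = np.random.default_rng(3)
        b = discretize(ds(rng.exponential(size=5000)), ds(rng.exponential(size=5000)), 0.1)
        assert b.prior_content.sum() == pytest.approx(1.0, abs=1e-12)
        assert b.posterior_content.sum() == pytest.approx(1.0, abs=1e-12)

    def test_identical_samples_give_unit_rb(self):
        v = np.random.default_rng(5).exponential(size=2000)
        b = discretize(ds(v), ds(v), 0.05)
        occupied = ~np.isnan(b.rb_per_bin)
        assert np.allclose(b.rb_per_bin[occupied], 1.0)
        assert strength(b, rb_first_bin(b)) == pytest.approx(1.0)

    def test_single_bin_when_delta_star_exceeds_range(self):
        b = discretize(ds([0.1, 0.2]), ds([0.05, 0.3]), delta_star=10.0)
        assert rb_first_bin(b) == pytest.approx(1.0)
        assert strength(b, 1.0) == pytest.approx(1.0)

    def test_all_posterior_mass_in_first_bin(self):
        prior = np.array([0.01] * 25 + [1.5] * 75)
        post = np.full(100, 0.02)
        b = discretize(ds(prior), ds(post), 0.1)
        assert rb_first_bin(b) == pytest.approx(1 / 0.25)

    def test_rejects_bad_delta_star(self):
        with pytest.raises(ValueError):
            discretize(ds([0.1]), ds([0.1]), 0.0)

    def test_undefined_rb_raises_with_guidance(self):
        b = discretize(ds([1.0, 2.0]), ds([0.05, 2.0]), 0.1)
        with pytest.raises(UndefinedRBError, match="prior_quantile"):
            rb_first_bin(b)

    def test_zero_prior_bins_never_below_finite_rb0(self):
        # bin 0: both occupied; a later bin with only posterior mass counts as
        # rb = +inf and must not enter the strength sum
        prior = np.array([0.05] * 50 + [0.95] * 50)
        post = np.array([0.05] * 50 + [0.45] * 50)
        b = discretize(ds(prior), ds(post), 0.1)
        rb0 = rb_first_bin(b)
        assert strength(b, rb0) == pytest.approx(0.5)

    def test_recount_oracle_exact(self):
        rng = np.random.default_rng(7)
        prior = rng.gamma(2.0, 0.5, size=10_000)
        post = rng.gamma(1.5, 0.3, size=10_000)
        b = discretize(ds(prior), ds(post), 0.07)
        rb0, st = naive_recount(prior, post, 0.07)
        assert rb_first_bin(b) == rb0
        assert strength(b, rb_first_bin(b)) == pytest.approx(st, abs=1e-12)

    def test_prior_quantile_bins_hold_equal_prior_mass(self):
        rng = np.random.default_rng(11)
        prior = rng.gamma(3.0, 1.0, size=10_000)
        post = rng.gamma(3.0, 0.5, size=10_000)
        b = discretize(ds(prior), ds(post), 0.05, binning="prior_quantile")
        assert np.allclose(b.prior_content[:-1], 0.05, atol=1e-3)
        assert b.posterior_content.sum() == pytest.approx(1.0)

    def test_quantile_binning_requires_probability_width(self):
        with pytest.raises(ValueError):
            discretize(ds([0.1, 0.5]), ds([0.2]), 2.0, binning="prior_quantile")


class TestDeltaStarDefault:
    def test_policies(self):
        assert delta_star_default(0.1, 20, "equal") == 0.1
        assert delta_star_default(0.1, 20, "per-coordinate") == pytest.approx(0.005)

    def test_validation(self):
        with pytest.raises(ValueError):
            delta_star_default(-0.1, 3)
        with pytest.raises(ValueError):
            delta_star_default(0.1, 3, "bogus")


class TestAssess:
    def test_reproducible_from_seed(self, bioassay):
        a = assess(bioassay, "euclid", delta=0.05, N=5000, seed=42)
        b = assess(bioassay, "euclid", delta=0.05, N=5000, seed=42)
        assert a.rb0 == b.rb0 and a.strength == b.strength

    def test_strength_is_probability(self, bioassay):
        r = assess(bioassay, "euclid", delta=0.05, N=5000, seed=1)
        assert 0.0 <= r.strength <= 1.0
        assert r.rb0 >= 0.0

    def test_rb0_equals_first_bin_entry(self, bioassay):
        r = assess(bioassay, "kl", delta=0.05, N=5000, seed=2)
        assert r.rb0 == r.bins.rb_per_bin[0]

    def test_recount_oracle_through_pipeline(self, bioassay):
        from rbgof.distances import distance_sample
        from rbgof.sampling import sample_posterior, sample_prior

        N, seed, delta = 10_000, 6, 0.05
        dp = distance_sample(sample_prior(bioassay.m, N, seed), bioassay.X, "euclid")
        dq = distance_sample(sample_posterior(bioassay, N, seed + 1), bioassay.X, "euclid")
        r = assess(bioassay, "euclid", delta=delta, N=N, seed=seed)
        rb0, st = naive_recount(dp.values, dq.values, delta)
        assert r.rb0 == rb0
        assert r.strength == pytest.approx(st, abs=1e-12)

    def test_rejects_small_N(self, bioassay):
        with pytest.raises(ValueError):
            assess(bioassay, "euclid", delta=0.05, N=100, seed=0)

    def test_grid_matches_individual_assessments(self, bioassay):
        grid = assess_grid(bioassay, ["euclid"], [0.05, 0.1], N=5000, seed=3)
        for r in grid:
            single = assess(bioassay, "euclid", delta=r.delta, N=5000, seed=3)
            assert r.rb0 == single.rb0 and r.strength == single.strength

    def test_effective_range_covers_occupied_bins(self, bioassay):
        r = assess(bioassay, "euclid", delta=0.1, N=5000, seed=4)
        assert r.effective_range_upper >= r.bins.prior_content[:-1].nonzero()[0][-1] * 0.1


class TestConsistency:
    def test_rb_grows_on_surface_and_vanishes_off_surface(self, design_m5):
        """Evidence accumulates correctly as cell counts grow.

        On data from a true logistic model the relative belief ratio should
        exceed 1 (and grow with n); on the m=5 off-surface truth it should
        collapse toward 0.  Medians over 20 replicate datasets.
        """
        from rbgof import generate_data

        X3 = np.column_stack([np.ones(3), [0.0, 1.0, 2.0]])
        truth_false = np.array([0.875, 0.327, 0.107, 0.198, 0.908])
        medians = {}
        for n in (10, 50, 200):
            rbs = []
            for rep in range(20):
                data = generate_data(X3, beta=[0.5, -1.0], n=n, seed=1000 + rep)
                rbs.append(assess(data, "euclid", delta=0.05, N=20_000, seed=rep).rb0)
            medians[n] = np.median(rbs)
        assert medians[10] <= medians[50] <= medians[200]
        assert medians[200] > 1.0

        rbs_false = []
        for rep in range(20):
            data = generate_data(design_m5, truth=truth_false, n=200, seed=2000 + rep)
            rbs_false.append(assess(data, "euclid", delta=0.05, N=20_000, seed=rep).rb0)
        assert np.median(rbs_false) < 0.05
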