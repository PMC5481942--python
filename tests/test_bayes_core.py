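"""Conjugate updating, KL divergence, and the resistance weight.

The independent oracles here are deliberately dumb: grid-based Bayes
(pointwise prior × likelihood, normalized numerically) and numerical
integration of the KL integrand, neither of which shares code with the
closed forms they check.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from socialbayes import bayes_core as bc


# ---------------------------------------------------------------- oracles


def grid_bayes_oracle(prior: bc.GaussianBelief, like_mean, like_prec, lo=-30.0, hi=30.0, n=60001):
    """Posterior mean/variance by brute-force normalization on a grid."""
    x = np.linspace(lo, hi, n)
    log_post = stats.norm.logpdf(x, prior.mean, math.sqrt(prior.variance))
    if like_prec > 0:
        log_post = log_post + stats.norm.logpdf(x, like_mean, 1.0 / math.sqrt(like_prec))
    w = np.exp(log_post - log_post.max())
    w /= np.trapezoid(w, x)
    mean = np.trapezoid(w * x, x)
    var = np.trapezoid(w * (x - mean) ** 2, x)
    return mean, var


def kl_numeric_oracle(p: bc.GaussianBelief, q: bc.GaussianBelief) -> float:
    """∫ p log(p/q) by adaptive quadrature over a generous support."""
    sp, sq = math.sqrt(p.variance), math.sqrt(q.variance)

    def integrand(x):
        lp = stats.norm.logpdf(x, p.mean, sp)
        lq = stats.norm.logpdf(x, q.mean, sq)
        return np.exp(lp) * (lp - lq)

    lo = p.mean - 15 * sp
    hi = p.mean + 15 * sp
    val, _ = integrate.quad(integrand, lo, hi, limit=200)
    return val


# ------------------------------------------------------------- unit tests


class TestGaussianBelief:
    @pytest.mark.parametrize("variance", [0.0, -1.0, float("nan")])
    def test_bad_variance_rejected(self, variance):
        with pytest.raises(ValueError):
            bc.GaussianBelief(mean=0.0, variance=variance)

    def test_precision(self):
        assert bc.GaussianBelief(0.0, 0.25).precision == pytest.approx(4.0)


class TestParticipantParams:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            bc.ParticipantParams({}, s2_low=0.5, s2_high=0.8, w_low=0.0, w_high=1.0)
        with pytest.raises(ValueError):
            bc.ParticipantParams({}, s2_low=1.0, s2_high=0.5, w_low=2.0, w_high=1.0)

    def test_prior_lookup(self):
        params = bc.ParticipantParams(
            {"j": 0.3}, s2_low=1.2, s2_high=0.6, w_low=0.0, w_high=1.0
        )
        low = bc.prior_for_trial(params, {"product_id": "j", "high_conf": 0})
        high = bc.prior_for_trial(params, {"product_id": "j", "high_conf": 1})
        assert (low.mean, low.variance) == (0.3, 1.2)
        assert (high.mean, high.variance) == (0.3, 0.6)
        with pytest.raises(KeyError):
            bc.prior_for_trial(params, {"product_id": "nope", "high_conf": 0})

    def test_likelihood_split(self):
        params = bc.ParticipantParams({}, 1.0, 1.0, w_low=1.0, w_high=3.0)
        trial = {"m_std": 0.7, "many_reviews": 1}
        assert bc.likelihood_for_trial(params, trial) == (0.7, 3.0)
        trial["many_reviews"] = 0
        assert bc.likelihood_for_trial(params, trial)[1] == 1.0


class TestPosteriorUpdate:
    def test_equal_precisions_meet_in_middle(self):
        post = bc.posterior_update(bc.GaussianBelief(0.0, 1.0), 1.0, 1.0)
        assert post.mean == pytest.approx(0.5)
        assert post.variance == pytest.approx(0.5)

    def test_zero_precision_is_identity(self):
        prior = bc.GaussianBelief(0.37, 2.1)
        post = bc.posterior_update(prior, 5.0, 0.0)
        assert post.mean == prior.mean
        assert post.variance == prior.variance

    def test_worked_example_against_grid(self):
        prior = bc.GaussianBelief(0.2, 0.5)
        post = bc.posterior_update(prior, 1.0, 4.0)
        assert post.mean == pytest.approx(0.73333333, abs=1e-6)
        assert post.variance == pytest.approx(0.16666667, abs=1e-6)
        gm, gv = grid_bayes_oracle(prior, 1.0, 4.0)
        assert post.mean == pytest.approx(gm, abs=1e-4)
        assert post.variance == pytest.approx(gv, abs=1e-4)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        mu=st.floats(-3, 3),
        var=st.floats(0.05, 5),
        lm=st.floats(-3, 3),
        lp=st.floats(0, 10),
    )
    def test_conjugacy_matches_grid(self, mu, var, lm, lp):
        prior = bc.GaussianBelief(mu, var)
        post = bc.posterior_update(prior, lm, lp)
        gm, gv = grid_bayes_oracle(prior, lm, lp)
        assert post.mean == pytest.approx(gm, abs=1e-4)
        assert post.variance == pytest.approx(gv, abs=1e-4)

    def test_convex_combination_weight_is_resistance(self):
        prior = bc.GaussianBelief(-0.4, 0.8)
        for lp in [0.0, 0.3, 2.0, 50.0]:
            post = bc.posterior_update(prior, 1.6, lp)
            r = bc.resistance_weight(prior.precision, lp)
            assert post.mean == pytest.approx(r * prior.mean + (1 - r) * 1.6, abs=1e-12)


class TestTrialLoglik:
    def _params(self, **kw):
        defaults = dict(s2_low=1.0, s2_high=1.0, w_low=0.0, w_high=0.0)
        defaults.update(kw)
        return bc.ParticipantParams({"j": 0.0}, **defaults)

    def _trial(self, **kw):
        t = dict(product_id="j", high_conf=0, many_reviews=0, m_std=0.0, r1=0.0, r2=0.0)
        t.update(kw)
        return t

    def test_standard_normal_at_zero(self):
        ll = bc.trial_loglik(self._params(), self._trial())
        assert ll == pytest.approx(-math.log(2 * math.pi), abs=1e-10)

    def test_moving_r1_from_prior_mean_decreases(self):
        lls = [
            bc.trial_loglik(self._params(), self._trial(r1=r)) for r in [0.0, 0.5, 1.0, 2.0]
        ]
        assert all(a > b for a, b in zip(lls, lls[1:]))

    def test_against_density_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            s2h = rng.uniform(0.1, 2.0)
            params = bc.ParticipantParams(
                {"j": rng.normal()},
                s2_low=s2h + rng.uniform(0, 2),
                s2_high=s2h,
                w_low=rng.uniform(0, 2),
                w_high=rng.uniform(2, 5),
            )
            trial = self._trial(
                high_conf=int(rng.integers(2)),
                many_reviews=int(rng.integers(2)),
                m_std=rng.normal(),
                r1=rng.normal(),
                r2=rng.normal(),
            )
            prior = bc.prior_for_trial(params, trial)
            m, w = bc.likelihood_for_trial(params, trial)
            post = bc.posterior_update(prior, m, w)
            expected = stats.norm.logpdf(
                trial["r1"], prior.mean, math.sqrt(prior.variance)
            ) + stats.norm.logpdf(trial["r2"], post.mean, math.sqrt(post.variance))
            assert bc.trial_loglik(params, trial) == pytest.approx(expected, abs=1e-10)


class TestKL:
    def test_identity_is_zero(self):
        b = bc.GaussianBelief(0.3, 0.7)
        assert bc.kl_prior_to_posterior(b, b) == 0.0

    def test_pure_mean_shift(self):
        kl = bc.kl_prior_to_posterior(bc.GaussianBelief(0, 1), bc.GaussianBelief(1, 1))
        assert kl == pytest.approx(0.5)

    def test_pure_variance_change(self):
        kl = bc.kl_prior_to_posterior(bc.GaussianBelief(0, 1), bc.GaussianBelief(0, 0.5))
        assert kl == pytest.approx(0.1534264, abs=1e-6)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        m1=st.floats(-3, 3),
        v1=st.floats(0.05, 20),
        m2=st.floats(-3, 3),
        v2=st.floats(0.05, 20),
    )
    def test_matches_numerical_integration(self, m1, v1, m2, v2):
        p, q = bc.GaussianBelief(m1, v1), bc.GaussianBelief(m2, v2)
        kl = bc.kl_prior_to_posterior(p, q)
        assert kl >= 0.0
        assert kl == pytest.approx(kl_numeric_oracle(p, q), abs=1e-6)

    def test_monotone_in_review_precision(self):
        """More reliable reviews move beliefs more: KL rises, resistance falls."""
        prior = bc.GaussianBelief(0.0, 1.0)
        kls, res = [], []
        for w in [0.1, 0.5, 1.0, 3.0, 10.0]:
            post = bc.posterior_update(prior, 1.5, w)
            kls.append(bc.kl_prior_to_posterior(prior, post))
            res.append(bc.resistance_weight(prior.precision, w))
        assert all(a < b for a, b in zip(kls, kls[1:]))
        assert all(a > b for a, b in zip(res, res[1:]))


class TestResistance:
    def test_reviews_ignored_gives_one(self):
        assert bc.resistance_weight(1.0, 0.0) == 1.0

    def test_prior_discarded_limit_is_zero(self):
        vals = [bc.resistance_weight(1.0 / v, 1.0) for v in [1e2, 1e4, 1e6]]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(0.0, abs=1e-5)

    def test_equal_precision_symmetry(self):
        assert bc.resistance_weight(2.5, 2.5) == pytest.approx(0.5)

    def test_participant_mean(self):
        assert bc.participant_resistance([1.0] * 7) == 1.0
        assert bc.participant_resistance([0.0, 1.0]) == 0.5
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 1, size=210)
        assert bc.participant_resistance(vals) == pytest.approx(
            float(sum(vals)) / 210, abs=1e-12
        )
        with pytest.raises(ValueError):
            bc.participant_resistance([])


class TestDeriveOneTrial:
    def test_zero_weight_trial_is_inert(self):
        params = bc.ParticipantParams({"j": 0.4}, 1.0, 0.5, w_low=0.0, w_high=0.0)
        trial = dict(product_id="j", high_conf=1, many_reviews=1, m_std=2.0)
        d = bc.derive_one_trial(params, trial)
        assert d.kl == 0.0
        assert d.resistance == 1.0
        assert d.posterior == d.prior

    def test_invariants_validated(self):
        good = bc.derive_one_trial(
            bc.ParticipantParams({"j": 0.0}, 1.0, 1.0, w_low=2.0, w_high=2.0),
            dict(product_id="j", high_conf=0, many_reviews=0, m_std=1.0),
        )
        assert good.prior.precision + good.likelihood_precision == pytest.approx(
            good.posterior.precision, abs=1e-10
        )
        assert good.prior.mean <= good.posterior.mean <= good.likelihood_mean
        with pytest.raises(ValueError):
            bc.TrialDerived(
                prior=good.prior,
                likelihood_mean=good.likelihood_mean,
                likelihood_precision=good.likelihood_precision,
                posterior=good.posterior,
                kl=-0.1,
                resistance=good.resistance,
            )
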