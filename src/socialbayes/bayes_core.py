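"""Gaussian belief machinery for reliability-weighted social updating.

A person's pre-review value estimate for a product is modelled as a Gaussian
prior whose variance depends on their stated confidence (a per-participant
variance for low-confidence trials, shrunk by a nonpositive offset on
high-confidence trials).  The crowd's star rating acts as a Gaussian
likelihood whose precision scales with the perceived number of reviews.
Conjugate updating yields the posterior that generates the second rating.

Two trial-level summaries are derived from the fitted beliefs:

* the KL divergence from prior to posterior, the magnitude of the belief
  update in nats, and
* the *resistance* weight — the share of the posterior mean contributed by
  the prior mean, ``prior_precision / (prior_precision + review_precision)``.
  It is 1 when the reviews are ignored and tends to 0 when the prior is
  discarded.

Parameter identifiability: the perceived review count ``v + v'·I`` and the
perceived review variance ``tau^2`` enter the likelihood only through their
ratio, so :class:`ParticipantParams` stores the two identifiable precisions
``w_low = v / tau^2`` and ``w_high = (v + v') / tau^2`` and fixes
``tau^2 = 1`` for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "VAR_FLOOR",
    "GaussianBelief",
    "ParticipantParams",
    "TrialDerived",
    "prior_for_trial",
    "likelihood_for_trial",
    "posterior_update",
    "trial_loglik",
    "kl_prior_to_posterior",
    "resistance_weight",
    "participant_resistance",
    "derive_one_trial",
]

#: Variances below this are clamped before any division; well below the
#: resolution of z-scored behavioral data.
VAR_FLOOR = 1e-8

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class GaussianBelief:
    """A (mean, variance) pair serving as prior, likelihood, or posterior."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean):
            raise ValueError(f"belief mean must be finite, got {self.mean}")
        if not (self.variance > 0.0) or not np.isfinite(self.variance):
            raise ValueError(f"belief variance must be positive, got {self.variance}")

    @property
    def precision(self) -> float:
        return 1.0 / max(self.variance, VAR_FLOOR)

    def logpdf(self, x: float) -> float:
        v = max(self.variance, VAR_FLOOR)
        return -0.5 * (_LOG_2PI + math.log(v) + (x - self.mean) ** 2 / v)


@dataclass
class ParticipantParams:
    """Per-participant model: one prior mean per product plus four
    variance/precision parameters.

    ``s2_low``/``s2_high`` are the prior variances on low/high-confidence
    trials (high confidence means a tighter prior, so ``s2_high <= s2_low``);
    ``w_low``/``w_high`` are the perceived review precisions on few/many
    review trials (more reviews mean a more reliable crowd signal, so
    ``w_high >= w_low``).
    """

    prior_means: dict
    s2_low: float
    s2_high: float
    w_low: float
    w_high: float
    tau2_report: float = field(default=1.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.s2_high <= self.s2_low):
            raise ValueError(
                f"prior variances must satisfy 0 < s2_high <= s2_low, "
                f"got s2_high={self.s2_high}, s2_low={self.s2_low}"
            )
        if not (0.0 <= self.w_low <= self.w_high):
            raise ValueError(
                f"review precisions must satisfy 0 <= w_low <= w_high, "
                f"got w_low={self.w_low}, w_high={self.w_high}"
            )
        if not (self.tau2_report > 0.0):
            raise ValueError("tau2_report must be positive")

    def prior_variance(self, high_conf: int) -> float:
        return self.s2_high if high_conf else self.s2_low

    def review_precision(self, many_reviews: int) -> float:
        return self.w_high if many_reviews else self.w_low


@dataclass(frozen=True)
class TrialDerived:
    """Per-trial model outputs: beliefs plus the two update summaries."""

    prior: GaussianBelief
    likelihood_mean: float
    likelihood_precision: float
    posterior: GaussianBelief
    kl: float
    resistance: float

    def __post_init__(self) -> None:
        if self.likelihood_precision < 0.0:
            raise ValueError("likelihood precision must be non-negative")
        gap = self.posterior.precision - self.prior.precision - self.likelihood_precision
        if abs(gap) > 1e-6 * max(1.0, self.posterior.precision):
            raise ValueError("posterior precision must equal prior + likelihood precision")
        lo = min(self.prior.mean, self.likelihood_mean) - 1e-9
        hi = max(self.prior.mean, self.likelihood_mean) + 1e-9
        if self.likelihood_precision > 0 and not (lo <= self.posterior.mean <= hi):
            raise ValueError("posterior mean must lie between prior and likelihood means")
        if self.kl < 0.0:
            raise ValueError("KL divergence must be non-negative")
        if not (0.0 <= self.resistance <= 1.0):
            raise ValueError("resistance must lie in [0, 1]")


def prior_for_trial(params: ParticipantParams, trial: Mapping) -> GaussianBelief:
    """Prior belief for one trial: product-specific mean, confidence-split variance."""
    pid = trial["product_id"]
    if pid not in params.prior_means:
        raise KeyError(f"no prior mean for product {pid!r}")
    return GaussianBelief(
        mean=float(params.prior_means[pid]),
        variance=params.prior_variance(int(trial["high_conf"])),
    )


def likelihood_for_trial(params: ParticipantParams, trial: Mapping) -> tuple[float, float]:
    """Review evidence for one trial: (mean on the standardized scale, precision)."""
    m_std = float(trial["m_std"])
    if not np.isfinite(m_std):
        raise ValueError("m_std missing or non-finite on trial")
    return m_std, params.review_precision(int(trial["many_reviews"]))


def posterior_update(
    prior: GaussianBelief, likelihood_mean: float, likelihood_precision: float
) -> GaussianBelief:
    """Conjugate Gaussian update: precisions add, means combine precision-weighted."""
    if likelihood_precision < 0.0:
        raise ValueError("likelihood precision must be non-negative")
    p0 = prior.precision
    p_post = p0 + likelihood_precision
    mean = (p0 * prior.mean + likelihood_precision * likelihood_mean) / p_post
    return GaussianBelief(mean=mean, variance=1.0 / p_post)


def trial_loglik(params: ParticipantParams, trial: Mapping) -> float:
    """Log-likelihood of one trial's two ratings.

    The first rating is a draw from the prior, the second from the posterior
    formed after seeing the reviews; the trial contributes the sum of both
    log-densities.
    """
    prior = prior_for_trial(params, trial)
    m_std, w = likelihood_for_trial(params, trial)
    post = posterior_update(prior, m_std, w)
    return prior.logpdf(float(trial["r1"])) + post.logpdf(float(trial["r2"]))


def kl_prior_to_posterior(prior: GaussianBelief, posterior: GaussianBelief) -> float:
    """KL(prior ‖ posterior) between two Gaussians, in nats.

    ``log(sd_post / sd_prior) + (var_prior + (mu_prior - mu_post)^2) /
    (2 var_post) - 1/2``; zero iff the two beliefs coincide.
    """
    vp = max(prior.variance, VAR_FLOOR)
    vq = max(posterior.variance, VAR_FLOOR)
    kl = 0.5 * math.log(vq / vp) + (vp + (prior.mean - posterior.mean) ** 2) / (2.0 * vq) - 0.5
    # closed form can go a hair negative through rounding when p == q
    return max(kl, 0.0)


def resistance_weight(prior_precision: float, review_precision: float) -> float:
    """Bayesian weight of the prior mean in the posterior mean.

    1 when the review evidence carries no weight (reviews ignored), tending
    to 0 as the prior precision vanishes relative to the review precision
    (prior discarded).
    """
    if not (prior_precision > 0.0):
        raise ValueError("prior precision must be positive")
    if review_precision < 0.0:
        raise ValueError("review precision must be non-negative")
    return prior_precision / (prior_precision + review_precision)


def participant_resistance(resistances: Iterable[float]) -> float:
    """Participant-level resistance: arithmetic mean over the trial values."""
    arr = np.asarray(list(resistances), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot average resistance over zero trials")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("resistance values must lie in [0, 1]")
    return float(arr.mean())


def derive_one_trial(params: ParticipantParams, trial: Mapping) -> TrialDerived:
    """All model-derived quantities for a single trial."""
    prior = prior_for_trial(params, trial)
    m_std, w = likelihood_for_trial(params, trial)
    post = posterior_update(prior, m_std, w)
    return TrialDerived(
        prior=prior,
        likelihood_mean=m_std,
        likelihood_precision=w,
        posterior=post,
        kl=kl_prior_to_posterior(prior, post),
        resistance=resistance_weight(prior.precision, w),
    )
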