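"""Synthetic review summaries and two-phase rating data.

The generator emulates the study conditions the analysis assumes: 18
participants each rate 210 retail products twice on a 0–500 slider, the
second time after seeing an Amazon-style review summary (mean stars, review
count, 5-bin histogram).  Ratings follow the package's own generative
model — the first liking rating is a draw from the participant's Gaussian
prior, the second from the conjugate posterior formed with the crowd mean,
weighted by a review precision that depends on whether the product has many
reviews.

Confidence is linked to belief precision, discounted when the prior and the
crowd disagree and boosted at the extremes of the value scale (two robust
empirical signatures of confidence reports that the conjugate-Gaussian
posterior alone does not produce).  Raw slider values are produced by
participant-specific affine maps with jittered centers and scales so the
z-scoring stage downstream is exercised non-trivially.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import HIST_COLUMNS, SLIDER_MAX, stars_to_slider

__all__ = [
    "ReviewCountLaw",
    "StarMeanLaw",
    "ParamRanges",
    "ConfidenceLink",
    "CohortSpec",
    "SimulatedCohort",
    "simulate_reviews",
    "simulate_participant",
    "simulate_cohort",
]


@dataclass(frozen=True)
class ReviewCountLaw:
    """Heavy-tailed (log-normal) law for how many people reviewed a product."""

    mu: float = math.log(60.0)
    sigma: float = 1.1
    lo: int = 3
    hi: int = 2000

    def __post_init__(self):
        if self.lo < 1 or self.hi < self.lo or self.sigma < 0:
            raise ValueError("invalid review-count law")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        counts = np.rint(np.exp(rng.normal(self.mu, self.sigma, size=n)))
        return np.clip(counts, self.lo, self.hi).astype(int)


@dataclass(frozen=True)
class StarMeanLaw:
    """Truncated-normal law on [1, 5] for a product's mean star rating.

    Defaults skew high, as retail review means do.
    """

    mean: float = 3.6
    sd: float = 0.65
    lo: float = 1.0
    hi: float = 5.0

    def __post_init__(self):
        if not (self.lo < self.hi) or self.sd <= 0:
            raise ValueError("invalid star-mean law")

    def _frozen(self):
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self._frozen().rvs(size=n, random_state=rng)

    @property
    def expected_mean(self) -> float:
        """Mean of the truncated law (not the untruncated ``mean``)."""
        return float(self._frozen().mean())


@dataclass(frozen=True)
class ParamRanges:
    """Simulation intervals for each participant's structural parameters.

    ``s2_high`` is drawn as a ratio of ``s2_low`` and ``w_high`` as
    ``w_low`` plus a positive gap, so the model's ordering constraints
    (tighter prior under high confidence, heavier weight under many
    reviews) hold for every draw.
    """

    s2_low: tuple[float, float] = (0.35, 0.8)
    s2_high_ratio: tuple[float, float] = (0.3, 0.85)
    w_low: tuple[float, float] = (0.3, 1.0)
    w_high_gap: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self):
        for name in ("s2_low", "s2_high_ratio", "w_low", "w_high_gap"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ValueError(f"interval {name} is not ordered")
        if self.s2_low[0] <= 0 or self.s2_high_ratio[0] <= 0:
            raise ValueError("variance intervals must be positive")
        if self.s2_high_ratio[1] > 1.0:
            raise ValueError("s2_high_ratio must stay within (0, 1]")
        if self.w_low[0] < 0 or self.w_high_gap[0] < 0:
            raise ValueError("precision intervals must be non-negative")

    def draw(self, rng: np.random.Generator) -> dict[str, float]:
        s2_low = rng.uniform(*self.s2_low)
        s2_high = s2_low * rng.uniform(*self.s2_high_ratio)
        w_low = rng.uniform(*self.w_low)
        w_high = w_low + rng.uniform(*self.w_high_gap)
        return {"s2_low": s2_low, "s2_high": s2_high, "w_low": w_low, "w_high": w_high}


@dataclass(frozen=True)
class ConfidenceLink:
    """How reported confidence is generated from the trial's beliefs.

    Second confidence is ``slope * log(posterior precision)
    − conflict_weight * |R1 − M| + extremity_weight * (posterior mean −
    its participant mean)² + noise``: precision-tracking with a penalty for
    prior–crowd disagreement and a bonus at the ends of the rating scale.
    The extremity quadratic is centered on the participant's own mean
    posterior value because all judgments are analyzed on per-participant
    standardized scales.
    """

    slope: float = 1.0
    conflict_weight: float = 0.25
    extremity_weight: float = 0.4
    noise_sd: float = 1.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to draw a reproducible synthetic cohort."""

    n_participants: int = 18
    n_products: int = 210
    review_count_law: ReviewCountLaw = field(default_factory=ReviewCountLaw)
    star_mean_law: StarMeanLaw = field(default_factory=StarMeanLaw)
    param_ranges: ParamRanges = field(default_factory=ParamRanges)
    confidence_link: ConfidenceLink = field(default_factory=ConfidenceLink)
    #: jitter intervals for the participant-specific slider maps
    rating_center: tuple[float, float] = (230.0, 270.0)
    rating_scale: tuple[float, float] = (65.0, 85.0)
    conf_center: tuple[float, float] = (230.0, 270.0)
    conf_scale: tuple[float, float] = (55.0, 75.0)
    seed: int = 7

    def __post_init__(self):
        if self.n_participants < 1 or self.n_products < 1:
            raise ValueError("cohort must have at least one participant and product")


class SimulatedCohort(NamedTuple):
    trials: pd.DataFrame
    reviews: pd.DataFrame
    true_params: pd.DataFrame
    true_prior_means: pd.DataFrame


def _product_ids(n: int) -> list[str]:
    return [f"prod{j:03d}" for j in range(1, n + 1)]


def simulate_reviews(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the product set: star means, review counts, histograms.

    The histogram is multinomial over the 5 star bins with shifted-binomial
    probabilities ``1 + Binomial(4, (target - 1) / 4)``, whose mean equals
    the drawn target star mean exactly (so the summary mean is unbiased);
    ``mean_stars`` is then recomputed from the drawn histogram, making the
    summary exactly self-consistent.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = spec.n_products
    target = spec.star_mean_law.sample(rng, n)
    counts = spec.review_count_law.sample(rng, n)
    bins = np.arange(1, 6, dtype=float)
    q = (target - 1.0) / 4.0
    k = np.arange(5)
    probs = stats.binom.pmf(k[None, :], 4, q[:, None])
    hist = np.stack([rng.multinomial(c, p) for c, p in zip(counts, probs)])
    mean_stars = hist @ bins / counts
    out = pd.DataFrame({"product_id": _product_ids(n), "mean_stars": mean_stars, "n_reviews": counts})
    out[HIST_COLUMNS] = hist
    return out


@dataclass(frozen=True)
class _SliderMaps:
    rating_center: float
    rating_scale: float
    conf_center: float
    conf_scale: float

    def rating_raw(self, z: np.ndarray) -> np.ndarray:
        return np.clip(self.rating_center + self.rating_scale * z, 0.0, SLIDER_MAX)

    def conf_raw(self, z: np.ndarray) -> np.ndarray:
        return np.clip(self.conf_center + self.conf_scale * z, 0.0, SLIDER_MAX)


def _draw_maps(spec: CohortSpec, rng: np.random.Generator) -> _SliderMaps:
    return _SliderMaps(
        rating_center=rng.uniform(*spec.rating_center),
        rating_scale=rng.uniform(*spec.rating_scale),
        conf_center=rng.uniform(*spec.conf_center),
        conf_scale=rng.uniform(*spec.conf_scale),
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def simulate_participant(
    spec: CohortSpec,
    reviews: pd.DataFrame,
    true_params: dict[str, float],
    prior_means: np.ndarray,
    seed: int | np.random.Generator,
    maps: _SliderMaps | None = None,
    participant_id: str = "p01",
) -> pd.DataFrame:
    """One participant's 2 × n_products ratings from the generative model.

    Latent confidence C1 is drawn first; its within-participant median
    split selects which prior variance actually generates R1, so the
    high-confidence flag recovered downstream is linked to the tighter
    prior by construction.  All four judgments are mapped back onto the raw
    0–500 slider through the participant's affine maps.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if maps is None:
        maps = _SliderMaps(
            rating_center=float(np.mean(spec.rating_center)),
            rating_scale=float(np.mean(spec.rating_scale)),
            conf_center=float(np.mean(spec.conf_center)),
            conf_scale=float(np.mean(spec.conf_scale)),
        )
    link = spec.confidence_link
    n = len(reviews)
    if len(prior_means) != n:
        raise ValueError("need one true prior mean per product")

    s2_low, s2_high = true_params["s2_low"], true_params["s2_high"]
    w_low, w_high = true_params["w_low"], true_params["w_high"]

    c1_lat = rng.normal(size=n)
    high_conf = c1_lat > np.median(c1_lat)
    s2 = np.where(high_conf, s2_high, s2_low)

    r1_z = prior_means + rng.normal(size=n) * np.sqrt(s2)

    m_z = (stars_to_slider(reviews["mean_stars"].to_numpy()) - maps.rating_center) / maps.rating_scale
    many = reviews["n_reviews"].to_numpy() > np.median(reviews["n_reviews"].to_numpy())
    w = np.where(many, w_high, w_low)

    post_prec = 1.0 / s2 + w
    a = (1.0 / s2) / post_prec
    post_mean = a * prior_means + (1.0 - a) * m_z
    r2_z = post_mean + rng.normal(size=n) * np.sqrt(1.0 / post_prec)

    c2_lat = (
        link.slope * np.log(post_prec)
        - link.conflict_weight * np.abs(r1_z - m_z)
        + link.extremity_weight * (post_mean - post_mean.mean()) ** 2
        + rng.normal(size=n) * link.noise_sd
    )

    out = pd.DataFrame(
        {
            "participant_id": participant_id,
            "product_id": reviews["product_id"].to_numpy(),
            "r1_raw": maps.rating_raw(r1_z),
            "c1_raw": maps.conf_raw(_zscore(c1_lat)),
            "r2_raw": maps.rating_raw(r2_z),
            "c2_raw": maps.conf_raw(_zscore(c2_lat)),
            "mean_stars": reviews["mean_stars"].to_numpy(),
            "n_reviews": reviews["n_reviews"].to_numpy(),
        }
    )
    out[HIST_COLUMNS] = reviews[HIST_COLUMNS].to_numpy()
    return out


def simulate_cohort(spec: CohortSpec | None = None) -> SimulatedCohort:
    """Full cohort draw: reviews, trials, and the true-parameter tables.

    Structural parameters come from ``spec.param_ranges``; prior means are
    i.i.d. standard normal on the standardized scale.  Everything is driven
    by child generators spawned from ``spec.seed``.
    """
    spec = spec or CohortSpec()
    root = np.random.SeedSequence(spec.seed)
    kids = root.spawn(spec.n_participants + 1)
    reviews = simulate_reviews(spec, np.random.default_rng(kids[0]))

    trials_parts, param_rows, mu_rows = [], [], []
    for i in range(spec.n_participants):
        pid = f"p{i + 1:02d}"
        rng = np.random.default_rng(kids[i + 1])
        params = spec.param_ranges.draw(rng)
        mu = rng.normal(size=spec.n_products)
        maps = _draw_maps(spec, rng)
        trials_parts.append(
            simulate_participant(spec, reviews, params, mu, rng, maps, pid)
        )
        param_rows.append(
            {
                "participant_id": pid,
                **params,
                "rating_center": maps.rating_center,
                "rating_scale": maps.rating_scale,
            }
        )
        mu_rows.append(
            pd.DataFrame(
                {"participant_id": pid, "product_id": reviews["product_id"], "mu_true": mu}
            )
        )
    return SimulatedCohort(
        trials=pd.concat(trials_parts, ignore_index=True),
        reviews=reviews,
        true_params=pd.DataFrame(param_rows),
        true_prior_means=pd.concat(mu_rows, ignore_index=True),
    )


def zero_weight_spec(base: CohortSpec | None = None, seed: int | None = None) -> CohortSpec:
    """A cohort spec whose participants give reviews no weight (w = 0)."""
    base = base or CohortSpec()
    ranges = replace(base.param_ranges, w_low=(0.0, 0.0), w_high_gap=(0.0, 0.0))
    return replace(base, param_ranges=ranges, seed=base.seed if seed is None else seed)
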