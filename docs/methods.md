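# Methods

## The model

Each participant *i* rates each of *J* products twice on a 0–500 slider:
a first liking rating R1 with confidence C1 (no social information), and a
second rating R2 with confidence C2 after seeing the product's review
summary — mean stars *m* ∈ [1,5], reviewer count *n*, 5-bin histogram.
All four judgment types are z-scored within participant (sample SD, n−1)
before any modelling, removing idiosyncratic scale use.

The generative account of the two ratings is conjugate-Gaussian:

- **Prior.** R1 ~ N(μ_ij, σ²_i + σ′_i·I_highconf), with one free prior
  mean per product and a nonpositive confidence offset σ′_i: trials rated
  above the participant's median C1 get the tighter variance. Internally
  the two variances are stored directly as (s2_low, s2_high) with
  s2_high ≤ s2_low — identical content, better numerics.
- **Review evidence.** The crowd mean acts as a Gaussian likelihood with
  precision (v_i + v′_i·I_manyreviews)/τ²_i, split at the stimulus-set
  median review count. Ratings identify only the two ratios, so the
  package stores the identifiable precisions w_low = v/τ² and
  w_high = (v+v′)/τ² (w_high ≥ w_low) and fixes τ² = 1 for reporting.
- **Posterior.** Precisions add; the posterior mean is the
  precision-weighted average of prior mean and crowd mean. R2 is a draw
  from this posterior.

Two trial summaries follow from the fitted beliefs. The belief-update
magnitude is the Gaussian KL divergence KL(prior ‖ posterior) =
log(σ_post/σ_prior) + (σ²_prior + (μ_prior − μ_post)²)/(2σ²_post) − ½,
reported in nats. The **resistance** to the reviews is the weight of the
prior mean in the posterior mean, prior precision / (prior precision +
review precision): 1 when reviews are ignored, → 0 when the prior is
discarded; it is averaged over products to give a per-participant index.

The crowd mean is made commensurable with the standardized ratings by the
monotone affine map stars [1,5] → slider [0,500] followed by the
participant's R1 z-transform. Both median splits use a strict ">"; ties
go to the low group. The confidence split is per participant; the
review-count split is computed once over the product set.

## Fitting

Parameters per participant: J prior means plus (s2_low, s2_high, w_low,
w_high), estimated jointly by maximizing the likelihood of both ratings.
Because both densities are Gaussian and the posterior mean is affine in
μ_ij, each prior mean has the closed-form maximizer
μ* = (r1 + r2 − (1−a)·m) / (1+a), where a is the prior weight implied by
(s2, w) on that trial. The fit profiles every μ_ij analytically and
searches only the four structural parameters, reparameterized as
(log s2_high, log(s2_low − s2_high), log w_low, log(w_high − w_low)) so
both order constraints hold by construction on an unconstrained space.
Each of 10 random restarts (initial values log-uniform, variances in
[0.1, 10], precisions in [0.01, 10]) runs L-BFGS-B (ftol 1e-8) followed by
a Nelder–Mead polish — finite-difference gradients occasionally stall in
the flat valley where w → 0, and the derivative-free polish removes those
stalls; the best restart is returned. Exponents are capped and variances
floored at 1e-8 to keep wild steps finite. Fits whose w_high ends at or
below 0.05 are flagged `zero_weight` but retained in behavioral outputs.

**Known estimator property.** This is an incidental-parameter setting:
two observations share each profiled μ_ij. Joint ML is therefore *not*
consistent for the variance-side parameters — prior variances are
underestimated by roughly a factor of two at J = 210, w_low is shrunk
toward 0 and w_high inflated, and at the boundary w = 0 the fitted weight
retains an upward bias (the profiled means absorb the misfit a spurious
positive w introduces, and the smaller implied posterior variance pays
for it). Simulation at the default scale shows fitted w_high has ≈ 57%
of its sampling mass above 0.05 when the true weight is zero. The
quantities the pipeline actually reports are unaffected in practice: the
fit-quality correlations (fitted prior mean ↔ R1, posterior mean ↔ R2)
sit near 0.90–0.92, parameter *orderings* are preserved, and zero-weight
cohorts still collapse to near-unit resistance and near-zero KL relative
to matched cohorts with real review weight. Interpret the absolute scale
of fitted variances/precisions with this bias in mind.

## Regression battery

Three mixed-effects analyses on the standardized trials (statsmodels
MixedLM, ML fits — likelihood-ratio tests on fixed effects require ML,
so REML is off):

1. update (R2 − R1) ~ dev + dev×many_reviews + dev×high_conf, where
   dev = M − R1;
2. confidence update (C2 − C1) ~ |R1 − M|;
3. C2 ~ R2².

Each model has a participant random intercept plus an uncorrelated random
slope (variance component) for every focal term; each reported LRT drops
a focal fixed effect together with its random-slope variance, giving 2-df
chi-square statistics. The interactions use the median-split indicators,
not continuous C1 or n — the psychological scaling of those quantities is
unlikely to be linear. When a random-effects fit is singular (common for
difference outcomes, whose participant means are exactly zero after
z-scoring) the model is refit with the simplified structure and flagged;
the last-resort fallback is pooled OLS, which equals the mixed ML
solution at the zero-variance boundary, so the reported log-likelihoods
remain exact.

The qualitative signatures of reliability-weighted integration are:
dev > 0 (movement toward the crowd), dev×many_reviews > 0 (more movement
when the crowd is large), dev×high_conf < 0 (less movement when initially
confident), |R1 − M| effect on confidence update < 0 (disagreement costs
confidence), and R2² effect on C2 > 0 (confidence highest at the ends of
the scale).

## Synthetic cohort generator

The generator emulates the study conditions: 18 participants × 210
products, ratings on a 0–500 slider, Amazon-style review summaries. It
is the package's own generative model run forward, with these laws:

- **Review counts**: log-normal, median 60, σ_log = 1.1, clipped to
  [3, 2000] — heavy-tailed, like retail review counts.
- **Star means**: truncated normal on [1, 5], location 3.6, SD 0.65 —
  skewed high, like retail review means. Histograms are multinomial with
  shifted-binomial bin probabilities 1 + Binomial(4, (m−1)/4), whose mean
  equals the drawn target exactly; mean_stars is recomputed from the
  drawn histogram so every summary is exactly self-consistent.
- **Structural parameters** per participant: s2_low ~ U(0.35, 0.8),
  s2_high = s2_low·U(0.3, 0.85), w_low ~ U(0.3, 1.0),
  w_high = w_low + U(0.5, 2.0). Drawing the constrained parameters as
  ratio/gap keeps the orderings true for every draw. These ranges put the
  fit-quality correlations near 0.90, the value observed on real raters.
- **Prior means**: i.i.d. N(0, 1) on the standardized scale.
- **Trial flow**: a latent C1 ~ N(0,1) is drawn first and its
  within-participant median split selects the prior variance that actually
  generates R1, so the recovered high-confidence flag is linked to the
  tighter prior by construction. R2 is a posterior draw using the true w
  for the product's review-count split.
- **Confidence link**: C2 = log(posterior precision) −
  0.25·|R1 − M| + 0.4·(posterior mean − its mean)² + N(0, 1). The
  precision term expresses confidence-as-precision; the conflict and
  extremity terms reproduce two robust empirical signatures of confidence
  reports that a conjugate-Gaussian posterior alone cannot produce (its
  precision is independent of prior–evidence disagreement and of rating
  extremity — indeed, without the conflict term the generator's
  confidence-driven variance split induces a small *positive* artifact
  between |R1 − M| and confidence update, the wrong sign). The weights
  were set by matching the magnitude hierarchy of the printed behavioral
  statistics this design produces on real raters (deviation ≫ quadratic
  ≫ conflict ≫ interactions), with the precision slope and unit noise
  keeping the posterior-precision/C2 correlation near 0.27, inside the
  empirically observed band. The extremity quadratic is centered on the
  participant's own mean posterior value because the analysis operates on
  per-participant standardized scales.
- **Slider back-maps**: participant-specific affine maps with jittered
  centers (ratings U(230, 270)) and scales (U(65, 85)), clipped to
  [0, 500], so the z-scoring stage is exercised non-trivially. Clipping
  affects well under 1% of draws at the default scales.

What the generator does *not* emulate: real product categories or review
text, sequential/order effects, response times, slider anchoring,
heteroskedastic scale use within a participant, and any dependence of a
participant's prior means on the crowd's opinion. Passing tests on this
cohort therefore show that the pipeline recovers the structure the model
assumes — not that real raters obey the model.

## Problem sizes and numerical choices

Cohort-level computations (fits, regressions, derived measures) run at
the full study scale, 18 × 210 = 3,780 trials; a cohort fit takes roughly
ten seconds on one CPU and the full simulate → fit → analyze pipeline
about one minute. Oracle comparisons use a grid Bayes oracle on
[−30, 30] (60,001 points) and adaptive quadrature for KL; the profiled
prior-mean closed form is checked against parabolic interpolation, which
is exact for this quadratic objective. Degenerate inputs fail loudly:
constant rating columns raise a degenerate-scale error (they indicate
erratic raters, for which an optional |skewness| > 3 filter is provided),
non-positive variances are rejected at construction, and an
empty-derived-trials resistance average is an error rather than a NaN.

Every stochastic routine takes an explicit seed; cohort and fit seeds are
spawned per participant from a root seed, so whole-pipeline runs are
reproducible bit-for-bit given the config.
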