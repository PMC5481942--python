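"""Per-participant maximum-likelihood fitting with profiled prior means.

Each participant contributes 420 ratings (two per product).  The model has
one prior mean per product plus four structural parameters: the two prior
variances (low/high confidence) and the two perceived review precisions
(few/many reviews).  Because both ratings are Gaussian and the posterior
mean is affine in the prior mean, each product's prior mean has a unique
closed-form maximizer given the structural parameters.  The fit therefore
profiles all prior means out analytically and runs a bounded quasi-Newton
search over the four structural parameters only, on an unconstrained
log-scale that enforces s2_high <= s2_low and w_low <= w_high by
construction.  Multiple random restarts guard against local optima.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .bayes_core import (
    VAR_FLOOR,
    ParticipantParams,
    derive_one_trial,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "NonConvergenceError",
    "profile_prior_mean",
    "fit_participant",
    "fit_cohort",
    "derive_trials",
    "precision_confidence_check",
    "fit_table",
]

logger = logging.getLogger(__name__)

_LOG_2PI = np.log(2.0 * np.pi)


class NonConvergenceError(RuntimeError):
    """Every optimizer restart failed for a participant."""


@dataclass
class FitConfig:
    """Settings for the per-participant ML fit."""

    n_restarts: int = 10
    #: convergence tolerance on the objective (scipy ftol)
    tol: float = 1e-8
    #: restart initial values drawn log-uniformly from these ranges
    var_init_range: tuple[float, float] = (0.1, 10.0)
    prec_init_range: tuple[float, float] = (0.01, 10.0)
    max_iter: int = 1000
    #: fitted participants with w_high at or below this are flagged as
    #: zero-update (reviews carried no measurable weight)
    zero_weight_threshold: float = 0.05
    seed: int = 0


@dataclass
class FitResult:
    """Outcome of one participant's fit."""

    participant_id: object
    params: ParticipantParams
    loglik: float
    n_trials: int
    converged: bool
    n_restarts_used: int
    corr_prior_r1: float
    corr_post_r2: float
    zero_weight: bool
    restart_logliks: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.loglik):
            raise ValueError("fit log-likelihood must be finite")
        for name in ("corr_prior_r1", "corr_post_r2"):
            r = getattr(self, name)
            if np.isfinite(r) and not (-1.0 - 1e-9 <= r <= 1.0 + 1e-9):
                raise ValueError(f"{name} outside [-1, 1]: {r}")


def profile_prior_mean(s2: float, w: float, m_std: float, r1: float, r2: float) -> float:
    """Closed-form prior mean maximizing one trial's two-rating likelihood.

    With posterior precision P = 1/s2 + w and prior weight a = (1/s2)/P,
    the objective log N(r1; mu, s2) + log N(r2; a*mu + (1-a)*m_std, 1/P) is
    quadratic in mu; its unique maximizer is
    ``(r1 + r2 - (1-a) * m_std) / (1 + a)``.
    """
    if not (s2 > 0.0):
        raise ValueError("prior variance must be positive")
    if w < 0.0:
        raise ValueError("review precision must be non-negative")
    a = (1.0 / s2) / (1.0 / s2 + w)
    return (r1 + r2 - (1.0 - a) * m_std) / (1.0 + a)


@dataclass(frozen=True)
class _TrialArrays:
    r1: np.ndarray
    r2: np.ndarray
    m: np.ndarray
    high_conf: np.ndarray
    many: np.ndarray

    @classmethod
    def from_frame(cls, trials: pd.DataFrame) -> "_TrialArrays":
        need = ["r1", "r2", "m_std", "high_conf", "many_reviews"]
        missing = [c for c in need if c not in trials.columns]
        if missing:
            raise ValueError(f"trials not prepared for fitting; missing: {missing}")
        return cls(
            r1=trials["r1"].to_numpy(dtype=float),
            r2=trials["r2"].to_numpy(dtype=float),
            m=trials["m_std"].to_numpy(dtype=float),
            high_conf=trials["high_conf"].to_numpy(dtype=int).astype(bool),
            many=trials["many_reviews"].to_numpy(dtype=int).astype(bool),
        )


def _unpack(x: np.ndarray) -> tuple[float, float, float, float]:
    """Unconstrained 4-vector -> (s2_low, s2_high, w_low, w_high).

    s2_high = exp(x0), s2_low = s2_high + exp(x1), w_low = exp(x2),
    w_high = w_low + exp(x3): the ordering constraints hold for every x.
    """
    # cap the exponent so wild optimizer steps cannot overflow
    e = np.exp(np.clip(x, -700.0, 46.0))
    s2_high = e[0]
    s2_low = s2_high + e[1]
    w_low = e[2]
    w_high = w_low + e[3]
    return s2_low, s2_high, w_low, w_high


def _pack(s2_low: float, s2_high: float, w_low: float, w_high: float) -> np.ndarray:
    eps = 1e-12
    return np.log(
        np.maximum([s2_high, s2_low - s2_high, w_low, w_high - w_low], eps)
    )


def _profiled_negll(x: np.ndarray, arr: _TrialArrays) -> float:
    s2_low, s2_high, w_low, w_high = _unpack(x)
    s2 = np.where(arr.high_conf, s2_high, s2_low)
    s2 = np.maximum(s2, VAR_FLOOR)
    w = np.where(arr.many, w_high, w_low)
    p = 1.0 / s2 + w
    a = (1.0 / s2) / p
    mu = (arr.r1 + arr.r2 - (1.0 - a) * arr.m) / (1.0 + a)
    post_mean = a * mu + (1.0 - a) * arr.m
    post_var = 1.0 / p
    ll = -0.5 * (_LOG_2PI + np.log(s2) + (arr.r1 - mu) ** 2 / s2)
    ll += -0.5 * (_LOG_2PI + np.log(post_var) + (arr.r2 - post_mean) ** 2 / post_var)
    total = ll.sum()
    if not np.isfinite(total):
        return 1e12
    return -total


def _profiled_means(
    params: ParticipantParams, trials: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """(profiled prior means, implied posterior means) for each trial row."""
    arr = _TrialArrays.from_frame(trials)
    s2 = np.where(arr.high_conf, params.s2_high, params.s2_low)
    w = np.where(arr.many, params.w_high, params.w_low)
    p = 1.0 / np.maximum(s2, VAR_FLOOR) + w
    a = (1.0 / np.maximum(s2, VAR_FLOOR)) / p
    mu = (arr.r1 + arr.r2 - (1.0 - a) * arr.m) / (1.0 + a)
    post_mean = a * mu + (1.0 - a) * arr.m
    return mu, post_mean


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def fit_participant(
    trials: pd.DataFrame,
    config: FitConfig | None = None,
    seed: int | None = None,
) -> FitResult:
    """ML fit of one participant's structural parameters.

    ``trials`` must be a prepared table (see :func:`socialbayes.preprocess.prepare`)
    restricted to a single participant.  The prior means are profiled out at
    every objective evaluation; the best of ``n_restarts`` bounded
    quasi-Newton runs is returned.
    """
    config = config or FitConfig()
    if trials["participant_id"].nunique() != 1:
        raise ValueError("fit_participant expects trials from a single participant")
    pid = trials["participant_id"].iloc[0]
    arr = _TrialArrays.from_frame(trials)

    cells = pd.crosstab(arr.high_conf, arr.many)
    if cells.size < 4 or (cells.to_numpy() < 2).any():
        warnings.warn(
            f"participant {pid!r}: fewer than 2 trials in some "
            "confidence × review-count cell; fit may be poorly constrained",
            stacklevel=2,
        )

    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo_v, hi_v = np.log(config.var_init_range)
    lo_p, hi_p = np.log(config.prec_init_range)

    best = None
    restart_lls: list[float] = []
    n_used = 0
    for _ in range(config.n_restarts):
        s2_high0 = np.exp(rng.uniform(lo_v, hi_v))
        s2_gap0 = np.exp(rng.uniform(lo_v, hi_v))
        w_low0 = np.exp(rng.uniform(lo_p, hi_p))
        w_gap0 = np.exp(rng.uniform(lo_p, hi_p))
        x0 = _pack(s2_high0 + s2_gap0, s2_high0, w_low0, w_low0 + w_gap0)
        n_used += 1
        try:
            res = optimize.minimize(
                _profiled_negll,
                x0,
                args=(arr,),
                method="L-BFGS-B",
                options={
                    "maxiter": config.max_iter,
                    "ftol": config.tol,
                    "gtol": 1e-9,
                },
            )
        except (FloatingPointError, np.linalg.LinAlgError):  # pragma: no cover
            continue
        # derivative-free polish: finite-difference L-BFGS-B occasionally
        # stalls on the flat w -> 0 valley of the profiled surface
        res = optimize.minimize(
            _profiled_negll,
            res.x,
            args=(arr,),
            method="Nelder-Mead",
            options={"maxiter": 4000, "fatol": 1e-12, "xatol": 1e-10},
        )
        if not np.isfinite(res.fun):
            continue
        restart_lls.append(-float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise NonConvergenceError(
            f"all {config.n_restarts} restarts failed for participant {pid!r}"
        )

    s2_low, s2_high, w_low, w_high = _unpack(best.x)
    params = ParticipantParams(
        prior_means={}, s2_low=s2_low, s2_high=s2_high, w_low=w_low, w_high=w_high
    )
    mu, post_mean = _profiled_means(params, trials)
    params.prior_means = dict(zip(trials["product_id"], mu))

    return FitResult(
        participant_id=pid,
        params=params,
        loglik=-float(best.fun),
        n_trials=len(trials),
        converged=bool(best.success),
        n_restarts_used=n_used,
        corr_prior_r1=_pearson(mu, arr.r1),
        corr_post_r2=_pearson(post_mean, arr.r2),
        zero_weight=w_high <= config.zero_weight_threshold,
        restart_logliks=restart_lls,
    )


def fit_cohort(
    trials: pd.DataFrame, config: FitConfig | None = None
) -> dict[object, FitResult]:
    """Fit every participant; non-convergent fits are recorded, not fatal.

    Each participant receives an independent child seed derived from
    ``config.seed`` so the cohort fit is reproducible as a whole.
    """
    config = config or FitConfig()
    pids = list(pd.unique(trials["participant_id"]))
    seeds = np.random.SeedSequence(config.seed).generate_state(len(pids)) % (2**31)
    results: dict[object, FitResult] = {}
    for pid, s in zip(pids, seeds):
        sub = trials[trials["participant_id"] == pid]
        try:
            results[pid] = fit_participant(sub, config, seed=int(s))
        except NonConvergenceError as exc:
            logger.error("participant %r failed to converge: %s", pid, exc)
    return results


def derive_trials(fit: FitResult, trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial beliefs, KL divergences, and resistance weights for one fit."""
    if not fit.converged:
        warnings.warn(
            f"deriving trials from a non-converged fit for {fit.participant_id!r}",
            stacklevel=2,
        )
    rows = []
    for rec in trials.to_dict("records"):
        d = derive_one_trial(fit.params, rec)
        rows.append(
            {
                "participant_id": rec["participant_id"],
                "product_id": rec["product_id"],
                "prior_mean": d.prior.mean,
                "prior_var": d.prior.variance,
                "post_mean": d.posterior.mean,
                "post_var": d.posterior.variance,
                "kl": d.kl,
                "resistance": d.resistance,
            }
        )
    return pd.DataFrame(rows)


def precision_confidence_check(derived: pd.DataFrame, trials: pd.DataFrame) -> float:
    """Pearson correlation of model posterior precision with second confidence.

    The model never sees the confidence magnitudes (only their median
    split), so a positive correlation is an out-of-sample check that belief
    precision behaves like reported confidence.
    """
    merged = derived.merge(
        trials[["participant_id", "product_id", "c2"]],
        on=["participant_id", "product_id"],
        validate="one_to_one",
    )
    if len(merged) < 3:
        raise ValueError("need at least 3 trials for the precision-confidence check")
    prec = 1.0 / merged["post_var"].to_numpy(dtype=float)
    c2 = merged["c2"].to_numpy(dtype=float)
    if np.std(prec) == 0.0 or np.std(c2) == 0.0:
        raise ValueError("precision-confidence correlation undefined: zero variance")
    return float(np.corrcoef(prec, c2)[0, 1])


def fit_table(results: dict[object, FitResult], derived: pd.DataFrame | None = None) -> pd.DataFrame:
    """Cohort summary table, one row per fitted participant."""
    rows = []
    for pid, fit in results.items():
        row = {
            "participant_id": pid,
            "s2_low": fit.params.s2_low,
            "s2_high": fit.params.s2_high,
            "w_low": fit.params.w_low,
            "w_high": fit.params.w_high,
            "loglik": fit.loglik,
            "n_trials": fit.n_trials,
            "corr_prior_r1": fit.corr_prior_r1,
            "corr_post_r2": fit.corr_post_r2,
            "converged": fit.converged,
            "zero_weight": fit.zero_weight,
        }
        if derived is not None:
            sub = derived[derived["participant_id"] == pid]
            row["mean_resistance"] = float(sub["resistance"].mean())
            row["mean_kl"] = float(sub["kl"].mean())
        rows.append(row)
    return pd.DataFrame(rows)
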