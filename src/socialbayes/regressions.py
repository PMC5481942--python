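"""Hierarchical regression battery for the behavioral signatures.

Three mixed-effects analyses, all on per-participant z-scored judgments:

* rating update ``R2 − R1`` on the deviation from the crowd ``M − R1`` and
  its interactions with the median-split confidence and review-count
  indicators — updating toward the crowd, more so when the crowd is large,
  less so when initial confidence is high;
* confidence update ``C2 − C1`` on ``|R1 − M|`` — disagreement with the
  crowd costs confidence;
* second confidence ``C2`` on ``R2²`` — confidence is highest at the ends
  of the value scale.

Each model carries a participant random intercept plus an uncorrelated
random slope for every focal term (as a variance component); models are fit
by ML, and each reported likelihood-ratio test removes a focal fixed effect
together with its random-slope variance, giving 2-df chi-square statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "RegressionResult",
    "build_design",
    "fit_update_model",
    "fit_confidence_models",
    "signature_signs",
    "coefficient_frame",
    "lrt_frame",
    "coefficient_plot",
]

logger = logging.getLogger(__name__)

UPDATE_TERMS = ("dev", "dev_x_many", "dev_x_conf")

_REQUIRED = ["participant_id", "r1", "c1", "r2", "c2", "m_std", "high_conf", "many_reviews"]


@dataclass
class RegressionResult:
    """One fitted mixed model with its nested-model likelihood-ratio tests."""

    formula_label: str
    #: term -> (estimate, standard error, ci_low, ci_high)
    coefficients: dict[str, tuple[float, float, float, float]]
    #: comparison label -> (chi-square, df, p)
    lrt: dict[str, tuple[float, int, float]]
    n_obs: int
    n_participants: int
    loglik: float
    converged: bool = True
    simplified_random_structure: bool = False
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for label, (chi2, df, p) in self.lrt.items():
            if chi2 < -1e-8 or df < 1 or not (0.0 <= p <= 1.0):
                raise ValueError(f"invalid LRT entry {label}: {(chi2, df, p)}")
        for term, (est, se, lo, hi) in self.coefficients.items():
            if not (lo <= est <= hi):
                raise ValueError(f"CI does not bracket estimate for {term}")


def build_design(trials: pd.DataFrame) -> pd.DataFrame:
    """Analysis table: updates, crowd deviation, interactions, quadratic term."""
    missing = [c for c in _REQUIRED if c not in trials.columns]
    if missing:
        raise ValueError(f"trials table not prepared for regression; missing {missing}")
    out = trials[_REQUIRED].copy()
    out["update"] = out["r2"] - out["r1"]
    out["conf_update"] = out["c2"] - out["c1"]
    out["dev"] = out["m_std"] - out["r1"]
    out["abs_dev"] = out["dev"].abs()
    out["dev_x_many"] = out["dev"] * out["many_reviews"]
    out["dev_x_conf"] = out["dev"] * out["high_conf"]
    out["r2_sq"] = out["r2"] ** 2
    return out


def _fit_mixed(data: pd.DataFrame, response: str, fixed: tuple[str, ...],
               slope_terms: tuple[str, ...]):
    """ML mixed fit: random intercept + one variance component per slope term."""
    rhs = " + ".join(fixed) if fixed else "1"
    formula = f"{response} ~ {rhs}"
    vcf = {t: f"0 + {t}" for t in slope_terms}
    model = smf.mixedlm(
        formula, data, groups=data["participant_id"], re_formula="1",
        vc_formula=vcf or None,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=False, method="lbfgs", maxiter=2000)
        if not fit.converged:
            fit = model.fit(reml=False, method="cg", maxiter=2000)
    return fit


class _PooledFit:
    """Stand-in for a mixed fit whose random variances sit at the zero
    boundary, where the ML solution coincides with pooled OLS."""

    def __init__(self, ols):
        self.llf = float(ols.llf)
        self.fe_params = ols.params
        self.bse_fe = ols.bse
        self.converged = True


def _fit_with_fallback(data, response, fixed, slope_terms):
    """Full random structure, then intercept-only, then the OLS boundary.

    Random-effect variances estimated at (or next to) zero make the mixed
    Hessian singular; at that boundary the ML log-likelihood equals the
    pooled OLS one, so the last resort is exact, not an approximation.
    """
    structures = [slope_terms] if slope_terms else []
    structures.append(())
    for slopes in structures:
        try:
            fit = _fit_mixed(data, response, fixed, slopes)
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning(
                "mixed fit of %s ~ %s with slopes %s failed (%s)",
                response, fixed, slopes, exc,
            )
            continue
        if fit.converged and np.isfinite(fit.llf):
            return fit, slopes != tuple(slope_terms)
    rhs = " + ".join(fixed) if fixed else "1"
    ols = smf.ols(f"{response} ~ {rhs}", data).fit()
    return _PooledFit(ols), True


def _result_from_fits(label, data, response, fixed, focal_terms, slope_terms):
    full, simplified = _fit_with_fallback(data, response, fixed, slope_terms)
    coefs: dict[str, tuple[float, float, float, float]] = {}
    z = stats.norm.ppf(0.975)
    for term in ("Intercept", *fixed):
        est = float(full.fe_params[term])
        se = float(full.bse_fe[term])
        coefs[term] = (est, se, est - z * se, est + z * se)

    lrt: dict[str, tuple[float, int, float]] = {}
    notes: list[str] = []
    for term in focal_terms:
        red_fixed = tuple(t for t in fixed if t != term)
        red_slopes = () if simplified else tuple(t for t in slope_terms if t != term)
        reduced, red_simpl = _fit_with_fallback(data, response, red_fixed, red_slopes)
        df = 1 + (0 if simplified else int(term in slope_terms))
        chi2 = max(2.0 * (full.llf - reduced.llf), 0.0)
        p = float(stats.chi2.sf(chi2, df))
        lrt[f"drop_{term}"] = (chi2, df, p)
        if red_simpl and not simplified:
            notes.append(f"reduced model for {term} used simplified random structure")
    return RegressionResult(
        formula_label=label,
        coefficients=coefs,
        lrt=lrt,
        n_obs=len(data),
        n_participants=int(data["participant_id"].nunique()),
        loglik=float(full.llf),
        converged=bool(full.converged),
        simplified_random_structure=simplified,
        notes=notes,
    )


def fit_update_model(
    table: pd.DataFrame, terms: tuple[str, ...] = UPDATE_TERMS
) -> RegressionResult:
    """Rating update ``R2 − R1`` on crowd deviation and its interactions.

    ``terms`` selects which of the deviation and interaction predictors
    enter; each gets a fixed effect, a participant random slope, and a 2-df
    LRT against the model without it.
    """
    if table["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants for a hierarchical fit")
    return _result_from_fits(
        "update ~ " + " + ".join(terms), table, "update", terms, terms, terms
    )


def fit_confidence_models(table: pd.DataFrame) -> dict[str, RegressionResult]:
    """The two confidence regressions.

    ``conf_update``: confidence update on |R1 − M| (expected negative);
    ``c2_quadratic``: second confidence on R2² (expected positive).
    """
    if table["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants for a hierarchical fit")
    return {
        "conf_update": _result_from_fits(
            "conf_update ~ abs_dev", table, "conf_update",
            ("abs_dev",), ("abs_dev",), ("abs_dev",),
        ),
        "c2_quadratic": _result_from_fits(
            "c2 ~ r2_sq", table, "c2", ("r2_sq",), ("r2_sq",), ("r2_sq",)
        ),
    }


def signature_signs(
    update: RegressionResult, confidence: dict[str, RegressionResult]
) -> dict[str, bool]:
    """Check the qualitative signatures of reliability-weighted integration."""
    return {
        "dev_positive": update.coefficients["dev"][0] > 0,
        "dev_x_many_positive": update.coefficients["dev_x_many"][0] > 0,
        "dev_x_conf_negative": update.coefficients["dev_x_conf"][0] < 0,
        "abs_dev_negative": confidence["conf_update"].coefficients["abs_dev"][0] < 0,
        "r2_sq_positive": confidence["c2_quadratic"].coefficients["r2_sq"][0] > 0,
    }


def coefficient_frame(results: dict[str, RegressionResult]) -> pd.DataFrame:
    rows = []
    for label, res in results.items():
        for term, (est, se, lo, hi) in res.coefficients.items():
            rows.append(
                {"model": label, "term": term, "estimate": est, "se": se,
                 "ci_low": lo, "ci_high": hi, "n_obs": res.n_obs}
            )
    return pd.DataFrame(rows)


def lrt_frame(results: dict[str, RegressionResult]) -> pd.DataFrame:
    rows = []
    for label, res in results.items():
        for comp, (chi2, df, p) in res.lrt.items():
            rows.append({"model": label, "comparison": comp, "chi2": chi2, "df": df, "p": p})
    return pd.DataFrame(rows)


def coefficient_plot(results: dict[str, RegressionResult], path) -> None:
    """Fixed-effect coefficients with 95% CIs, one panel per model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(results), figsize=(4 * len(results), 3.5), squeeze=False)
    for ax, (label, res) in zip(axes[0], results.items()):
        terms = [t for t in res.coefficients if t != "Intercept"]
        est = [res.coefficients[t][0] for t in terms]
        lo = [res.coefficients[t][2] for t in terms]
        hi = [res.coefficients[t][3] for t in terms]
        y = np.arange(len(terms))
        ax.errorbar(
            est, y,
            xerr=[np.subtract(est, lo), np.subtract(hi, est)],
            fmt="o", capsize=3,
        )
        ax.axvline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_yticks(y, terms)
        ax.set_title(label, fontsize=9)
        ax.set_xlabel("fixed effect (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
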