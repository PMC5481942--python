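"""Shared fixtures: the default synthetic cohort, fitted once per session.

The full-scale cohort (18 participants × 210 products) and its
profile-likelihood fits are reused by the fitting, regression, and
acceptance tests, so the expensive work happens once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import socialbayes as sb
from socialbayes import fitting as ft

#: fit seed used for every cohort-level fit in the suite
FIT_SEED = 8


@pytest.fixture(scope="session")
def default_cohort() -> sb.SimulatedCohort:
    return sb.simulate_cohort(sb.CohortSpec())


@pytest.fixture(scope="session")
def prepared_trials(default_cohort) -> pd.DataFrame:
    return sb.prepare(default_cohort.trials, default_cohort.reviews)


@pytest.fixture(scope="session")
def cohort_fits(prepared_trials) -> dict:
    return ft.fit_cohort(prepared_trials, ft.FitConfig(seed=FIT_SEED))


@pytest.fixture(scope="session")
def cohort_derived(cohort_fits, prepared_trials) -> pd.DataFrame:
    return pd.concat(
        [
            ft.derive_trials(fit, prepared_trials[prepared_trials["participant_id"] == pid])
            for pid, fit in cohort_fits.items()
        ],
        ignore_index=True,
    )


@pytest.fixture(scope="session")
def fit_summary(cohort_fits, cohort_derived) -> pd.DataFrame:
    return ft.fit_table(cohort_fits, cohort_derived)


@pytest.fixture(scope="session")
def zero_weight_results() -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Cohort simulated with zero review weight, prepared and fitted."""
    cohort = sb.simulate_cohort(sb.zero_weight_spec())
    prepared = sb.prepare(cohort.trials, cohort.reviews)
    fits = ft.fit_cohort(prepared, ft.FitConfig(seed=FIT_SEED))
    derived = pd.concat(
        [
            ft.derive_trials(fit, prepared[prepared["participant_id"] == pid])
            for pid, fit in fits.items()
        ],
        ignore_index=True,
    )
    return prepared, fits, derived


@pytest.fixture(scope="session")
def design_table(prepared_trials) -> pd.DataFrame:
    return sb.build_design(prepared_trials)


@pytest.fixture(scope="session")
def regression_results(design_table) -> dict:
    update = sb.fit_update_model(design_table)
    confidence = sb.fit_confidence_models(design_table)
    return {"update": update, **confidence}


def toy_prepared_trials(
    seed: int,
    n: int = 210,
    s2_low: float = 0.6,
    s2_high: float = 0.3,
    w_low: float = 0.5,
    w_high: float = 1.5,
    participant_id: str = "x",
) -> pd.DataFrame:
    """Single participant drawn directly on the standardized scale.

    Bypasses the raw-slider round trip: useful when a test needs exact
    control over the generative parameters without clipping or empirical
    re-standardization.
    """
    rng = np.random.default_rng(seed)
    mu = rng.normal(size=n)
    hc = (rng.normal(size=n) > 0).astype(int)
    s2 = np.where(hc == 1, s2_high, s2_low)
    r1 = mu + rng.normal(size=n) * np.sqrt(s2)
    m = rng.normal(1.0, 1.0, size=n)
    many = (rng.normal(size=n) > 0).astype(int)
    w = np.where(many == 1, w_high, w_low)
    p = 1.0 / s2 + w
    a = (1.0 / s2) / p
    post_mean = a * mu + (1.0 - a) * m
    r2 = post_mean + rng.normal(size=n) * np.sqrt(1.0 / p)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "product_id": [f"t{j}" for j in range(n)],
            "r1": r1,
            "c1": rng.normal(size=n),
            "r2": r2,
            "c2": rng.normal(size=n),
            "m_std": m,
            "high_conf": hc,
            "many_reviews": many,
        }
    )
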