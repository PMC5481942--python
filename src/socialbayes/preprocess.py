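"""Tabular I/O, per-participant standardization, and median splits.

The pipeline works from a flat trials table: one row per
(participant, product), carrying the two liking ratings (R1, R2) and two
confidence ratings (C1, C2) on the raw 0–500 slider scale, plus the
product's review summary (mean stars, reviewer count, 5-bin histogram).

Standardization z-scores each of the four judgment columns separately
within each participant (sample SD, n−1), the same correction for
idiosyncratic scale use applied before both the behavioral regressions and
the model fit.  The review mean is brought onto each participant's
standardized rating scale by the affine map stars [1,5] → slider [0,500]
followed by that participant's R1 z-transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TRIAL_RAW_COLUMNS",
    "REVIEW_COLUMNS",
    "HIST_COLUMNS",
    "SchemaError",
    "ValidationError",
    "DegenerateScaleError",
    "ZTransform",
    "read_trials",
    "write_trials",
    "standardize",
    "r1_transforms",
    "median_split_confidence",
    "median_split_reviews",
    "stars_to_slider",
    "align_review_mean",
    "prepare",
    "filter_erratic",
]

HIST_COLUMNS = [f"hist_{k}" for k in range(1, 6)]
TRIAL_RAW_COLUMNS = [
    "participant_id",
    "product_id",
    "r1_raw",
    "c1_raw",
    "r2_raw",
    "c2_raw",
    "mean_stars",
    "n_reviews",
    *HIST_COLUMNS,
]
REVIEW_COLUMNS = ["product_id", "mean_stars", "n_reviews", *HIST_COLUMNS]

_JUDGMENTS = {"r1": "r1_raw", "c1": "c1_raw", "r2": "r2_raw", "c2": "c2_raw"}

SLIDER_MAX = 500.0
#: tolerance for the histogram-mean vs mean_stars consistency check
STAR_MEAN_TOL = 0.05


class SchemaError(ValueError):
    """The input table does not match the documented column schema."""


class ValidationError(ValueError):
    """The input table violates a content invariant (values, histograms)."""


class DegenerateScaleError(ValueError):
    """A participant used a rating scale with no variation."""


@dataclass(frozen=True)
class ZTransform:
    """The affine z-scoring transform of one participant's raw column."""

    mean: float
    sd: float

    def __call__(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd


def read_trials(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a trials CSV; return (trials, deduplicated review summaries).

    Validation errors are aggregated so one pass reports every offending
    product/row rather than stopping at the first.
    """
    trials = pd.read_csv(path)
    missing = [c for c in TRIAL_RAW_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trials file {path} is missing column(s): {', '.join(missing)}")

    problems: list[str] = []
    for col in ["r1_raw", "c1_raw", "r2_raw", "c2_raw"]:
        bad = trials.loc[(trials[col] < 0) | (trials[col] > SLIDER_MAX), col]
        if len(bad):
            problems.append(f"{col} outside [0, {SLIDER_MAX:g}] on {len(bad)} row(s)")

    reviews = (
        trials[REVIEW_COLUMNS].drop_duplicates(subset="product_id").reset_index(drop=True)
    )
    dup = trials[REVIEW_COLUMNS].drop_duplicates()
    if dup["product_id"].duplicated().any():
        clash = sorted(dup.loc[dup["product_id"].duplicated(), "product_id"].unique())
        problems.append(f"inconsistent review summaries for product(s): {clash}")

    hist = reviews[HIST_COLUMNS].to_numpy()
    hist_sum = hist.sum(axis=1)
    mismatch = reviews.loc[hist_sum != reviews["n_reviews"].to_numpy(), "product_id"]
    if len(mismatch):
        problems.append(
            "histogram does not sum to n_reviews for product(s): "
            f"{sorted(mismatch.tolist())}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        hist_mean = hist @ np.arange(1, 6) / np.where(hist_sum > 0, hist_sum, 1)
    off = np.abs(hist_mean - reviews["mean_stars"].to_numpy()) > STAR_MEAN_TOL
    off &= hist_sum > 0
    if off.any():
        problems.append(
            "histogram mean disagrees with mean_stars (>±0.05) for product(s): "
            f"{sorted(reviews.loc[off, 'product_id'].tolist())}"
        )
    if (reviews["mean_stars"] < 1).any() or (reviews["mean_stars"] > 5).any():
        problems.append("mean_stars outside [1, 5]")

    if problems:
        raise ValidationError("; ".join(problems))
    return trials, reviews


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trials table as CSV (full float precision, no index)."""
    trials.to_csv(path, index=False, float_format="%.12g")


def _zscore_column(x: np.ndarray, participant, col: str) -> np.ndarray:
    if len(np.unique(x)) < 2:
        raise DegenerateScaleError(
            f"participant {participant!r} has a constant {col} column; "
            "cannot standardize a degenerate scale"
        )
    return (x - x.mean()) / x.std(ddof=1)


def standardize(trials: pd.DataFrame) -> pd.DataFrame:
    """Z-score r1/c1/r2/c2 separately per participant (sample SD, n−1)."""
    out = trials.copy()
    for std_col, raw_col in _JUDGMENTS.items():
        out[std_col] = np.nan
    for pid, idx in out.groupby("participant_id").groups.items():
        for std_col, raw_col in _JUDGMENTS.items():
            x = out.loc[idx, raw_col].to_numpy(dtype=float)
            out.loc[idx, std_col] = _zscore_column(x, pid, raw_col)
    return out


def r1_transforms(trials: pd.DataFrame) -> dict[object, ZTransform]:
    """Per-participant z-transform of the raw first rating column."""
    out: dict[object, ZTransform] = {}
    for pid, grp in trials.groupby("participant_id"):
        x = grp["r1_raw"].to_numpy(dtype=float)
        if len(np.unique(x)) < 2:
            raise DegenerateScaleError(
                f"participant {pid!r} has a constant r1_raw column"
            )
        out[pid] = ZTransform(mean=float(x.mean()), sd=float(x.std(ddof=1)))
    return out


def median_split_confidence(trials: pd.DataFrame) -> pd.DataFrame:
    """Set high_conf = 1 iff C1 strictly exceeds the participant's median C1.

    Ties at the median get 0; the flag is invariant to any strictly monotone
    rescaling of the confidence column.
    """
    out = trials.copy()
    med = out.groupby("participant_id")["c1_raw"].transform("median")
    out["high_conf"] = (out["c1_raw"] > med).astype(int)
    return out


def median_split_reviews(reviews: pd.DataFrame) -> pd.DataFrame:
    """Flag products whose review count strictly exceeds the stimulus-set median.

    One global split over the product set — review counts are stimulus
    properties, unlike confidence, which is participant-specific.
    """
    out = reviews.copy()
    med = out["n_reviews"].median()
    out["many_reviews"] = (out["n_reviews"] > med).astype(int)
    return out


def stars_to_slider(mean_stars) -> np.ndarray:
    """Affine map of the 1–5 star scale onto the 0–500 slider scale."""
    return (np.asarray(mean_stars, dtype=float) - 1.0) / 4.0 * SLIDER_MAX


def align_review_mean(mean_stars, transform: ZTransform):
    """Review mean on a participant's standardized rating scale.

    Stars are first placed on the raw slider scale ([1,5] → [0,500],
    monotone affine) and then passed through the participant's R1
    z-transform, so the crowd mean and the participant's standardized
    ratings are commensurable.
    """
    return transform(stars_to_slider(mean_stars))


def prepare(trials: pd.DataFrame, reviews: pd.DataFrame | None = None) -> pd.DataFrame:
    """Standardize and annotate a raw trials table for modelling.

    Adds r1/c1/r2/c2 (z-scored per participant), high_conf and many_reviews
    median-split flags, and m_std (review mean on each participant's
    standardized rating scale).
    """
    if reviews is None:
        reviews = trials[REVIEW_COLUMNS].drop_duplicates(subset="product_id")
    out = standardize(trials)
    out = median_split_confidence(out)
    flags = median_split_reviews(reviews)[["product_id", "many_reviews"]]
    out = out.drop(columns=["many_reviews"], errors="ignore").merge(
        flags, on="product_id", how="left", validate="many_to_one"
    )
    transforms = r1_transforms(trials)
    out["m_std"] = [
        float(align_review_mean(ms, transforms[pid]))
        for pid, ms in zip(out["participant_id"], out["mean_stars"])
    ]
    return out


def filter_erratic(
    trials: pd.DataFrame, threshold: float = 3.0, on_raw: bool = True
) -> tuple[pd.DataFrame, list]:
    """Optionally drop participants with erratically skewed rating use.

    A participant is excluded when |skewness| of either liking-rating column
    exceeds ``threshold``.  Returns (kept trials, excluded participant ids).
    """
    cols = ["r1_raw", "r2_raw"] if on_raw else ["r1", "r2"]
    excluded = []
    for pid, grp in trials.groupby("participant_id"):
        skews = [abs(stats.skew(grp[c].to_numpy(dtype=float))) for c in cols]
        if max(skews) > threshold:
            excluded.append(pid)
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} participant(s) with rating skewness > "
            f"{threshold}: {excluded}",
            stacklevel=2,
        )
    kept = trials[~trials["participant_id"].isin(excluded)].reset_index(drop=True)
    return kept, excluded
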