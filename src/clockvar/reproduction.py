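"""Reproduction-task processing: outlier filtering, centering, and the
per-participant central-tendency slope.

Reproduced durations regress toward the mean of the experienced durations
(Vierordt's law).  The per-participant OLS slope of reproduced on presented
duration indexes the strength of that pull: 1 means veridical reproduction
(no reliance on context), 0 means the same response regardless of the
presented duration (full reliance on the prior).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CentralTendencyFit",
    "FilterSummary",
    "InsufficientVariationError",
    "filter_outliers",
    "center_durations",
    "central_tendency_fit",
    "fit_cohort",
    "condition_means",
    "fits_to_frame",
    "write_fits_csv",
    "read_fits_csv",
]

logger = logging.getLogger(__name__)


class InsufficientVariationError(ValueError):
    """Too few trials or presented levels to fit a regression line."""


@dataclass(frozen=True)
class CentralTendencyFit:
    """OLS fit of (centered) reproduced on (centered) presented duration."""

    participant_id: str
    slope: float
    intercept: float
    n_trials_used: int


@dataclass(frozen=True)
class FilterSummary:
    n_input: int
    n_removed: int

    @property
    def proportion_removed(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0


def filter_outliers(
    trials: pd.DataFrame,
    low: float = 0.5,
    high: float = 2.5,
    inclusive: bool = False,
) -> tuple[pd.DataFrame, FilterSummary]:
    """Remove trials with implausibly fast or slow responses.

    A trial is removed iff its reproduced duration is below ``low`` or above
    ``high`` (strict inequalities by default, so boundary responses are
    kept; set ``inclusive=True`` to drop the boundaries too).
    """
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    r = trials["reproduced_duration_s"]
    if inclusive:
        bad = (r <= low) | (r >= high)
    else:
        bad = (r < low) | (r > high)
    kept = trials.loc[~bad].copy()
    summary = FilterSummary(n_input=len(trials), n_removed=int(bad.sum()))
    if summary.n_removed:
        logger.info(
            "outlier filter (%g, %g): removed %d of %d trials (%.2f%%)",
            low, high, summary.n_removed, summary.n_input,
            100 * summary.proportion_removed,
        )
    return kept, summary


def center_durations(trials: pd.DataFrame, reference: float = 1.4) -> pd.DataFrame:
    """Shift presented and reproduced durations by ``-reference`` seconds.

    Centering on the middle duration puts the predictor at mean ~0, which
    makes regression intercepts and additional effects directly
    interpretable; centering with ``-reference`` undoes it.
    """
    out = trials.copy()
    out["presented_duration_s"] = out["presented_duration_s"] - reference
    out["reproduced_duration_s"] = out["reproduced_duration_s"] - reference
    return out


def central_tendency_fit(trials: pd.DataFrame) -> CentralTendencyFit:
    """Per-participant OLS of reproduced on presented duration.

    Translation-invariant: the slope is identical on raw or centered
    durations.  Requires at least 3 trials spanning at least 2 distinct
    presented levels.
    """
    pids = trials["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError(f"expected exactly one participant, got {len(pids)}")
    pid = pids[0]
    x = trials["presented_duration_s"].to_numpy(dtype=float)
    y = trials["reproduced_duration_s"].to_numpy(dtype=float)
    if x.size < 3:
        raise InsufficientVariationError(
            f"participant {pid}: need >= 3 trials, got {x.size}"
        )
    if np.unique(x).size < 2:
        raise InsufficientVariationError(
            f"participant {pid}: need >= 2 distinct presented levels"
        )
    slope, intercept = np.polyfit(x, y, 1)
    return CentralTendencyFit(
        participant_id=pid,
        slope=float(slope),
        intercept=float(intercept),
        n_trials_used=int(x.size),
    )


def fit_cohort(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant central-tendency fits over a (filtered, centered)
    cohort table; participants left without enough usable trials or
    presented-level variation are skipped with a warning."""
    fits = []
    for pid, grp in trials.groupby("participant_id", sort=False):
        try:
            fits.append(central_tendency_fit(grp))
        except InsufficientVariationError as err:
            logger.warning("dropping participant %s from slope fits: %s", pid, err)
    return fits_to_frame(fits)


def fits_to_frame(fits) -> pd.DataFrame:
    cols = ["participant_id", "slope", "intercept", "n_trials_used"]
    if not fits:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([vars(f) for f in fits], columns=cols)


def condition_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean reproduced duration per presented level x order condition."""
    if trials.empty:
        return pd.DataFrame(
            columns=["presented_duration_s", "order_condition", "n", "mean_reproduced_s"]
        )
    out = (
        trials.groupby(["presented_duration_s", "order_condition"])["reproduced_duration_s"]
        .agg(n="size", mean_reproduced_s="mean")
        .reset_index()
    )
    return out


def write_fits_csv(fits: pd.DataFrame, path) -> None:
    fits.rename(columns={"intercept": "intercept_s"}).to_csv(
        path, index=False, float_format="%.9f"
    )


def read_fits_csv(path) -> pd.DataFrame:
    return pd.read_csv(path).rename(columns={"intercept_s": "intercept"})
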