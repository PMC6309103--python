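"""Production-task processing: start-up removal, participant screening, and
drift-corrected variability measures.

The central quantity is the scaled RMSR: the root mean squared residual
around a per-participant linear drift fit of produced duration on trial
index, divided by the participant's mean production.  Detrending removes
the variance contributed by slow drifts of the internal 1-s representation
(which would inflate a plain standard deviation), and scaling by the mean
makes the measure dimensionless in accordance with the scalar property of
timing noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VariabilityMeasures",
    "ScreeningReport",
    "InsufficientDataError",
    "remove_startup",
    "screen_participants",
    "production_summary",
    "summarize_cohort",
    "implied_total_drift",
    "measures_to_frame",
    "write_measures_csv",
    "read_measures_csv",
    "write_screening_csv",
]

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Too few analyzed trials to compute a variability measure."""


@dataclass(frozen=True)
class VariabilityMeasures:
    """Per-participant production-task variability summary.

    ``sd`` is the sample standard deviation (denominator n-1) of the
    analyzed productions; ``rmsr`` is the root of the mean (denominator n)
    squared residual from the participant's OLS drift line; ``scaled_rmsr``
    is ``rmsr / mean_production``.  ``rmsr <= sd`` always holds for n >= 3
    because the residual sum of squares never exceeds the centered sum of
    squares and the n denominator is the larger one.
    """

    participant_id: str
    n_analyzed: int
    mean_production: float
    sd: float
    drift_slope: float
    drift_intercept: float
    rmsr: float
    scaled_rmsr: float


@dataclass(frozen=True)
class ScreeningReport:
    """Outcome of aberrant-producer screening."""

    kept_ids: frozenset
    excluded_ids: frozenset
    exceed_counts: dict

    def __post_init__(self) -> None:
        if self.kept_ids & self.excluded_ids:
            raise ValueError("kept and excluded sets overlap")


def remove_startup(trials: pd.DataFrame, n_startup: int = 2) -> pd.DataFrame:
    """Drop the first ``n_startup`` trials per participant and renumber.

    Trials are taken in presentation order (``trial_index``); the survivors
    are recoded 1..k per participant, so a 20-trial session with two
    start-up trials yields indices 1-18.
    """
    if n_startup < 0:
        raise ValueError(f"n_startup must be >= 0, got {n_startup}")
    pieces = []
    for pid, grp in trials.groupby("participant_id", sort=False):
        grp = grp.sort_values("trial_index")
        if len(grp) <= n_startup:
            raise ValueError(
                f"participant {pid}: n_startup={n_startup} leaves no analyzed "
                f"trials (has {len(grp)})"
            )
        kept = grp.iloc[n_startup:].copy()
        kept["trial_index"] = np.arange(1, len(kept) + 1)
        pieces.append(kept)
    if not pieces:
        return trials.copy()
    return pd.concat(pieces, ignore_index=True)


def screen_participants(
    trials: pd.DataFrame, limit: float = 3.0, min_count: int = 5
) -> ScreeningReport:
    """Exclude participants who repeatedly produce aberrantly long intervals.

    A participant is excluded iff the number of analyzed productions strictly
    greater than ``limit`` seconds is at least ``min_count``.  Screening is
    meant to run after start-up removal.
    """
    kept, excluded, counts = set(), set(), {}
    for pid, grp in trials.groupby("participant_id", sort=False):
        n_over = int((grp["produced_duration_s"] > limit).sum())
        counts[pid] = n_over
        if n_over >= min_count:
            excluded.add(pid)
            logger.warning(
                "excluding participant %s: %d productions over %.3g s "
                "(rule: >= %d)", pid, n_over, limit, min_count
            )
        else:
            kept.add(pid)
    return ScreeningReport(frozenset(kept), frozenset(excluded), counts)


def production_summary(
    trials: pd.DataFrame,
    sd_ddof: int = 1,
    rmsr_denominator: str = "n",
    df_corrected: bool = False,
) -> VariabilityMeasures:
    """Variability measures for one participant's analyzed trials.

    Fits produced duration on the recoded trial index by OLS and reports
    the sample SD, the drift slope/intercept, the RMSR and the scaled RMSR.

    Parameters
    ----------
    sd_ddof
        Delta degrees of freedom of the standard deviation (1 = sample SD).
    rmsr_denominator
        ``"n"`` for the literal mean squared residual (default) or ``"n-2"``
        for the unbiased residual variance.
    df_corrected
        If True, multiply scaled_rmsr by sqrt(n / (n - 2)) so its square is
        an unbiased estimate of the squared clock CV.
    """
    pids = trials["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError(f"expected exactly one participant, got {len(pids)}")
    pid = pids[0]
    y = trials.sort_values("trial_index")["produced_duration_s"].to_numpy(dtype=float)
    n = y.size
    if n < 3:
        raise InsufficientDataError(
            f"participant {pid}: need >= 3 analyzed trials, got {n}"
        )
    if not np.all(np.isfinite(y)) or np.any(y <= 0):
        raise ValueError(f"participant {pid}: durations must be finite and positive")
    t = trials.sort_values("trial_index")["trial_index"].to_numpy(dtype=float)
    if np.ptp(t) == 0:
        raise ValueError(f"participant {pid}: trial index has no variation")

    mean = float(y.mean())
    sd = float(y.std(ddof=sd_ddof))
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    rss = float(resid @ resid)
    if rmsr_denominator == "n":
        rmsr = math.sqrt(rss / n)
    elif rmsr_denominator == "n-2":
        rmsr = math.sqrt(rss / (n - 2))
    else:
        raise ValueError(f"rmsr_denominator must be 'n' or 'n-2', got {rmsr_denominator!r}")
    scaled = rmsr / mean
    if df_corrected:
        scaled *= math.sqrt(n / (n - 2))
    return VariabilityMeasures(
        participant_id=pid,
        n_analyzed=n,
        mean_production=mean,
        sd=sd,
        drift_slope=float(slope),
        drift_intercept=float(intercept),
        rmsr=rmsr,
        scaled_rmsr=scaled,
    )


def summarize_cohort(trials: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Per-participant :func:`production_summary` over a cohort table.

    Participants with fewer than 3 analyzed trials are dropped with a
    warning rather than aborting the whole analysis.
    """
    rows = []
    for pid, grp in trials.groupby("participant_id", sort=False):
        try:
            rows.append(production_summary(grp, **kwargs))
        except InsufficientDataError as err:
            logger.warning("dropping participant %s: %s", pid, err)
    return measures_to_frame(rows)


def measures_to_frame(measures) -> pd.DataFrame:
    cols = [
        "participant_id",
        "n_analyzed",
        "mean_production",
        "sd",
        "drift_slope",
        "drift_intercept",
        "rmsr",
        "scaled_rmsr",
    ]
    if not measures:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([vars(m) for m in measures], columns=cols)


#: Column mapping between in-memory measure names and the CSV header.
_MEASURES_CSV_COLUMNS = {
    "participant_id": "participant_id",
    "n_analyzed": "n_analyzed",
    "mean_production": "mean_production_s",
    "sd": "sd_s",
    "drift_slope": "drift_slope_s_per_trial",
    "drift_intercept": "drift_intercept_s",
    "rmsr": "rmsr_s",
    "scaled_rmsr": "scaled_rmsr",
}


def write_measures_csv(measures: pd.DataFrame, path) -> None:
    measures.rename(columns=_MEASURES_CSV_COLUMNS).to_csv(
        path, index=False, float_format="%.9f"
    )


def read_measures_csv(path) -> pd.DataFrame:
    inverse = {v: k for k, v in _MEASURES_CSV_COLUMNS.items()}
    return pd.read_csv(path).rename(columns=inverse)


def write_screening_csv(report: ScreeningReport, path) -> None:
    rows = [
        {
            "participant_id": pid,
            "n_over_limit": n,
            "excluded": pid in report.excluded_ids,
        }
        for pid, n in sorted(report.exceed_counts.items())
    ]
    pd.DataFrame(rows, columns=["participant_id", "n_over_limit", "excluded"]).to_csv(
        path, index=False
    )


def implied_total_drift(drift_slope: float, n_analyzed: int) -> float:
    """Total drift in milliseconds implied by a per-trial slope.

    Multiplies the slope by the number of analyzed trials (18 for a 20-trial
    session with two start-up trials removed) and converts to ms, so a slope
    of -0.08 s/trial maps to -1440 ms.
    """
    return drift_slope * n_analyzed * 1000.0
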