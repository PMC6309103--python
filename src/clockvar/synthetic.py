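"""Synthetic timing data with the statistical structure of a 1-s production
task and a multi-duration reproduction task.

The generator emulates a cohort of participants, each characterised by a
scalar internal clock (noise standard deviation proportional to the timed
duration), a slow linear drift of the internal 1-s representation across
production trials, inflated "start-up" trials at the beginning of the
production session, and a Bayesian observer in the reproduction task that
combines the noisy percept of the presented duration (likelihood) with a
static Gaussian prior over durations.  The precision-weighted combination
produces the central-tendency (regression-to-the-mean) effect whose slope
is available in closed form from :func:`expected_central_slope`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DURATION_FLOOR",
    "PAPER_DESIGN",
    "DEFAULT_HYPERPARAMS",
    "ParticipantParams",
    "TaskDesign",
    "SimulationError",
    "sample_participants",
    "simulate_production",
    "simulate_reproduction",
    "simulate_cohort",
    "expected_central_slope",
    "likelihood_weight",
    "participants_to_frame",
    "write_production_csv",
    "read_production_csv",
    "write_reproduction_csv",
    "read_reproduction_csv",
]

#: Physical lower truncation bound for any simulated duration (seconds).
#: A plausible minimum keypress latency; keeps all samples strictly positive.
DURATION_FLOOR = 0.05

PRODUCTION_COLUMNS = [
    "participant_id",
    "order_condition",
    "trial_index",
    "produced_duration_s",
]
REPRODUCTION_COLUMNS = [
    "participant_id",
    "order_condition",
    "block",
    "trial_index",
    "presented_duration_s",
    "reproduced_duration_s",
]

ORDER_CONDITIONS = ("production_first", "reproduction_first")


class SimulationError(RuntimeError):
    """A generative model produced an impossible state (e.g. a non-positive
    mean duration implied by extreme drift)."""


@dataclass(frozen=True)
class TaskDesign:
    """Block structure of the multi-duration reproduction task."""

    n_blocks: int = 2
    trials_per_block: int = 120
    duration_levels: tuple[float, ...] = (1.17, 1.4, 1.68)
    presentations_per_level_per_block: int = 40

    def __post_init__(self) -> None:
        expected = self.presentations_per_level_per_block * len(self.duration_levels)
        if self.trials_per_block != expected:
            raise ValueError(
                "trials_per_block must equal presentations_per_level_per_block "
                f"x number of levels ({expected}), got {self.trials_per_block}"
            )
        if any(d <= 0 for d in self.duration_levels):
            raise ValueError("duration levels must be strictly positive")


#: The three-duration, two-block reproduction design used throughout.
PAPER_DESIGN = TaskDesign()


@dataclass(frozen=True)
class ParticipantParams:
    """Generative ground truth for one simulated participant.

    Parameters
    ----------
    clock_cv
        Coefficient of variation of the internal clock: the standard
        deviation of timing noise is ``clock_cv`` times the timed duration
        (scalar property).
    mu_one_second
        Internal representation of 1 s, in seconds.
    drift_slope
        Linear change of the internal 1-s representation per analyzed
        production trial (seconds/trial).
    startup_mean_factor, startup_cv_factor
        Mean and noise inflation of the initial production trials.
    motor_cv
        Scalar noise applied at response execution in the reproduction task.
    prior_mean, prior_sd
        Static Gaussian prior over durations used by the observer.
    order_condition
        Which task the participant performed first.
    """

    participant_id: str
    clock_cv: float
    mu_one_second: float
    drift_slope: float = 0.0
    startup_mean_factor: float = 1.8
    startup_cv_factor: float = 2.5
    motor_cv: float = 0.05
    prior_mean: float = float(np.mean(PAPER_DESIGN.duration_levels))
    prior_sd: float = 0.2
    order_condition: str = "production_first"

    def __post_init__(self) -> None:
        for name in ("clock_cv", "motor_cv"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        for name in ("mu_one_second", "prior_mean", "prior_sd"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")
        for name in ("startup_mean_factor", "startup_cv_factor"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if not math.isfinite(self.drift_slope):
            raise ValueError("drift_slope must be finite")
        if self.order_condition not in ORDER_CONDITIONS:
            raise ValueError(
                f"order_condition must be one of {ORDER_CONDITIONS}, "
                f"got {self.order_condition!r}"
            )


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------

#: Default population hyperparameters.  Each entry is either a constant or a
#: distribution spec understood by :func:`_sample_field`.
DEFAULT_HYPERPARAMS: dict[str, object] = {
    "clock_cv": ("uniform", 0.05, 0.25),
    "mu_one_second": ("uniform", 0.7, 1.2),
    "drift_slope": ("truncnorm", -0.0055, 0.02, -0.03, 0.05),
    "startup_mean_factor": 1.8,
    "startup_cv_factor": 2.5,
    "motor_cv": 0.05,
    "prior_mean": float(np.mean(PAPER_DESIGN.duration_levels)),
    "prior_sd": 0.2,
}


def _sample_field(name: str, spec: object, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` values for one hyperparameter.

    ``spec`` is a number (constant), or a tuple:
    ``("uniform", lo, hi)``, ``("normal", mean, sd)``,
    ``("truncnorm", mean, sd, lo, hi)``.
    """
    if isinstance(spec, (int, float)):
        return np.full(size, float(spec))
    if not isinstance(spec, (tuple, list)) or not spec:
        raise ValueError(f"hyperparameter {name!r}: unrecognised spec {spec!r}")
    kind = spec[0]
    args = [float(a) for a in spec[1:]]
    if kind == "uniform":
        lo, hi = args
        if hi < lo:
            raise ValueError(f"hyperparameter {name!r}: uniform needs lo <= hi")
        return rng.uniform(lo, hi, size)
    if kind == "normal":
        mean, sd = args
        if sd < 0:
            raise ValueError(f"hyperparameter {name!r}: normal sd must be >= 0")
        return rng.normal(mean, sd, size)
    if kind == "truncnorm":
        mean, sd, lo, hi = args
        if sd < 0:
            raise ValueError(f"hyperparameter {name!r}: truncnorm sd must be >= 0")
        if hi <= lo:
            raise ValueError(f"hyperparameter {name!r}: truncnorm needs lo < hi")
        if sd == 0:
            return np.full(size, min(max(mean, lo), hi))
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)
    raise ValueError(f"hyperparameter {name!r}: unknown distribution {kind!r}")


def sample_participants(
    n: int,
    hyperparams: Mapping[str, object] | None = None,
    seed: int = 0,
) -> list[ParticipantParams]:
    """Sample ``n`` participants from population hyperparameters.

    The task-order condition alternates with the parity of the sequential
    participant number (odd-numbered participants run the production task
    first).  Identical ``(n, hyperparams, seed)`` give identical output.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        unknown = set(hyperparams) - set(hp)
        if unknown:
            raise ValueError(f"unknown hyperparameter(s): {sorted(unknown)}")
        hp.update(hyperparams)
    rng = np.random.default_rng(seed)
    draws = {name: _sample_field(name, spec, n, rng) for name, spec in hp.items()}
    out = []
    for i in range(n):
        num = i + 1
        out.append(
            ParticipantParams(
                participant_id=f"p{num:03d}",
                order_condition=ORDER_CONDITIONS[(num + 1) % 2],
                **{name: float(draws[name][i]) for name in hp},
            )
        )
    return out


def participants_to_frame(participants: Iterable[ParticipantParams]) -> pd.DataFrame:
    """Ground-truth parameter table, one row per participant."""
    return pd.DataFrame([dataclasses.asdict(p) for p in participants])


# ---------------------------------------------------------------------------
# Production task
# ---------------------------------------------------------------------------


def _truncated_normal(
    mean: np.ndarray, sd: np.ndarray, floor: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw from N(mean, sd) truncated below at ``floor`` (elementwise)."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    out = mean.copy()
    noisy = sd > 0
    if np.any(noisy):
        a = (floor - mean[noisy]) / sd[noisy]
        out[noisy] = stats.truncnorm.rvs(
            a, np.inf, loc=mean[noisy], scale=sd[noisy], random_state=rng
        )
    # degenerate (sd == 0) draws are the mean itself, floored
    out[~noisy] = np.maximum(out[~noisy], floor)
    return out


def simulate_production(
    params: ParticipantParams,
    n_trials: int = 20,
    n_startup: int = 2,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate one production session.

    The first ``n_startup`` trials are drawn around an inflated mean
    ``mu_one_second * startup_mean_factor`` with noise inflated by
    ``startup_cv_factor``; subsequent trials follow the drifting mean
    ``mu_one_second + drift_slope * (t - n_startup)`` with scalar noise
    ``clock_cv`` times the trial mean.  All draws are truncated below at
    :data:`DURATION_FLOOR`.
    """
    if n_startup < 0 or n_trials < n_startup:
        raise ValueError(
            f"need n_trials >= n_startup >= 0, got {n_trials}, {n_startup}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(1, n_trials + 1)
    startup = t <= n_startup
    mu = np.where(
        startup,
        params.mu_one_second * params.startup_mean_factor,
        params.mu_one_second + params.drift_slope * (t - n_startup),
    )
    if np.any(mu <= 0):
        bad = int(t[mu <= 0][0])
        raise SimulationError(
            f"participant {params.participant_id}: drift_slope "
            f"{params.drift_slope} implies non-positive mean duration at trial {bad}"
        )
    sd = params.clock_cv * mu * np.where(startup, params.startup_cv_factor, 1.0)
    produced = _truncated_normal(mu, sd, DURATION_FLOOR, rng)
    return pd.DataFrame(
        {
            "participant_id": params.participant_id,
            "order_condition": params.order_condition,
            "trial_index": t,
            "produced_duration_s": produced,
        }
    )


# ---------------------------------------------------------------------------
# Reproduction task (Bayesian observer)
# ---------------------------------------------------------------------------


def likelihood_weight(
    presented: np.ndarray | float, clock_cv: float, prior_sd: float
) -> np.ndarray | float:
    """Weight lambda(d) given to the sensory likelihood in the posterior mean.

    lambda(d) = prior_sd^2 / (prior_sd^2 + (clock_cv * d)^2); 1 for a
    noise-free clock (veridical reproduction), 0 for an uninformative
    likelihood (full reliance on the prior).
    """
    lik_var = np.square(clock_cv * np.asarray(presented, dtype=float))
    return prior_sd**2 / (prior_sd**2 + lik_var)


def simulate_reproduction(
    params: ParticipantParams,
    design: TaskDesign = PAPER_DESIGN,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate one reproduction session under the Bayesian observer model.

    Per trial with presented duration ``d``: the percept is
    ``x ~ N(d, (clock_cv * d)^2)``; the observer's estimate is the posterior
    mean ``e = lambda(d) * x + (1 - lambda(d)) * prior_mean``; the response is
    ``N(e, (motor_cv * e)^2)`` truncated below at :data:`DURATION_FLOOR`.
    Within each block every duration level appears exactly
    ``presentations_per_level_per_block`` times in seeded random order.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per_block = np.repeat(design.duration_levels, design.presentations_per_level_per_block)
    frames = []
    for block in range(1, design.n_blocks + 1):
        d = rng.permutation(per_block)
        lam = likelihood_weight(d, params.clock_cv, params.prior_sd)
        x = d if params.clock_cv == 0 else rng.normal(d, params.clock_cv * d)
        e = lam * x + (1.0 - lam) * params.prior_mean
        e = np.maximum(e, DURATION_FLOOR)
        reproduced = _truncated_normal(e, params.motor_cv * e, DURATION_FLOOR, rng)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": params.participant_id,
                    "order_condition": params.order_condition,
                    "block": block,
                    "trial_index": np.arange(1, design.trials_per_block + 1),
                    "presented_duration_s": d,
                    "reproduced_duration_s": reproduced,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_cohort(
    participants: Sequence[ParticipantParams],
    design: TaskDesign = PAPER_DESIGN,
    n_production_trials: int = 20,
    n_startup: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate production and reproduction tables for a whole cohort.

    Per-participant streams are spawned from a single seed, so the cohort is
    reproducible as a unit while participants remain independent.
    """
    child_seeds = np.random.SeedSequence(seed).spawn(len(participants))
    prod, repr_ = [], []
    for p, ss in zip(participants, child_seeds):
        rng = np.random.default_rng(ss)
        prod.append(simulate_production(p, n_production_trials, n_startup, seed=rng))
        repr_.append(simulate_reproduction(p, design, seed=rng))
    if not participants:
        return (
            pd.DataFrame(columns=PRODUCTION_COLUMNS),
            pd.DataFrame(columns=REPRODUCTION_COLUMNS),
        )
    return pd.concat(prod, ignore_index=True), pd.concat(repr_, ignore_index=True)


# ---------------------------------------------------------------------------
# Analytic oracle
# ---------------------------------------------------------------------------


def expected_central_slope(
    params: ParticipantParams, duration_levels: Sequence[float] | None = None
) -> float:
    """Expected OLS slope of reproduced on presented duration.

    Under the observer model the expected reproduction at level ``d`` is
    ``m(d) = lambda(d) * d + (1 - lambda(d)) * prior_mean``; regressing this
    on the levels gives

        slope = sum_i (d_i - dbar) * m(d_i) / sum_i (d_i - dbar)^2.

    Because the likelihood weight shrinks with the presented duration
    (scalar noise), the prior-mean term varies across levels and
    contributes to the slope.  The slope is 1 for a noise-free clock,
    strictly decreasing in ``clock_cv``, and tends to 0 as the likelihood
    becomes uninformative.
    """
    if duration_levels is None:
        duration_levels = PAPER_DESIGN.duration_levels
    d = np.asarray(duration_levels, dtype=float)
    if np.unique(d).size < 2:
        raise ValueError("need at least 2 distinct duration levels")
    lam = likelihood_weight(d, params.clock_cv, params.prior_sd)
    m = lam * d + (1.0 - lam) * params.prior_mean
    dc = d - d.mean()
    return float(np.sum(dc * m) / np.sum(dc * dc))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def write_production_csv(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False, columns=PRODUCTION_COLUMNS, float_format="%.9f")


def read_production_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PRODUCTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"production CSV missing column(s): {sorted(missing)}")
    return df


def write_reproduction_csv(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False, columns=REPRODUCTION_COLUMNS, float_format="%.9f")


def read_reproduction_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(REPRODUCTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reproduction CSV missing column(s): {sorted(missing)}")
    return df
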