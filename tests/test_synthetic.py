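"""Generator contracts: determinism, design balance, the scalar property,
and agreement between simulation and the closed-form observer slope."""

import numpy as np
import pandas as pd
import pytest

import oracles
from clockvar import synthetic
from clockvar.synthetic import (
    PAPER_DESIGN,
    ParticipantParams,
    SimulationError,
    TaskDesign,
    expected_central_slope,
    sample_participants,
    simulate_production,
    simulate_reproduction,
)


class TestSampleParticipants:
    def test_empty_cohort(self):
        assert sample_participants(0, seed=1) == []

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            sample_participants(-1, seed=1)

    def test_improper_distribution_rejected(self):
        with pytest.raises(ValueError, match="sd"):
            sample_participants(5, {"clock_cv": ("normal", 0.1, -0.2)}, seed=1)

    def test_seed_determinism(self):
        a = sample_participants(63, seed=5)
        b = sample_participants(63, seed=5)
        assert a == b
        c = sample_participants(63, seed=6)
        assert a != c

    def test_order_alternates_by_parity(self):
        cohort = sample_participants(6, seed=0)
        orders = [p.order_condition for p in cohort]
        assert orders == [
            "production_first", "reproduction_first",
            "production_first", "reproduction_first",
            "production_first", "reproduction_first",
        ]

    def test_population_mean_of_uniform_hyperprior(self):
        # mean of U(0.05, 0.25) is 0.15; the sample mean of 2000 draws
        # must fall within 3 analytic standard errors
        cohort = sample_participants(
            2000, {"clock_cv": ("uniform", 0.05, 0.25)}, seed=7
        )
        cvs = np.array([p.clock_cv for p in cohort])
        se = oracles.uniform_mean_se(0.05, 0.25, 2000)
        assert abs(cvs.mean() - 0.15) < 3 * se


class TestSimulateProduction:
    def test_noise_free_sessions_are_constant(self, quiet_participant):
        df = simulate_production(quiet_participant, n_trials=20, seed=3)
        assert len(df) == 20
        np.testing.assert_allclose(df["produced_duration_s"], 1.0)

    def test_default_session_has_twenty_trials(self, typical_participant):
        df = simulate_production(typical_participant, seed=0)
        assert len(df) == 20
        assert list(df["trial_index"]) == list(range(1, 21))

    def test_determinism_under_seed(self, typical_participant):
        a = simulate_production(typical_participant, seed=9)
        b = simulate_production(typical_participant, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_scalar_property_pooled_sd(self):
        # pooled SD of drift-free trials converges to clock_cv * mu
        p = ParticipantParams(
            "s", clock_cv=0.1, mu_one_second=1.0, drift_slope=0.0,
            startup_mean_factor=1.0, startup_cv_factor=1.0,
        )
        df = simulate_production(p, n_trials=10_000, n_startup=0, seed=21)
        sd = df["produced_duration_s"].std(ddof=1)
        assert abs(sd - 0.1) < 0.002

    def test_extreme_drift_raises_naming_trial(self):
        p = ParticipantParams("d", clock_cv=0.1, mu_one_second=1.0, drift_slope=-0.2)
        with pytest.raises(SimulationError, match="trial"):
            simulate_production(p, n_trials=20, seed=0)

    def test_startup_trials_are_longer_on_average(self):
        p = ParticipantParams("u", clock_cv=0.05, mu_one_second=1.0)
        reps = [simulate_production(p, seed=s) for s in range(200)]
        first = np.mean([r["produced_duration_s"].iloc[0] for r in reps])
        rest = np.mean([r["produced_duration_s"].iloc[2:].mean() for r in reps])
        assert first > rest * 1.5


class TestSimulateReproduction:
    def test_noise_free_observer_is_veridical(self, quiet_participant):
        df = simulate_reproduction(quiet_participant, seed=2)
        np.testing.assert_allclose(
            df["reproduced_duration_s"], df["presented_duration_s"]
        )

    def test_vanishing_prior_width_pins_response_to_prior_mean(self):
        p = ParticipantParams(
            "p", clock_cv=0.2, mu_one_second=1.0, motor_cv=0.0,
            prior_mean=1.4, prior_sd=1e-9,
        )
        df = simulate_reproduction(p, seed=4)
        np.testing.assert_allclose(df["reproduced_duration_s"], 1.4, atol=1e-6)

    def test_design_balance_forty_per_level_per_block(self, typical_participant):
        df = simulate_reproduction(typical_participant, PAPER_DESIGN, seed=5)
        counts = df.groupby(["block", "presented_duration_s"]).size()
        assert (counts == 40).all()
        assert df["block"].nunique() == 2 and len(df) == 240

    def test_unbalanced_design_rejected(self):
        with pytest.raises(ValueError):
            TaskDesign(2, 100, (1.17, 1.4, 1.68), 40)

    def test_determinism_under_seed(self, typical_participant):
        a = simulate_reproduction(typical_participant, seed=8)
        b = simulate_reproduction(typical_participant, seed=8)
        pd.testing.assert_frame_equal(a, b)


class TestExpectedCentralSlope:
    def test_noise_free_slope_is_one(self):
        p = ParticipantParams("a", clock_cv=0.0, mu_one_second=1.0)
        assert expected_central_slope(p) == pytest.approx(1.0)

    def test_infinite_noise_slope_vanishes(self):
        p = ParticipantParams("a", clock_cv=1e6, mu_one_second=1.0)
        assert expected_central_slope(p) < 1e-6

    def test_requires_two_levels(self):
        p = ParticipantParams("a", clock_cv=0.1, mu_one_second=1.0)
        with pytest.raises(ValueError):
            expected_central_slope(p, [1.4, 1.4])

    def test_strictly_decreasing_in_clock_cv(self):
        slopes = [
            expected_central_slope(
                ParticipantParams("a", clock_cv=cv, mu_one_second=1.0)
            )
            for cv in np.linspace(0.0, 0.5, 11)
        ]
        assert all(a > b for a, b in zip(slopes, slopes[1:]))
        assert all(0 < s <= 1 for s in slopes)

    def test_matches_monte_carlo_mean_slope(self):
        # simulation and closed form must agree within Monte-Carlo error
        p = ParticipantParams(
            "mc", clock_cv=0.15, mu_one_second=1.0, prior_sd=0.25, motor_cv=0.0
        )
        slopes = []
        for s in range(400):
            df = simulate_reproduction(p, seed=s)
            x = df["presented_duration_s"].to_numpy()
            y = df["reproduced_duration_s"].to_numpy()
            slopes.append(oracles.ols_line_bruteforce(x, y)[0])
        mc = np.mean(slopes)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(mc - expected_central_slope(p)) < 3 * se

    def test_higher_noise_gives_smaller_simulated_slope(self):
        lo = ParticipantParams("lo", clock_cv=0.05, mu_one_second=1.0, motor_cv=0.0)
        hi = ParticipantParams("hi", clock_cv=0.25, mu_one_second=1.0, motor_cv=0.0)
        slopes = {}
        for name, p in [("lo", lo), ("hi", hi)]:
            vals = []
            for s in range(300):
                df = simulate_reproduction(p, seed=s)
                vals.append(
                    oracles.ols_line_bruteforce(
                        df["presented_duration_s"], df["reproduced_duration_s"]
                    )[0]
                )
            slopes[name] = np.mean(vals)
        assert slopes["hi"] < slopes["lo"]


class TestCsvRoundTrip:
    def test_production_and_reproduction_schemas(self, tmp_path, small_cohort):
        _, prod, repr_ = small_cohort
        pp, rp = tmp_path / "prod.csv", tmp_path / "repr.csv"
        synthetic.write_production_csv(prod, pp)
        synthetic.write_reproduction_csv(repr_, rp)
        assert pp.read_text().splitlines()[0] == (
            "participant_id,order_condition,trial_index,produced_duration_s"
        )
        assert rp.read_text().splitlines()[0] == (
            "participant_id,order_condition,block,trial_index,"
            "presented_duration_s,reproduced_duration_s"
        )
        prod2 = synthetic.read_production_csv(pp)
        np.testing.assert_allclose(
            prod2["produced_duration_s"], prod["produced_duration_s"], atol=1e-9
        )

    def test_missing_column_rejected(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("participant_id,trial_index\np001,1\n")
        with pytest.raises(ValueError, match="missing"):
            synthetic.read_production_csv(bad)
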