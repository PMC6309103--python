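"""Default-prior Bayes-factor machinery, checked against brute-force grid
quadrature oracles and an independent mixed-model likelihood."""

import math

import numpy as np
import pandas as pd
import pytest

import oracles
from clockvar import bayes, synthetic
from clockvar.bayes import (
    DegenerateDataError,
    ModelSpec,
    bf_correlation,
    bf_model_comparison,
    bf_one_sample,
    interpret_bf,
)


def _pairs_with_exact_r(n: int, r: float):
    """Deterministic (x, y) with sample correlation exactly r."""
    x = np.arange(float(n))
    x = (x - x.mean()) / x.std()
    v = np.sin(np.arange(float(n)))
    v = v - v.mean()
    v = v - (v @ x) / (x @ x) * x
    v = v / v.std()
    y = r * x + math.sqrt(1 - r * r) * v
    return x, y


class TestInterpretBf:
    @pytest.mark.parametrize(
        "bf,label",
        [
            (1.0, "inconclusive"),
            (2.23, "anecdotal"),       # weak evidence, direction aside
            (1 / 2.23, "anecdotal"),   # inversion convention
            (5.0, "moderate"),
            (20.0, "strong"),
            (50.0, "very strong"),
            (325.58, "extreme"),
            (1e-4, "extreme"),
        ],
    )
    def test_bands(self, bf, label):
        assert interpret_bf(bf) == label

    def test_invalid_bf_rejected(self):
        with pytest.raises(ValueError):
            interpret_bf(0.0)


class TestOneSampleBf:
    def test_null_favored_at_t_zero(self):
        x = np.concatenate([np.arange(10.0), -np.arange(10.0)])  # mean exactly 0
        res = bf_one_sample(x, null_value=0.0)
        assert res.bf10 < 1

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.3, 1.0, 40)
        a = bf_one_sample(x)
        b = bf_one_sample(17.3 * x)
        assert a.log_bf10 == pytest.approx(b.log_bf10, abs=1e-8)

    @pytest.mark.parametrize("t,n", [(6.0, 50), (2.0, 20), (0.5, 12), (-3.0, 30)])
    def test_matches_grid_quadrature_oracle(self, t, n):
        # construct data with the target t statistic: mean = t/sqrt(n), sd = 1
        base = np.arange(float(n))
        base = (base - base.mean()) / base.std(ddof=1)
        x = base + t / math.sqrt(n)
        res = bf_one_sample(x)
        oracle = oracles.jzs_bf_grid(t, n)
        assert res.bf10 == pytest.approx(oracle, rel=5e-4)  # 4 significant digits
        assert res.numerical_error < 1e-6

    def test_monotone_in_abs_t(self):
        n = 25
        base = np.arange(float(n))
        base = (base - base.mean()) / base.std(ddof=1)
        bfs = [bf_one_sample(base + t / math.sqrt(n)).bf10 for t in (0.0, 1.0, 2.5, 4.0, 8.0)]
        assert all(a < b for a, b in zip(bfs, bfs[1:]))

    def test_degenerate_data_rejected(self):
        with pytest.raises(DegenerateDataError):
            bf_one_sample(np.ones(10))


class TestCorrelationBf:
    def test_perfect_association(self):
        x = np.arange(63.0)
        res = bf_correlation(x, 2 * x + 1)
        assert res.posterior_median_r > 0.99
        assert res.bf10 > 100

    def test_independent_data_favor_null(self):
        rng = np.random.default_rng(2024)
        res = bf_correlation(rng.standard_normal(1000), rng.standard_normal(1000))
        assert res.bf10 < 1

    def test_matches_grid_posterior_oracle_at_study_size(self):
        x, y = _pairs_with_exact_r(63, -0.45)
        res = bf_correlation(x, y)
        bf_o, med_o, mad_o, ci_o = oracles.corr_posterior_grid(-0.45, 63)
        assert res.bf10 == pytest.approx(bf_o, rel=5e-4)
        assert res.posterior_median_r == pytest.approx(med_o, abs=5e-4)
        assert res.posterior_mad == pytest.approx(mad_o, abs=5e-4)
        assert res.credible_interval[0] == pytest.approx(ci_o[0], abs=5e-4)
        assert res.credible_interval[1] == pytest.approx(ci_o[1], abs=5e-4)
        assert res.credible_interval[0] < res.posterior_median_r < res.credible_interval[1]

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            bf_correlation(np.ones(10), np.arange(10.0))

    def test_sign_symmetry(self):
        x, y = _pairs_with_exact_r(40, 0.3)
        x2, y2 = _pairs_with_exact_r(40, -0.3)
        a, b = bf_correlation(x, y), bf_correlation(x2, y2)
        assert a.log_bf10 == pytest.approx(b.log_bf10, abs=1e-6)
        assert a.posterior_median_r == pytest.approx(-b.posterior_median_r, abs=1e-6)


def _model_data(n_participants=12, seed=5, cv_range=(0.05, 0.3)):
    """Small centered cohort with heterogeneous clock noise, joined with the
    true scaled clock noise as the measure column."""
    from clockvar import production, reproduction

    participants = synthetic.sample_participants(
        n_participants, {"clock_cv": ("uniform", *cv_range)}, seed=seed
    )
    design = synthetic.TaskDesign(1, 45, (1.17, 1.4, 1.68), 15)
    prod, repr_ = synthetic.simulate_cohort(participants, design=design, seed=seed + 1)
    measures = production.summarize_cohort(production.remove_startup(prod, 2))
    kept, _ = reproduction.filter_outliers(repr_)
    centered = reproduction.center_durations(kept)
    return centered.merge(
        measures[["participant_id", "scaled_rmsr"]].rename(
            columns={"scaled_rmsr": "measure"}
        ),
        on="participant_id",
    )


DUR = ModelSpec("duration", {"intercept", "presented_duration"})
FULL = ModelSpec(
    "full",
    {"intercept", "presented_duration", "order", "measure",
     "measure:presented_duration"},
)
MEAS = ModelSpec(
    "measure",
    {"intercept", "presented_duration", "measure", "measure:presented_duration"},
)


class TestModelSpec:
    def test_intercept_mandatory(self):
        with pytest.raises(ValueError, match="intercept"):
            ModelSpec("bad", {"presented_duration"})

    def test_interaction_requires_mains(self):
        with pytest.raises(ValueError, match="interaction"):
            ModelSpec("bad", {"intercept", "measure:presented_duration"})

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ModelSpec("bad", {"intercept", "banana"})


class TestModelComparison:
    def test_identical_specs_give_unit_bf(self):
        data = _model_data()
        res = bf_model_comparison(
            data, [DUR, ModelSpec("duration_copy", DUR.fixed_terms)]
        )
        assert res.bf("duration", "duration_copy") == pytest.approx(1.0, abs=1e-12)

    def test_transitivity_in_log_space(self):
        data = _model_data()
        res = bf_model_comparison(
            data,
            [ModelSpec("null", {"intercept"}), DUR, MEAS, FULL],
        )
        lab = res.log_bf("null", "duration")
        lbc = res.log_bf("duration", "full")
        lac = res.log_bf("null", "full")
        assert abs(lab + lbc - lac) < 1e-10

    def test_non_nested_specs_rejected(self):
        data = _model_data()
        order_only = ModelSpec("order", {"intercept", "presented_duration", "order"})
        with pytest.raises(ValueError, match="nest"):
            bf_model_comparison(data, [order_only, MEAS])

    def test_informative_measure_preferred(self):
        data = _model_data(n_participants=16, seed=31)
        res = bf_model_comparison(data, [DUR, MEAS])
        assert res.log_bf("measure", "duration") > math.log(10)

    def test_backends_agree_on_direction(self):
        data = _model_data(n_participants=16, seed=31)
        quad = bf_model_comparison(data, [DUR, MEAS], backend="quadrature")
        bic = bf_model_comparison(data, [DUR, MEAS], backend="bic")
        assert np.sign(quad.log_bf("measure", "duration")) == np.sign(
            bic.log_bf("measure", "duration")
        )

    def test_collinear_design_rejected(self):
        data = _model_data()
        data = data.assign(measure=data["presented_duration_s"])  # duplicate column
        with pytest.raises(ValueError):
            bf_model_comparison(data, [MEAS])


class TestProfileLikelihoodMl:
    def test_matches_statsmodels_mixedlm_at_interior_optimum(self):
        # random-intercept data with a clearly positive group variance, so the
        # reference ML fit is interior and statsmodels is a valid oracle
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        J, m = 20, 15
        groups = np.repeat(np.arange(J), m)
        x = rng.standard_normal(J * m)
        y = 0.5 * x + np.repeat(rng.normal(0, 1.0, J), m) + rng.normal(0, 0.7, J * m)
        X = ((x - x.mean()) / x.std())[:, None]
        ours = bayes._bic_log_marginal(y, X, groups)
        exog = np.column_stack([np.ones_like(y), X])
        fit = sm.MixedLM(y, exog, groups=groups).fit(reml=False)
        k = 2 + 2
        theirs = float(fit.llf) - 0.5 * k * math.log(y.size)
        assert ours == pytest.approx(theirs, abs=1e-3)
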