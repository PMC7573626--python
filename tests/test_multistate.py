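import dataclasses
import json
import math

import numpy as np
import pandas as pd
import pytest

from cnaml.multistate import (
    DEFAULT_GRID,
    MultistateModel,
    MultistateResults,
    StateSpace,
    _exponential_occupancy,
    _weibull_occupancy,
)
from cnaml.simulate import GeneratorConfig, generate_cohort


def manual_results(a, b, c, family="exponential", gamma=(1.0, 1.0, 1.0)):
    """Results object with prescribed baseline hazards and no covariates."""
    payload = {
        "family": family,
        "covariate_spec": {"cr1_relapse": [], "cr1_trm": [], "relapse_death": []},
        "transitions": {
            name: {
                "lambda0": lam, "gamma": g, "beta": {}, "bse": {},
                "loglik": 0.0, "n_at_risk": 0, "n_events": 1,
                "n_iter": 0, "grad_norm": 0.0, "zero_events": False,
            }
            for name, lam, g in zip(
                ("cr1_relapse", "cr1_trm", "relapse_death"), (a, b, c), gamma)
        },
    }
    return MultistateResults.from_json(json.dumps(payload))


NO_COVS = pd.Series(dtype=float)


def recovery_config(n=1000, seed=0):
    """Correctly-specified generation: HSCT recorded exactly when assigned."""
    return GeneratorConfig(n_patients=n, seed=seed, hsct_delay=0.0)


class TestStateSpace:
    def test_default_valid(self):
        StateSpace()

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            StateSpace(transitions=(("CR1", "RELAPSE"), ("RELAPSE", "CR1"),
                                    ("CR1", "TRM"), ("RELAPSE", "DEATH_RELAPSE")))


class TestOccupancy:
    def test_all_hazards_zero(self):
        res = manual_results(0.0, 0.0, 0.0)
        occ = res.predict_occupancy(NO_COVS, grid=DEFAULT_GRID).occupancy
        assert (occ["CR1"] == 1.0).all()
        assert (occ[["RELAPSE", "DEATH_RELAPSE", "TRM"]].to_numpy() == 0.0).all()

    def test_competing_exponential_closed_form(self):
        a, b, c = 0.03, 0.01, 0.08
        res = manual_results(a, b, c)
        occ = res.predict_occupancy(NO_COVS, grid=DEFAULT_GRID).occupancy
        t = DEFAULT_GRID
        np.testing.assert_allclose(occ["CR1"], np.exp(-(a + b) * t), atol=1e-12)
        np.testing.assert_allclose(
            occ["TRM"], b / (a + b) * (1 - np.exp(-(a + b) * t)), atol=1e-12)
        np.testing.assert_allclose(
            occ["RELAPSE"],
            a * (np.exp(-c * t) - np.exp(-(a + b) * t)) / (a + b - c), atol=1e-12)

    def test_exponential_closed_form_vs_numeric_integrator(self):
        """Dual route: the closed-form DAG solution agrees with the generic
        quadrature path (gamma=1) to < 1e-6 on all states."""
        res = manual_results(0.02, 0.005, 0.06)
        grid = np.arange(0.0, 61.0, 3.0)
        closed = _exponential_occupancy(grid, 0.02, 0.005, 0.06)
        fits = res.transitions
        numeric = _weibull_occupancy(
            grid, fits["cr1_relapse"], 1.0, fits["cr1_trm"], 1.0,
            fits["relapse_death"], 1.0)
        for state in ("CR1", "RELAPSE", "DEATH_RELAPSE", "TRM"):
            assert np.max(np.abs(closed[state] - numeric[state])) < 1e-6

    def test_conservation_random_models(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c = rng.uniform(0.001, 0.2, 3)
            occ = manual_results(a, b, c).predict_occupancy(
                NO_COVS, grid=np.linspace(0, 120, 41)).occupancy
            assert np.max(np.abs(occ.sum(axis=1) - 1.0)) < 1e-8

    def test_monotone_occupancies(self):
        occ = manual_results(0.05, 0.01, 0.1).predict_occupancy(
            NO_COVS, grid=DEFAULT_GRID).occupancy
        assert (np.diff(occ["CR1"]) <= 1e-15).all()
        assert (np.diff(occ["TRM"]) >= -1e-15).all()
        assert (np.diff(occ["DEATH_RELAPSE"]) >= -1e-12).all()

    def test_weibull_conservation_and_shape(self):
        res = manual_results(0.01, 0.003, 0.05, family="weibull",
                             gamma=(1.3, 0.8, 1.1))
        occ = res.predict_occupancy(NO_COVS, grid=np.linspace(0, 60, 13)).occupancy
        assert np.max(np.abs(occ.sum(axis=1) - 1.0)) < 1e-7
        assert occ["CR1"].iloc[0] == 1.0

    def test_grid_must_start_at_zero(self):
        with pytest.raises(ValueError, match="grid"):
            manual_results(0.01, 0.01, 0.01).predict_occupancy(
                NO_COVS, grid=np.array([1.0, 2.0]))


class TestFitting:
    def test_no_covariate_rate_is_events_over_persontime(self):
        cfg = GeneratorConfig(
            n_patients=1000, seed=6,
            transition_hazards={"cr1_relapse": 0.02, "cr1_trm": 0.0,
                                "relapse_death": 0.0, "refractory_death": 0.0},
            covariate_effects={},
            cr_probability={"intercept": 50.0}, p_induction=1.0,
            hsct_policy={"favorable": 0.0, "intermediate": 0.0, "adverse": 0.0},
        )
        cohort = generate_cohort(cfg)
        spec = {"cr1_relapse": [], "cr1_trm": [], "relapse_death": []}
        res = MultistateModel(cohort, covariate_spec=spec).fit()
        fit = res.transitions["cr1_relapse"]
        # closed-form MLE: events / person-time
        events = sum(1 for p in cohort if p.history.relapse_time is not None)
        exposure = sum(
            (min(x for x in (p.history.relapse_time, p.history.death_time,
                             p.history.last_followup) if x is not None)
             - p.history.cr1_time)
            for p in cohort if p.history.cr1_time is not None
        )
        assert fit.lambda0 == pytest.approx(events / exposure, rel=1e-6)
        assert fit.lambda0 == pytest.approx(0.02, rel=0.10)

    def test_zero_event_transition_flagged(self):
        cfg = GeneratorConfig(
            n_patients=200, seed=3,
            transition_hazards={"cr1_relapse": 0.0, "cr1_trm": 0.01,
                                "relapse_death": 0.0, "refractory_death": 0.05},
            covariate_effects={},
            cr_probability={"intercept": 50.0}, p_induction=1.0,
        )
        res = MultistateModel(generate_cohort(cfg)).fit()
        assert res.transitions["cr1_relapse"].zero_events
        assert res.transitions["cr1_relapse"].lambda0 == 0.0
        assert any("cr1_relapse" in w for w in res.warnings())

    def test_hsct_effect_recovered_single_cohort(self):
        cohort = generate_cohort(recovery_config(n=2000, seed=17))
        res = MultistateModel(cohort).fit()
        beta = res.transitions["cr1_relapse"].beta
        assert beta["hsct"] == pytest.approx(-0.7, abs=0.15)

    def test_weibull_on_exponential_data_gives_gamma_near_one(self):
        cohort = generate_cohort(recovery_config(n=2000, seed=23))
        res = MultistateModel(cohort, family="weibull").fit()
        fit = res.transitions["cr1_relapse"]
        assert fit.gamma == pytest.approx(1.0, abs=0.1)

    def test_json_round_trip_preserves_predictions(self):
        cohort = generate_cohort(recovery_config(n=600, seed=2))
        res = MultistateModel(cohort).fit()
        back = MultistateResults.from_json(res.to_json())
        x = pd.Series({"age_c": -24.0, "sex_female": 1.0, "log10_wcc": 1.0,
                       "cat2": 0.0, "cat3": 0.0, "cat4": 0.0, "cat5": 1.0,
                       "hsct": 0.0})
        grid = np.linspace(0, 60, 11)
        a = res.predict_occupancy(x, grid=grid).occupancy
        b = back.predict_occupancy(x, grid=grid).occupancy
        pd.testing.assert_frame_equal(a, b)

    def test_no_cr1_patients_is_error(self):
        cfg = GeneratorConfig(n_patients=30, seed=1,
                              cr_probability={"intercept": -50.0},
                              p_salvage_cr=0.0)
        with pytest.raises(ValueError, match="CR1"):
            MultistateModel(generate_cohort(cfg))


class TestStrategies:
    def test_null_hsct_effect_identical_columns(self):
        cohort = generate_cohort(dataclasses.replace(
            recovery_config(n=1500, seed=4),
            covariate_effects={"cr1_relapse": {}, "cr1_trm": {}, "relapse_death": {}},
        ))
        spec = {"cr1_relapse": ["age_c"], "cr1_trm": ["age_c"], "relapse_death": ["age_c"]}
        res = MultistateModel(cohort, covariate_spec=spec).fit()
        x = pd.Series({"age_c": 0.0, "hsct": 0.0})
        table = res.compare_strategies(x)
        pivot = table.pivot(index="horizon_months", columns="strategy", values="P_CR1")
        np.testing.assert_allclose(pivot["hsct_cr1"], pivot["no_hsct"], atol=1e-12)

    def test_protective_hsct_raises_lfs_at_every_horizon(self):
        cohort = generate_cohort(recovery_config(n=2000, seed=5))
        res = MultistateModel(cohort).fit()
        x = pd.Series({"age_c": -24.0, "sex_female": 1.0, "log10_wcc": 1.0,
                       "cat2": 0.0, "cat3": 0.0, "cat4": 0.0, "cat5": 1.0,
                       "hsct": 0.0})
        table = res.compare_strategies(x, horizons=(12.0, 24.0, 60.0))
        pivot = table.pivot(index="horizon_months", columns="strategy", values="P_CR1")
        # the generator's HSCT effect on relapse is protective (beta < 0)
        assert (pivot["hsct_cr1"] > pivot["no_hsct"]).all()

    def test_table_matches_direct_closed_form(self):
        a, b, c = 0.02, 0.004, 0.07
        res = manual_results(a, b, c)
        table = res.compare_strategies(NO_COVS, horizons=(24.0, 60.0))
        for _, row in table.iterrows():
            t = row["horizon_months"]
            assert row["P_CR1"] == pytest.approx(math.exp(-(a + b) * t), abs=1e-12)
        final = table[table["horizon_months"] == 60.0].iloc[0]
        expected_dr = a / (a + b) * (1 - math.exp(-(a + b) * 60)) - \
            a * (math.exp(-c * 60) - math.exp(-(a + b) * 60)) / (a + b - c)
        assert final["P_DEATH_RELAPSE"] == pytest.approx(expected_dr, abs=1e-12)
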