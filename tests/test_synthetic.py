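"""Generator contracts: determinism, closed-form expectations, error paths."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from thermofate import synthetic as syn
from thermofate.calibration import fit_surface_calibration
from thermofate.io_ingest import TemperatureTrace


def _flat_env(**kw):
    defaults = dict(
        season_length_days=2,
        noise_sd=0.0,
        microhabitat_offsets={h: 0.0 for h in syn.DEFAULT_HABITATS},
        models_per_habitat=1,
    )
    defaults.update(kw)
    return syn.EnvConfig(**defaults)


class TestEnvironment:
    def test_zero_noise_zero_offsets_all_traces_identical(self):
        traces = syn.gen_environment(_flat_env())
        base = traces[0].values
        for t in traces[1:]:
            np.testing.assert_array_equal(t.values, base)
        # and equal to the diel sinusoid itself
        cfg = _flat_env()
        hours = traces[0].timestamps.hour + traces[0].timestamps.minute / 60
        expected = cfg.season_mean + cfg.day_mean_amp * np.sin(2 * np.pi * (hours - 9) / 24)
        np.testing.assert_allclose(base, expected)

    def test_habitat_offset_is_additive(self):
        offsets = {h: 0.0 for h in syn.DEFAULT_HABITATS}
        offsets["burrow"] = -5.0
        traces = syn.gen_environment(_flat_env(microhabitat_offsets=offsets))
        by_hab = {t.microhabitat: t for t in traces}
        np.testing.assert_allclose(
            by_hab["burrow"].values, by_hab["open"].values - 5.0
        )

    def test_seed_contract(self):
        cfg = syn.EnvConfig(season_length_days=2, rng_seed=42)
        a = syn.gen_environment(cfg)
        b = syn.gen_environment(syn.EnvConfig(season_length_days=2, rng_seed=42))
        c = syn.gen_environment(syn.EnvConfig(season_length_days=2, rng_seed=43))
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.values, tb.values)
        assert any(not np.array_equal(ta.values, tc.values) for ta, tc in zip(a, c))

    def test_unknown_habitat_rejected(self):
        with pytest.raises(ValueError, match="unknown habitat"):
            syn.EnvConfig(microhabitat_offsets={"lava_field": 1.0})

    def test_full_period_at_configured_step(self):
        cfg = _flat_env(season_length_days=3, time_step=30)
        t = syn.gen_environment(cfg)[0]
        assert len(t) == 3 * 24 * 2
        assert (np.diff(t.timestamps.asi8) == 30 * 60 * 1e9).all()


class TestLizardTb:
    def test_pull_and_clamp_hand_case(self):
        # mean Te = 20, midpoint 30, gain 0.5 -> pull to 25; envelope [20, 35] allows it
        ts = pd.date_range("2018-10-01", periods=1, freq="h")
        env = [
            TemperatureTrace("a", "copper_model", "open", ts, [20.0]),
            TemperatureTrace("b", "copper_model", "tree", ts, [20.0]),
        ]
        beh = syn.BehaviourConfig(tset_low=25.0, tset_high=35.0, tracking_gain=0.5,
                                  tb_noise_sd=0.0)
        tb = syn.gen_lizard_tb(env, beh, seed=0)
        # degenerate envelope [20, 20]: clamped back to 20
        assert tb.values[0] == 20.0
        env[1] = TemperatureTrace("b", "copper_model", "tree", ts, [35.0])
        beh2 = syn.BehaviourConfig(tset_low=25.0, tset_high=35.0, tracking_gain=0.5,
                                   tb_noise_sd=0.0)
        # mean Te = 27.5, pull halfway to midpoint 30 -> 28.75, inside [20, 35]
        tb2 = syn.gen_lizard_tb(env, beh2, seed=0)
        assert tb2.values[0] == pytest.approx(27.5 + 0.5 * (30 - 27.5))

    def test_conformer_equals_mean_te(self):
        env = syn.gen_environment(_flat_env())
        beh = syn.BehaviourConfig(mode="thermoconformer", tb_noise_sd=0.0)
        tb = syn.gen_lizard_tb(env, beh, seed=0)
        np.testing.assert_allclose(tb.values, np.mean([t.values for t in env], axis=0))

    def test_empty_env_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_lizard_tb([], syn.BehaviourConfig(), seed=0)


class TestAccel:
    @pytest.fixture
    def tb_at(self):
        def make(temp, n_min=5):
            ts = pd.date_range("2018-10-01 10:00", periods=n_min, freq="min")
            return TemperatureTrace("L1", "lizard", None, ts, np.full(n_min, temp))

        return make

    def test_no_bouts_constant_baseline(self, tb_at):
        perf = syn.TruePerformance(bout_rate=0.0)
        tr = syn.gen_accel(tb_at(30.0, 10), perf, hz=6, seed=1)
        mag = np.hypot(tr.x_heave, tr.y_surge)
        np.testing.assert_allclose(mag, perf.baseline)

    def test_bout_magnitude_at_peak_and_breadth(self, tb_at):
        perf = syn.TruePerformance(topt_true=36.6, pmax_true=4.0, breadth=5.0,
                                   baseline=0.2, bout_rate=60.0)  # every minute a bout
        tr = syn.gen_accel(tb_at(36.6, 20), perf, hz=6, seed=1, noise_sd=0.0)
        mag = np.hypot(tr.x_heave, tr.y_surge)
        np.testing.assert_allclose(mag, 4.0, rtol=1e-12)
        # one breadth away: baseline + (pmax - baseline) * exp(-1/2)
        tr2 = syn.gen_accel(tb_at(36.6 + 5.0, 20), perf, hz=6, seed=1, noise_sd=0.0)
        expected = 0.2 + 3.8 * np.exp(-0.5)
        np.testing.assert_allclose(np.hypot(tr2.x_heave, tr2.y_surge), expected)

    def test_resultant_preserved_under_axis_decomposition(self, tb_at):
        perf = syn.TruePerformance(bout_rate=30.0)
        tr = syn.gen_accel(tb_at(30.0, 30), perf, hz=6, seed=3, noise_sd=0.0)
        mag = np.hypot(tr.x_heave, tr.y_surge)
        q = perf.curve(30.0)
        assert set(np.round(np.unique(mag), 10)) <= {round(perf.baseline, 10), round(float(q), 10)}

    def test_sample_rate(self, tb_at):
        tr = syn.gen_accel(tb_at(30.0, 2), syn.TruePerformance(), hz=6, seed=0)
        assert len(tr) == 2 * 60 * 6


class TestGradientPairs:
    def test_noiseless_recovery_to_machine_precision(self):
        pairs = syn.gen_gradient_pairs(1.770, 1.058, n=200, noise_sd=0.0, seed=7)
        model = fit_surface_calibration(pairs)
        assert model.intercept == pytest.approx(1.770, abs=1e-9)
        assert model.slope == pytest.approx(1.058, abs=1e-10)

    def test_identity_line(self):
        pairs = syn.gen_gradient_pairs(0.0, 1.0, n=50, noise_sd=0.0, seed=1)
        np.testing.assert_allclose(pairs["body"], pairs["surface"])

    def test_surface_range(self):
        pairs = syn.gen_gradient_pairs(0.0, 1.0, n=500, noise_sd=0.0, seed=2)
        assert pairs["surface"].between(20, 40).all()

    def test_n_too_small(self):
        with pytest.raises(ValueError):
            syn.gen_gradient_pairs(0.0, 1.0, n=1, noise_sd=0.0, seed=0)


class TestEncounterHistories:
    def test_zero_betas_give_half_per_occasion_survival(self):
        truth = syn.SurvivalTruth(betas={"intercept": 0.0}, n_occasions=5)
        cov = pd.DataFrame(index=[f"l{i}" for i in range(2000)])
        hist = syn.gen_encounter_histories(truth, cov, seed=11)
        s = sum(h.n_survived for h in hist)
        d = sum(h.died for h in hist)
        assert s / (s + d) == pytest.approx(0.5, abs=0.02)

    def test_huge_intercept_no_deaths(self):
        truth = syn.SurvivalTruth(betas={"intercept": 20.0}, n_occasions=13)
        cov = pd.DataFrame(index=[f"l{i}" for i in range(50)])
        hist = syn.gen_encounter_histories(truth, cov, seed=1)
        assert not any(h.died for h in hist)
        assert all(len(h.states) == 13 for h in hist)

    def test_cumulative_survival_closed_form(self):
        # phi = 0.9 over 13 occasions -> cumulative 0.9^13 ~ 0.254
        truth = syn.SurvivalTruth(betas={"intercept": float(logit(0.9))}, n_occasions=13)
        cov = pd.DataFrame(index=[f"l{i}" for i in range(4000)])
        hist = syn.gen_encounter_histories(truth, cov, seed=5)
        frac_alive = np.mean([len(h.states) == 13 and not h.died for h in hist])
        assert frac_alive == pytest.approx(0.9**13, abs=0.02)

    def test_covariate_mismatch_rejected(self):
        truth = syn.SurvivalTruth(betas={"intercept": 0.0, "pmax": 1.0})
        cov = pd.DataFrame({"mass": [1.0]}, index=["l0"])
        with pytest.raises(ValueError, match="pmax"):
            syn.gen_encounter_histories(truth, cov, seed=0)

    def test_staggered_entry_and_censoring(self):
        truth = syn.SurvivalTruth(betas={"intercept": 20.0}, n_occasions=10)
        cov = pd.DataFrame(index=["a", "b"])
        hist = syn.gen_encounter_histories(
            truth, cov, seed=2, first_occasion={"b": 7}
        )
        by_id = {h.lizard_id: h for h in hist}
        assert by_id["b"].first_occasion == 7
        assert len(by_id["b"].states) == 3
        hist_c = syn.gen_encounter_histories(truth, cov, seed=2, censor_rate=1.0)
        assert all(h.states == ["censored"] for h in hist_c)
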