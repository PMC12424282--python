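"""Known-fate likelihood, MLE, AICc and model ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from thermofate import io_ingest as io
from thermofate import survival as surv
from thermofate import synthetic as syn


def _hist(states, lid="l1", cov=None, first=0):
    return surv.EncounterHistory(
        lizard_id=lid, first_occasion=first, states=list(states), covariates=cov or {}
    )


def _intercept_design(histories):
    return np.ones((len(histories), 1))


class TestBuildHistories:
    @pytest.fixture
    def lizards(self):
        return [
            io.LizardRecord("l1", "male", 350.0, "2018-09-01", "2019-01-31"),
        ]

    def _fates(self, rows):
        return [io.FateRecord(lid, d, s) for lid, d, s in rows]

    def test_full_season_alive(self, lizards):
        fates = self._fates([("l1", "2018-12-30", "alive")])
        h = surv.build_histories(fates, lizards, season_start="2018-10-01")
        assert h[0].states == ["survived"] * 13

    def test_death_on_day_10_weekly_occasions(self, lizards):
        # day 10 falls in the second 7-day occasion
        fates = self._fates([("l1", "2018-10-11", "dead")])
        h = surv.build_histories(fates, lizards, season_start="2018-10-01")
        assert h[0].states == ["survived", "died"]

    def test_censor_day_20_gives_two_survived(self, lizards):
        fates = self._fates([("l1", "2018-10-21", "censored")])
        h = surv.build_histories(fates, lizards, season_start="2018-10-01")
        assert h[0].states == ["survived", "survived", "censored"]

    def test_staggered_entry(self):
        lizards = [io.LizardRecord("l2", "female", 300.0, "2018-10-20", "2019-01-31")]
        fates = self._fates([("l2", "2018-12-30", "alive")])
        h = surv.build_histories(fates, lizards, season_start="2018-10-01")
        assert h[0].first_occasion == 2
        assert len(h[0].states) == 11

    def test_fate_outside_tracking_window_rejected(self, lizards):
        fates = self._fates([("l1", "2019-06-01", "alive")])
        with pytest.raises(io.ValidationError, match="outside tracking"):
            surv.build_histories(fates, lizards, season_start="2018-10-01")

    def test_signal_loss_mid_season_censors(self, lizards):
        # last record day 18, no terminal status -> 2 survived + censored
        fates = self._fates([("l1", "2018-10-19", "alive")])
        h = surv.build_histories(fates, lizards, season_start="2018-10-01")
        assert h[0].states == ["survived", "survived", "censored"]


class TestLoglik:
    def test_closed_form_binomial(self):
        hists = [_hist(["survived"])] * 3 + [_hist(["died"])]
        X = _intercept_design(hists)
        beta = [logit(0.75)]
        expected = 3 * np.log(0.75) + np.log(0.25)
        assert surv.loglik(hists, beta, X) == pytest.approx(expected)

    def test_all_survive_limit(self):
        hists = [_hist(["survived"] * 5)]
        X = _intercept_design(hists)
        assert surv.loglik(hists, [20.0], X) == pytest.approx(0.0, abs=1e-6)

    def test_beta_zero_gives_log_half_per_interval(self):
        hists = [_hist(["survived", "survived", "died"])]
        X = _intercept_design(hists)
        assert surv.loglik(hists, [0.0], X) == pytest.approx(3 * np.log(0.5))

    def test_invariant_to_history_splitting(self):
        other = _hist(["survived", "died"], lid="o", cov={"z": -0.5})
        whole = [_hist(["survived"] * 4 + ["died"], cov={"z": 1.0}), other]
        split = [
            _hist(["survived"] * 4, lid="a", cov={"z": 1.0}),
            _hist(["died"], lid="b", cov={"z": 1.0}),
            other,
        ]
        for beta in ([0.3, -0.2], [1.0, 0.5]):
            Xw, _, _ = surv.design_matrix(whole, "phi ~ z", standardize=False)
            Xs, _, _ = surv.design_matrix(split, "phi ~ z", standardize=False)
            assert surv.loglik(whole, beta, Xw) == pytest.approx(
                surv.loglik(split, beta, Xs)
            )


class TestFit:
    def test_intercept_only_closed_form(self):
        hists = [_hist(["survived"])] * 3 + [_hist(["died"])]
        f = surv.fit(hists, "phi ~ 1")
        assert expit(f.betas[0]) == pytest.approx(0.75, abs=1e-6)

    def test_all_survived_boundary(self):
        hists = [_hist(["survived"] * 3)] * 4
        f = surv.fit(hists, "phi ~ 1")
        assert f.boundary
        assert f.phi_hat[0] == pytest.approx(1.0)
        s, se = surv.seasonal_survival(f, 13)
        assert s == pytest.approx(1.0) and se == 0.0

    def test_profile_lower_bound_when_no_deaths(self):
        hists = [_hist(["survived"] * 10)]
        lb = surv.profile_phi_lower(hists)
        # 2 * 10 * log(phi) = -chi2_1(0.90) at the bound
        from scipy.stats import chi2

        assert lb == pytest.approx(np.exp(-chi2.ppf(0.90, 1) / 20))

    def test_two_parameter_fit_matches_grid_oracle(self):
        rng = np.random.default_rng(9)
        hists = []
        for i in range(10):
            z = float(rng.normal())
            phi = expit(1.0 + 0.8 * z)
            states = []
            for _ in range(5):
                if rng.random() < phi:
                    states.append("survived")
                else:
                    states.append("died")
                    break
            hists.append(_hist(states, lid=f"l{i}", cov={"z": z}))
        f = surv.fit(hists, "phi ~ z", standardize=False)
        X, _, _ = surv.design_matrix(hists, "phi ~ z", standardize=False)
        # brute-force grid search at 0.001 resolution around the MLE
        b0 = np.arange(f.betas[0] - 0.05, f.betas[0] + 0.05, 0.001)
        b1 = np.arange(f.betas[1] - 0.05, f.betas[1] + 0.05, 0.001)
        lls = np.array(
            [[surv.loglik(hists, [a, b], X) for b in b1] for a in b0]
        )
        i, j = np.unravel_index(np.argmax(lls), lls.shape)
        assert abs(b0[i] - f.betas[0]) <= 1e-3 + 1e-9
        assert abs(b1[j] - f.betas[1]) <= 1e-3 + 1e-9
        assert lls.max() <= f.loglik + 1e-9

    def test_rank_deficiency_detected(self):
        hists = [
            _hist(["survived"], lid=f"l{i}", cov={"a": 1.0, "b": 2.0}) for i in range(4)
        ] + [_hist(["died"], lid="l9", cov={"a": 1.0, "b": 2.0})]
        with pytest.raises(io.ValidationError, match="rank"):
            surv.fit(hists, "phi ~ a + b", standardize=False)

    def test_parameter_recovery(self):
        # mean fitted betas across replicates near simulation truth
        truth = syn.SurvivalTruth(
            betas={"intercept": 2.0, "z": 0.8}, n_occasions=13
        )
        rng = np.random.default_rng(10)
        b0s, b1s = [], []
        for rep in range(40):
            cov = pd.DataFrame({"z": rng.normal(size=60)},
                               index=[f"l{i}" for i in range(60)])
            hists = syn.gen_encounter_histories(truth, cov, seed=rep)
            f = surv.fit(hists, "phi ~ z", standardize=False)
            b0s.append(f.betas[0])
            b1s.append(f.betas[1])
        assert np.mean(b0s) == pytest.approx(2.0, abs=3 * np.std(b0s) / np.sqrt(40) + 0.1)
        assert np.mean(b1s) == pytest.approx(0.8, abs=3 * np.std(b1s) / np.sqrt(40) + 0.1)


class TestSeasonalSurvival:
    def test_power_arithmetic(self):
        hists = [_hist(["survived"] * 9 + ["died"])] * 5  # phi-hat = 45/50 = 0.9
        f = surv.fit(hists, "phi ~ 1")
        s, se = surv.seasonal_survival(f, 13)
        assert s == pytest.approx(0.9**13, abs=1e-4)
        assert se > 0

    def test_delta_method_matches_simulation(self):
        # SE from the delta method should approximate the sampling SD of phi^n
        truth = syn.SurvivalTruth(betas={"intercept": float(logit(0.9))}, n_occasions=13)
        ests, ses = [], []
        for rep in range(60):
            cov = pd.DataFrame(index=[f"l{i}" for i in range(40)])
            hists = syn.gen_encounter_histories(truth, cov, seed=100 + rep)
            f = surv.fit(hists, "phi ~ 1")
            s, se = surv.seasonal_survival(f, 13)
            ests.append(s)
            ses.append(se)
        assert np.mean(ses) == pytest.approx(np.std(ests), rel=0.35)


class TestAicc:
    def test_formula_arithmetic(self):
        assert surv.aicc(-10.0, 2, 100) == pytest.approx(24 + 12 / 97)

    def test_k_zero_reduces_to_minus_two_loglik(self):
        assert surv.aicc(-10.0, 0, 100) == pytest.approx(20.0)

    def test_large_n_approaches_aic(self):
        assert surv.aicc(-10.0, 3, 10**9) == pytest.approx(26.0, abs=1e-6)

    def test_small_n_undefined(self):
        assert np.isnan(surv.aicc(-10.0, 5, 6))


class TestModelTable:
    def _histories(self, seed=0, n=40, beta_z=1.2):
        rng = np.random.default_rng(seed)
        truth = syn.SurvivalTruth(
            betas={"intercept": 1.5, "z": beta_z}, n_occasions=13
        )
        cov = pd.DataFrame({"z": rng.normal(size=n)}, index=[f"l{i}" for i in range(n)])
        return syn.gen_encounter_histories(truth, cov, seed=seed + 1)

    def test_duplicate_models_tie(self):
        hists = self._histories()
        tab, _ = surv.model_table(hists, {"a": "phi ~ z", "b": "phi ~ z"})
        assert tab["delta_aicc"].iloc[0] == 0.0
        assert tab["delta_aicc"].iloc[1] == 0.0

    def test_weights_sum_to_one(self):
        hists = self._histories()
        tab, _ = surv.model_table(
            hists, {"null": "phi ~ 1", "z": "phi ~ z", "zz": "phi ~ z"}
        )
        assert tab["weight"].sum() == pytest.approx(1.0)

    def test_failed_model_listed_not_ranked(self):
        hists = self._histories()
        tab, fits = surv.model_table(
            hists, {"null": "phi ~ 1", "bad": "phi ~ nonexistent"}
        )
        bad = tab[tab["model"] == "bad"].iloc[0]
        assert bad["failure"] != "" and np.isnan(bad["aicc"])
        assert "bad" not in fits

    def test_strong_effect_selected(self):
        # with a strong covariate effect the covariate model should win AICc
        wins = 0
        for rep in range(20):
            hists = self._histories(seed=rep, n=80, beta_z=1.5)
            tab, _ = surv.model_table(hists, {"null": "phi ~ 1", "z": "phi ~ z"})
            wins += tab["model"].iloc[0] == "z"
        assert wins >= 16

    def test_needs_two_models(self):
        with pytest.raises(ValueError):
            surv.model_table(self._histories(), {"only": "phi ~ 1"})


class TestFormulaAndDesign:
    def test_interaction_expansion(self):
        terms = surv._parse_formula("phi ~ sex * pmax")
        assert terms == [(), ("sex",), ("pmax",), ("pmax", "sex")]

    def test_standardization_skips_binary(self):
        hists = [
            _hist(["survived"], lid=f"l{i}", cov={"sex": float(i % 2), "z": float(i)})
            for i in range(6)
        ]
        X, names, scaling = surv.design_matrix(hists, "phi ~ sex + z")
        assert "sex" not in scaling and "z" in scaling
        zcol = X[:, names.index("z")]
        assert zcol.mean() == pytest.approx(0.0, abs=1e-12)
        assert zcol.std() == pytest.approx(1.0)

    def test_missing_covariate_named(self):
        hists = [_hist(["survived"], cov={})]
        with pytest.raises(io.ValidationError, match="pmax"):
            surv.design_matrix(hists, "phi ~ pmax")
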