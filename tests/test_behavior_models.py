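"""Regressor construction, mixed-model fitting, comparison, sequential effect."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from fpseq import behavior_models as bm, paradigm, synthetic_data as sd


@pytest.fixture(scope="module")
def small_fitted(study_hazards):
    """Six participants, low noise: sessions, regressor table, full-model fit."""
    hz_u, hz_c = study_hazards
    sessions = paradigm.generate_sessions(6, seed=21, mode="idealized")
    params = sd.BehaviorGenParams(sd_participant=0.01, sd_fp1context=0.0, sd_resid=0.02)
    table = sd.simulate_reaction_times(sessions, hz_u, hz_c, params, 9)
    reg = bm.build_regressor_table(table, hz_u, hz_c)
    fp2 = reg[(reg["position"] == "FP2") & reg["hf_c"].notna()]
    # the generator plants no FP1-category effect, so the recovery fit uses
    # the participant intercept alone (the 2-level category intercept is
    # nearly confounded with HF_C and only blurs a noiseless check)
    fit = bm.fit_mixed_model(fp2, random_terms=("participant",))
    return params, reg, fp2, fit


class TestRegressorTable:
    def test_row_counts_at_study_scale(self, study_hazards):
        """31 participants with no false alarms give 18,600 FP2 rows."""
        hz_u, hz_c = study_hazards
        sessions = paradigm.generate_sessions(31, seed=3, mode="idealized")
        params = sd.BehaviorGenParams(sd_participant=0, sd_fp1context=0, sd_resid=0)
        table = sd.simulate_reaction_times(sessions, hz_u, hz_c, params, 0)
        reg = bm.build_regressor_table(table, hz_u, hz_c)
        assert (reg["position"] == "FP2").sum() == 18600
        assert (reg["position"] == "FP1").sum() == 18600

    def test_false_alarms_excluded_only(self, idealized_session, study_hazards):
        hz_u, hz_c = study_hazards
        table = sd.simulate_reaction_times(
            idealized_session, hz_u, hz_c, sd.BehaviorGenParams(), 0
        )
        table = sd.inject_false_alarms(table, 0.05, 1)
        reg = bm.build_regressor_table(table, hz_u, hz_c)
        assert len(reg) == (~table["false_alarm"]).sum()

    def test_interaction_is_exact_product(self, small_fitted):
        _, reg, _, _ = small_fitted
        fp2 = reg[reg["position"] == "FP2"]
        np.testing.assert_array_equal(
            fp2["hf_uc"].to_numpy(), (fp2["hf_u"] * fp2["hf_c"]).to_numpy()
        )

    def test_hf_c_matches_direct_lookup(self, idealized_session, study_hazards):
        hz_u, hz_c = study_hazards
        table = sd.simulate_reaction_times(
            idealized_session, hz_u, hz_c, sd.BehaviorGenParams(), 0
        )
        reg = bm.build_regressor_table(table, hz_u, hz_c)
        sub = table[(table["position"] == "FP2") & (table["block"] == 1)]
        row = sub.iloc[0]
        key = (1, paradigm.duration_category(row["fp1_context_s"]))
        expected = hz_c[key].value_at(round(row["foreperiod_s"], 2))
        got = reg[(reg["position"] == "FP2") & (reg["block"] == 1)]["hf_c"].iloc[0]
        assert got == pytest.approx(expected)


class TestMixedModel:
    def test_recovers_planted_betas_at_low_noise(self, small_fitted):
        """Planted coefficients land within 3 SE (the hazard regressors are
        collinear, so the per-term SE — not the residual SD — sets the scale)."""
        params, _, _, fit = small_fitted
        assert fit.converged
        for term, planted in [
            ("HF_U", params.beta_u), ("HF_C", params.beta_c), ("HF_U:HF_C", params.beta_uc),
        ]:
            assert abs(fit.estimates[term] - planted) < 3 * fit.se[term]

    def test_gls_oracle_on_two_participant_toy(self):
        """GLS with the fitted variance components reproduces the estimates."""
        rng = np.random.default_rng(8)
        n_per, n_sub = 200, 2
        sub = np.repeat([1, 2], n_per)
        x = rng.uniform(0, 1, n_per * n_sub)
        y = 0.3 - 0.05 * x + np.array([0.02, -0.02])[sub - 1] + rng.normal(0, 0.03, n_per * n_sub)
        table = pd.DataFrame({
            "participant": sub, "position": "FP1", "block": 1,
            "rt": y, "log_rt": np.log(y), "hf_u": x,
            "hf_c": np.nan, "hf_uc": np.nan, "fp1_category": "",
        })
        fit = bm.fit_mixed_model(table, ("HF_U",), ("participant",),
                                 information_criteria=False)
        # closed-form GLS: V = sigma2*I + tau2 * Z Z', beta = (X'V^-1 X)^-1 X'V^-1 y
        tau2 = fit.re_variances["participant"]
        sigma2 = fit.resid_variance
        z = np.zeros((len(y), 2))
        z[np.arange(len(y)), sub - 1] = 1.0
        v = sigma2 * np.eye(len(y)) + tau2 * z @ z.T
        xmat = np.column_stack([np.ones(len(y)), x])
        vinv = np.linalg.inv(v)
        beta = np.linalg.solve(xmat.T @ vinv @ xmat, xmat.T @ vinv @ y)
        assert fit.estimates["(Intercept)"] == pytest.approx(beta[0], abs=1e-6)
        assert fit.estimates["HF_U"] == pytest.approx(beta[1], abs=1e-6)

    def test_standardized_beta_invariant_to_response_scaling(self, small_fitted):
        _, _, fp2, fit = small_fitted
        scaled = fp2.copy()
        scaled["rt"] = scaled["rt"] * 3.0 + 1.0
        fit2 = bm.fit_mixed_model(scaled, random_terms=("participant",),
                                  information_criteria=False)
        for term in ("HF_U", "HF_C", "HF_U:HF_C"):
            assert fit2.std_beta[term] == pytest.approx(fit.std_beta[term], abs=1e-3)

    def test_deviance_monotone_in_nesting(self, small_fitted):
        _, _, fp2, _ = small_fitted
        lls = []
        for terms in [("HF_U",), ("HF_U", "HF_C"), ("HF_U", "HF_C", "HF_U:HF_C")]:
            fit = bm.fit_mixed_model(fp2, terms, reml=False)
            lls.append(fit.llf_ml)
        assert lls[0] <= lls[1] + 1e-6 and lls[1] <= lls[2] + 1e-6

    def test_unknown_term_and_empty_table_fail(self, small_fitted):
        _, _, fp2, _ = small_fitted
        with pytest.raises(ValueError, match="unknown fixed term"):
            bm.fit_mixed_model(fp2, ("HF_X",))
        with pytest.raises(ValueError, match="empty"):
            bm.fit_mixed_model(fp2.iloc[:0])


class TestModelComparison:
    def test_identical_models_tie(self, small_fitted):
        _, _, fp2, _ = small_fitted
        a = bm.fit_mixed_model(fp2, ("HF_U",), reml=False, label="a")
        b = bm.fit_mixed_model(fp2, ("HF_U",), reml=False, label="b")
        assert a.aic == pytest.approx(b.aic, abs=0.2)

    def test_full_model_wins_when_interaction_planted(self, small_fitted):
        _, _, fp2, _ = small_fitted
        fits = [
            bm.fit_mixed_model(fp2, terms, reml=False, label=lab)
            for lab, terms in bm.FP2_MODELS.items()
        ]
        comp = bm.compare_models(fits)
        assert comp.ranking_aic[0] == "HF_U+HF_C+HF_U:HF_C"
        for lab, lr in comp.lr_tests.items():
            assert lr["p"] < 0.05

    def test_mismatched_n_obs_fails(self, small_fitted):
        _, _, fp2, _ = small_fitted
        a = bm.fit_mixed_model(fp2, ("HF_U",), reml=False)
        b = bm.fit_mixed_model(fp2.iloc[:-10], ("HF_U",), reml=False)
        with pytest.raises(ValueError, match="observation counts"):
            bm.compare_models([a, b])


class TestConditionalR2:
    def test_three_variance_hand_example(self):
        assert bm.conditional_r2_components(0.2, 0.3, 0.5) == pytest.approx(0.5)

    def test_limits(self):
        assert bm.conditional_r2_components(0.0, 0.0, 1.0) == pytest.approx(0.0)
        assert bm.conditional_r2_components(0.4, 0.6, 0.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            bm.conditional_r2_components(0.0, 0.0, 0.0)

    def test_fit_reports_consistent_value(self, small_fitted):
        _, _, _, fit = small_fitted
        assert 0.0 <= fit.conditional_r2 <= 1.0
        assert bm.conditional_r2(fit) == pytest.approx(fit.conditional_r2)


class TestSequentialEffect:
    def test_block1_has_only_congruent_cells(self, idealized_session, study_hazards):
        hz_u, hz_c = study_hazards
        table = sd.simulate_reaction_times(
            idealized_session, hz_u, hz_c, sd.BehaviorGenParams(), 0
        )
        out = bm.sequential_effect_summary(table)
        block1 = out[out["block"] == 1]
        assert set(block1["seq_type"]) == {"LL", "SS"}

    def test_planted_context_effect_orders_ls_above_ss(self, idealized_session):
        """With a long-FP1 slowdown planted directly, mean(LS) > mean(SS)."""
        table = idealized_session.copy()
        fp2 = table["position"] == "FP2"
        ctx_long = fp2 & (table["fp1_context_s"] >= 1.3)
        table.loc[fp2, "rt_s"] = 0.3
        table.loc[ctx_long, "rt_s"] = 0.35
        table.loc[table["position"] == "FP1", "rt_s"] = 0.3
        out = bm.sequential_effect_summary(table)
        b4 = out[out["block"] == 4].set_index("seq_type")["mean_rt"]
        assert b4["LS"] > b4["SS"]
        assert b4["LS"] == pytest.approx(0.35)


def test_outlier_exclusion_drops_extreme_rts_only(small_fitted):
    _, reg, _, _ = small_fitted
    fp1 = reg[reg["position"] == "FP1"].copy()
    spiked = fp1.copy()
    spiked.loc[spiked.index[0], "rt"] = 10.0  # absurd reaction time
    kept = bm.exclude_outliers(spiked, threshold_sd=2.5)
    assert len(kept) < len(spiked)
    assert 10.0 not in kept["rt"].to_numpy()
    # a clean table loses (almost) nothing beyond the tail fraction
    frac = len(bm.exclude_outliers(fp1)) / len(fp1)
    assert frac > 0.97
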