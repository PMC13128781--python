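import math

import numpy as np
import pandas as pd
import pytest

from speechnorms import synthdata
from speechnorms.model_compare import (
    akaike_weights,
    comparison_frame,
    corpus_support_log_ratio,
    corpus_support_ratio,
    filter_rt_trials,
    fit_acc_model,
    fit_rt_model,
    marginal_r2,
    model_summary_frame,
    run_validation,
)
from speechnorms.mixedmodels import MixedFitResult


def trials_frame(rows):
    return pd.DataFrame(rows, columns=["participant", "item", "rt", "accuracy"])


class TestFilter:
    def test_range_and_accuracy_rules(self):
        df = trials_frame([
            ("p1", "w1", 150.0, 1),    # below 200 ms -> excluded
            ("p1", "w2", 900.0, 0),    # incorrect -> excluded from RT set
            ("p1", "w3", 3500.0, 1),   # above 3000 ms -> excluded
            ("p1", "w4", 700.0, 1),
            ("p1", "w5", 710.0, 1),
            ("p1", "w6", 695.0, 1),
        ])
        out = filter_rt_trials(df)
        assert set(out["item"]) == {"w4", "w5", "w6"}

    def test_single_gross_outlier_removed_exactly(self):
        # tight cluster plus one far outlier: only the outlier goes
        rts = [500, 505, 495, 502, 498, 501, 499, 503, 497, 2600]
        df = trials_frame([("p1", f"w{i}", float(rt), 1) for i, rt in enumerate(rts)])
        out = filter_rt_trials(df)
        assert len(out) == 9
        assert 2600 not in out["rt"].values

    def test_injected_outliers_removed_and_oracle_match(self, small_norm_table):
        spec = synthdata.TrialSpec(
            n_participants=10, n_items=80, outlier_rate=0.03, seed=21
        )
        trials, truth = synthdata.gen_trials(spec, small_norm_table)
        out = filter_rt_trials(trials)
        injected = [t for kind in truth["outlier_trials"].values() for t in kind]
        assert not set(injected) & set(out.index)
        # independent naive oracle: explicit per-participant loops to convergence
        surv = trials[(trials.accuracy == 1) & (trials.rt >= 200) & (trials.rt <= 3000)]
        keep = set(surv.index)
        changed = True
        while changed:
            changed = False
            for p, grp in surv.loc[sorted(keep)].groupby("participant"):
                if len(grp) < 2:
                    continue
                m, s = grp.rt.mean(), grp.rt.std(ddof=1)
                for idx, rt in grp.rt.items():
                    if abs(rt - m) > 2.5 * s:
                        keep.discard(idx)
                        changed = True
        assert set(out.index) == keep

    def test_filter_is_a_fixed_point(self, small_norm_table):
        spec = synthdata.TrialSpec(
            n_participants=8, n_items=60, outlier_rate=0.05, seed=4
        )
        trials, _ = synthdata.gen_trials(spec, small_norm_table)
        once = filter_rt_trials(trials)
        twice = filter_rt_trials(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_single_pass_mode_is_subset(self, small_norm_table):
        trials, _ = synthdata.gen_trials(
            synthdata.TrialSpec(n_participants=8, n_items=60, seed=4), small_norm_table
        )
        one_pass = filter_rt_trials(trials, max_passes=1)
        converged = filter_rt_trials(trials)
        assert set(converged.index) <= set(one_pass.index) <= set(trials.index)

    def test_tiny_participant_retained_with_warning(self):
        df = trials_frame([
            ("p1", "w1", 500.0, 1),
            ("p2", "w1", 400.0, 1), ("p2", "w2", 410.0, 1), ("p2", "w3", 405.0, 1),
        ])
        with pytest.warns(UserWarning, match="fewer"):
            out = filter_rt_trials(df)
        assert ("p1" == out["participant"]).sum() == 1


class TestAkaikeWeights:
    def test_equal_aics_give_equal_weights(self):
        comp = akaike_weights({"a": 100.0, "b": 100.0, "c": 100.0})
        assert all(w == pytest.approx(1 / 3, abs=1e-12) for w in comp.weights.values())
        assert sum(comp.weights.values()) == pytest.approx(1.0, abs=1e-12)

    def test_delta_two_gives_ratio_e(self):
        comp = akaike_weights({"best": 100.0, "other": 102.0})
        assert comp.weights["best"] / comp.weights["other"] == pytest.approx(
            math.e, rel=1e-12
        )

    def test_shift_invariance(self):
        a = akaike_weights({"m1": 10.0, "m2": 13.0, "m3": 11.5})
        b = akaike_weights({"m1": 1010.0, "m2": 1013.0, "m3": 1011.5})
        for m in a.weights:
            assert a.weights[m] == pytest.approx(b.weights[m], abs=1e-12)

    def test_normalization_after_log_space(self):
        comp = akaike_weights({"a": 0.0, "b": 5000.0, "c": 10000.0})
        assert sum(comp.weights.values()) == pytest.approx(1.0, abs=1e-12)

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights({"only": 1.0})


class TestSupportRatio:
    def test_identical_aics_give_unit_ratio(self):
        comp = akaike_weights(
            {"A:freq": 50.0, "A:cd": 50.0, "B:freq": 50.0, "B:cd": 50.0}
        )
        assert corpus_support_ratio(comp, "A", "B") == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_ratio(self):
        aics = {"A:freq": 100.0, "A:cd": 98.0, "B:freq": 110.0, "B:cd": 108.0}
        comp = akaike_weights(aics)
        # by hand: deltas 2,0,12,10 -> ratio (e^-1 + 1) / (e^-6 + e^-5)
        expected = (math.exp(-1) + 1.0) / (math.exp(-6) + math.exp(-5))
        assert corpus_support_ratio(comp, "A", "B") == pytest.approx(expected, rel=1e-12)

    def test_log_ratio_survives_underflow(self):
        comp = akaike_weights(
            {"A:freq": 0.0, "A:cd": 1.0, "B:freq": 4000.0, "B:cd": 4001.0}
        )
        lr = corpus_support_log_ratio(comp, "A", "B")
        assert lr == pytest.approx(2000.0, abs=1.0)
        assert corpus_support_ratio(comp, "B", "A") == pytest.approx(0.0, abs=1e-300)

    def test_unknown_corpus_errors(self):
        comp = akaike_weights({"A:freq": 1.0, "B:freq": 2.0})
        with pytest.raises(KeyError):
            corpus_support_ratio(comp, "A", "C")


class TestMarginalR2:
    def _fit(self, kind, var_fixed, vc, scale):
        return MixedFitResult(
            kind=kind,
            fe_params=pd.Series([0.0]),
            bse=pd.Series([1.0]),
            vc=vc,
            scale=scale,
            llf=0.0,
            k=1,
            n_obs=10,
            converged=True,
            fitted_fixed_var=var_fixed,
        )

    def test_zero_slopes_give_zero(self):
        fit = self._fit("linear", 0.0, {"p": 1.0, "i": 2.0}, 3.0)
        assert marginal_r2(fit) == 0.0

    def test_known_variance_partition(self):
        # var_f / (var_f + tau_p + tau_i + sigma2), plugged by hand
        fit = self._fit("linear", 4.0, {"p": 1.0, "i": 2.0}, 3.0)
        assert marginal_r2(fit) == pytest.approx(4.0 / 10.0, abs=1e-12)

    def test_logit_uses_latent_scale_residual(self):
        fit = self._fit("binomial", 2.0, {"p": 0.5, "i": 0.5}, None)
        assert marginal_r2(fit) == pytest.approx(
            2.0 / (3.0 + math.pi**2 / 3.0), abs=1e-12
        )

    def test_bounded_for_fitted_model(self, small_norm_table):
        trials, _ = synthdata.gen_trials(
            synthdata.TrialSpec(n_participants=12, n_items=60, seed=6), small_norm_table
        )
        fit = fit_rt_model(filter_rt_trials(trials), "zipf")
        assert 0.0 <= fit.marginal_r2 <= 1.0

    def test_recovers_analytic_partition_from_simulation(self, small_norm_table):
        # all slopes zero except zipf: var_f ~= beta^2 var(zipf)
        beta = dict.fromkeys(synthdata.DEFAULT_RT_BETA, 0.0)
        beta.update(intercept=800.0, zipf=-40.0)
        spec = synthdata.TrialSpec(
            n_participants=30, n_items=150, rt_beta=beta,
            sd_participant=50.0, sd_item=30.0, sd_resid=100.0, seed=8,
        )
        trials, truth = synthdata.gen_trials(spec, small_norm_table)
        fit = fit_rt_model(trials, "zipf", )
        var_f = (40.0**2) * truth["item_covariates"].zipf.var(ddof=0)
        expected = var_f / (var_f + 50.0**2 + 30.0**2 + 100.0**2)
        # the fitted slope enters var_f quadratically, so allow generous
        # Monte-Carlo slack at this n
        assert fit.marginal_r2 == pytest.approx(expected, rel=0.3)


@pytest.fixture(scope="module")
def small_trials(small_norm_table):
    trials, _ = synthdata.gen_trials(
        synthdata.TrialSpec(n_participants=15, n_items=80, seed=13),
        small_norm_table,
    )
    return synthdata.add_noisy_predictor(trials, "zipf", "b_zipf", 0.8, seed=99)


class TestValidationDriver:
    def test_true_predictor_model_usually_wins(self, small_norm_table):
        # stochastic at this n: the generating predictor's model should
        # attain the lower AIC in a clear majority of replicates
        wins = 0
        for rep in range(9):
            trials, _ = synthdata.gen_trials(
                synthdata.TrialSpec(n_participants=15, n_items=80, seed=300 + rep),
                small_norm_table,
            )
            trials = synthdata.add_noisy_predictor(trials, "zipf", "b_zipf", 0.8, seed=rep)
            filtered = filter_rt_trials(trials)
            wins += fit_rt_model(filtered, "zipf").aic < fit_rt_model(filtered, "b_zipf").aic
        assert wins > 9 / 2

    def test_weights_cover_corpus_models_only_by_default(self, small_trials):
        report = run_validation(
            small_trials, {"A": {"freq": "zipf"}, "B": {"freq": "b_zipf"}}, outcome="rt"
        )
        assert set(report.comparison.labels) == {"A:freq", "B:freq"}
        with_base = run_validation(
            small_trials,
            {"A": {"freq": "zipf"}, "B": {"freq": "b_zipf"}},
            outcome="rt",
            include_baseline_in_weights=True,
        )
        assert "baseline" in with_base.comparison.labels

    def test_comparison_and_summary_frames(self, small_trials):
        report = run_validation(
            small_trials, {"A": {"freq": "zipf"}, "B": {"freq": "b_zipf"}}, outcome="rt"
        )
        frame = comparison_frame(report)
        assert {"model", "aic", "delta_aic", "weight", "marginal_r2"} <= set(frame.columns)
        assert frame.loc[frame.model != "baseline", "weight"].sum() == pytest.approx(1.0)
        summary = model_summary_frame(report.models["A:freq"])
        assert "zipf" in summary.term.values
        assert "tau00_participant" in summary.term.values

    def test_accuracy_models_report_odds_ratios(self, small_trials):
        report = run_validation(
            small_trials, {"A": {"freq": "zipf"}}, outcome="accuracy"
        )
        fit = report.models["A:freq"]
        summary = model_summary_frame(fit)
        assert "odds_ratio" in summary.columns
        assert (fit.result.odds_ratios > 0).all()

    def test_missing_predictor_column_errors(self, small_trials):
        with pytest.raises(ValueError, match="missing predictor"):
            fit_rt_model(small_trials, "no_such_column")
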