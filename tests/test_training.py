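"""Stepwise-AIC selection, bootstrap frequencies, OLS fits, evaluation."""
import numpy as np
import pandas as pd
import pytest

from contextpp.training import (
    StepwiseAICRegressor,
    TrainingSet,
    aic,
    bootstrap_selection,
    drop_aliased_columns,
    evaluate_r2,
    false_positive_bound,
    fit_scaling,
    fit_site_model,
    gaussian_loglik,
    information_capture_fraction,
    partial_correlation,
    seed_match_information_bits,
    select_training_mrnas,
    stepwise_select,
    top_n_response,
    top_prediction_count,
)
from contextpp.types import IsoformProfile, MirnaFamily, TranscriptModel


class TestAic:
    def test_definition(self):
        assert aic(0.0, 3) == 6.0

    def test_matches_hand_computed_gaussian_likelihood(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=50)
        rss = float(np.sum((y - y.mean()) ** 2))
        ll = gaussian_loglik(rss, 50)
        by_hand = -0.5 * 50 * (np.log(2 * np.pi) + np.log(rss / 50) + 1)
        assert ll == pytest.approx(by_hand)
        assert aic(ll, 1) == pytest.approx(-2 * by_hand + 2)

    def test_complexity_charge(self):
        assert aic(-10.0, 5) - aic(-10.0, 4) == 2.0


class TestStepwise:
    def test_noiseless_planted_truth_exactly_recovered(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(200, 10)), columns=[f"f{i}" for i in range(10)])
        y = 2 * X["f3"] - 1.5 * X["f7"]
        assert sorted(stepwise_select(X, y)) == ["f3", "f7"]

    def test_collinear_duplicate_selected_once(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(150, 4)), columns=list("abcd"))
        X["a_dup"] = X["a"]
        sel = stepwise_select(X, 3 * X["a"] + X["b"])
        assert sorted(sel) in (["a", "b"], ["a_dup", "b"])

    def test_noise_false_inclusion_rate(self):
        """AIC admits a null feature with probability ~0.157, so with five
        candidates at most one spurious feature enters in >= 80% of
        datasets."""
        hits = 0
        for s in range(60):
            rng = np.random.default_rng(s)
            X = pd.DataFrame(rng.normal(size=(1000, 5)))
            hits += len(stepwise_select(X, rng.normal(size=1000))) <= 1
        assert hits / 60 >= 0.8

    def test_estimator_interface(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(300, 6)), columns=[f"x{i}" for i in range(6)])
        y = 0.5 * X["x1"] - 0.3 * X["x4"] + rng.normal(0, 0.1, 300)
        reg = StepwiseAICRegressor().fit(X, y)
        assert set(reg.selected_features_) == {"x1", "x4"}
        pred = reg.predict(X)
        assert evaluate_r2(pred, y) > 0.9
        assert reg.get_params()["start"] == "intercept"


class TestBootstrapSelection:
    def make_training_set(self, seed=0, n=400):
        rng = np.random.default_rng(seed)
        per = {}
        for st in ("8mer", "7mer-m8", "7mer-A1", "6mer"):
            X = pd.DataFrame(rng.normal(size=(n, 6)),
                             columns=["t1", "t2", "t3", "n1", "n2", "n3"])
            y = 0.4 * X["t1"] - 0.35 * X["t2"] + 0.3 * X["t3"] + rng.normal(0, 0.1, n)
            exps = pd.Series(rng.integers(0, 5, n).astype(str))
            per[st] = (X, y, exps)
        return TrainingSet(per)

    def test_planted_truth_in_robust_set(self):
        rep = bootstrap_selection(self.make_training_set(), B=25, seed=7)
        assert set(rep.robust_set) == {"t1", "t2", "t3"}
        assert (rep.frequencies.loc[["t1", "t2", "t3"]] == 1.0).all().all()

    def test_heldout_r2_recorded(self):
        rep = bootstrap_selection(self.make_training_set(), B=5, seed=7)
        assert rep.heldout_r2.shape == (5, 4)
        assert (rep.heldout_r2 > 0.8).all().all()

    def test_stratified_sampling_contract(self):
        """Each bootstrap draws 70% +- 1 row of every experiment."""
        rng = np.random.default_rng(3)
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        y = X["a"] + rng.normal(0, 0.1, n)
        exps = pd.Series((["e0"] * 80) + (["e1"] * 120))

        drawn = []
        orig = StepwiseAICRegressor.fit

        def spy(self, Xs, ys):
            drawn.append(len(Xs))
            return orig(self, Xs, ys)

        StepwiseAICRegressor.fit = spy
        try:
            bootstrap_selection(TrainingSet({"8mer": (X, y, exps)}), B=3, seed=0)
        finally:
            StepwiseAICRegressor.fit = orig
        assert all(abs(k - round(0.7 * 80) - round(0.7 * 120)) <= 2 for k in drawn)

    def test_too_few_bootstraps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_selection(self.make_training_set(), B=1)


class TestFitSiteModel:
    def test_noiseless_beta_recovered(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        y = 1.0 + 0.5 * X["a"] - 0.25 * X["b"] + 0.1 * X["c"]
        model, ci = fit_site_model(X, y, "8mer")
        assert model.intercept == pytest.approx(1.0, abs=1e-10)
        assert model.coefficients["a"] == pytest.approx(0.5, abs=1e-10)
        assert model.cap == -0.03

    def test_coefficient_rmse_scales_with_noise(self):
        rng = np.random.default_rng(5)
        n, sigma = 10_000, 0.5
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        beta = np.array([0.3, -0.2, 0.1, 0.05])
        y = X.to_numpy() @ beta + rng.normal(0, sigma, n)
        model, _ = fit_site_model(X, y, "6mer")
        est = np.array([model.coefficients[c] for c in "abcd"])
        assert np.sqrt(np.mean((est - beta) ** 2)) < 3 * sigma / np.sqrt(n)

    def test_intercept_only_is_mean(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        model, _ = fit_site_model(pd.DataFrame(index=range(4)), y, "6mer")
        assert model.intercept == pytest.approx(y.mean())

    def test_singular_design_rejected_and_alias_dropper(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="singular"):
            fit_site_model(X, [1, 2, 3, 4], "8mer")
        assert drop_aliased_columns(X) == ["a"]


class TestFitScaling:
    def table(self, values, feature="F", st="8mer"):
        return pd.DataFrame({"feature": feature, "site_type": st, "value": values})

    def test_linear_interpolated_percentiles(self):
        st = fit_scaling(self.table(np.arange(1.0, 101.0)))
        p5, p95 = st.lookup("F", "8mer")
        assert (p5, p95) == (pytest.approx(5.95), pytest.approx(95.05))

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_scaling(self.table(np.ones(30)))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="need"):
            fit_scaling(self.table(np.arange(10.0)))


class TestPartialCorrelation:
    def test_empty_controls_is_pearson(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=200), rng.normal(size=200)
        assert partial_correlation(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_controlled_variable_has_zero_partial(self):
        # a response that is (essentially) the control itself carries no
        # signal once the control is regressed out
        rng = np.random.default_rng(7)
        c = rng.normal(size=500)
        x = c + rng.normal(0, 0.5, 500)
        y = c + rng.normal(0, 1e-6, 500)
        assert abs(partial_correlation(x, y, controls=c.reshape(-1, 1))) < 0.1

    def test_planted_partial_effect_estimated(self):
        rng = np.random.default_rng(8)
        n = 10_000
        c = rng.normal(size=(n, 2))
        x = c @ [0.5, -0.3] + rng.normal(size=n)
        target_r = 0.2
        y = c @ [0.4, 0.2] + target_r / np.sqrt(1 - target_r**2) * (x - c @ [0.5, -0.3]) \
            + rng.normal(size=n)
        got = partial_correlation(x, y, controls=c)
        assert got == pytest.approx(target_r, abs=0.03)

    def test_degenerate_residuals_flagged(self):
        c = np.arange(10.0)
        with pytest.raises(ValueError, match="degenerate"):
            partial_correlation(c, np.ones(10), controls=c.reshape(-1, 1))


class TestEvaluateR2:
    def test_perfect_and_invariance(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=100)
        assert evaluate_r2(y, y) == pytest.approx(1.0)
        assert evaluate_r2(3 * y - 2, y) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(10)
        assert evaluate_r2(rng.normal(size=10_000), rng.normal(size=10_000)) < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            evaluate_r2(np.ones(10), np.arange(10.0))


class TestTopNResponse:
    def ranked(self, n=600, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "transcript_id": [f"t{i}" for i in range(n)],
            "family_id": ["fam"] * n,
            "cwcs": np.sort(rng.uniform(-2, 0, n)),
        })
        fc = {(f"t{i}", "fam"): rng.normal() for i in range(n)}
        return df, fc

    def test_threshold_counts(self):
        df, fc = self.ranked()
        out = top_n_response(df, fc, thresholds=[4, 16], n_mirnas=7, resamples=50, seed=0)
        assert list(out["n_predictions"]) == [28, 112]

    def test_threshold_beyond_predictions_emits_no_row(self):
        df, fc = self.ranked(n=50)
        out = top_n_response(df, fc, thresholds=[4, 100], n_mirnas=7, resamples=20, seed=0)
        assert list(out["threshold"]) == [4]

    def test_random_scores_fall_inside_null_band(self):
        inside = 0
        for seed in range(20):
            df, fc = self.ranked(seed=seed)
            rng = np.random.default_rng(seed + 100)
            df = df.assign(cwcs=rng.permutation(df["cwcs"].to_numpy()))
            out = top_n_response(df, fc, thresholds=[16], n_mirnas=7,
                                 resamples=200, seed=seed)
            row = out.iloc[0]
            inside += row["null_low"] <= row["median_fc"] <= row["null_high"]
        assert inside >= 18  # >= 90% of seeds


class TestSelectTrainingMrnas:
    def build(self, abundances, utr3):
        t = TranscriptModel("tx", "g", "", "AUGUAA", utr3)
        ends = np.linspace(40, len(utr3), len(abundances)).astype(int)
        prof = IsoformProfile("tx", ends, abundances)
        return {"tx": t}, {"tx": prof}

    def test_dominant_isoform_threshold(self, family):
        utr3 = "C" * 40 + "ACAUUCCA" + "C" * 52
        txs, profs = self.build([0.05, 0.95], utr3)
        assert select_training_mrnas(txs, profs, family) == ["tx"]
        txs, profs = self.build([0.4, 0.6], utr3)
        assert select_training_mrnas(txs, profs, family) == []

    def test_multi_site_mrnas_excluded(self, family):
        utr3 = "C" * 20 + "ACAUUCC" + "C" * 10 + "ACAUUCC" + "C" * 20
        txs, profs = self.build([1.0], utr3)
        assert select_training_mrnas(txs, profs, family) == []


class TestWorkedExampleArithmetic:
    def test_site_information_contents(self):
        assert seed_match_information_bits(6) == 12.0
        assert seed_match_information_bits(7) == 14.0

    def test_information_capture(self):
        assert information_capture_fraction(0.044, 0.044 - 0.031) == pytest.approx(
            (0.044 - 0.013) / 0.044
        )

    def test_false_positive_bound(self):
        assert false_positive_bound(0.08) == pytest.approx(0.16)

    def test_top_prediction_counts(self):
        assert top_prediction_count(4, 7) == 28
        assert top_prediction_count(16, 7) == 112
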