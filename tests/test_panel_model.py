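import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirqpcr.errors import SeparationError, SingularDesignError, ValidationError
from mirqpcr.panel_model import (
    EpramModel,
    addition_check,
    deserialize_model,
    epram_score,
    fit_logistic,
    lr_test_drop_one,
    select_panel,
    serialize_model,
)


def _binary_exposure_data():
    """8/10 exposed cases vs 2/10 exposed controls."""
    x = np.r_[np.ones(8), np.zeros(2), np.ones(2), np.zeros(8)]
    y = np.r_[np.ones(10), np.zeros(10)]
    features = pd.DataFrame({"x": x})
    return features, y


class TestFitLogistic:
    def test_closed_form_two_by_two(self):
        features, y = _binary_exposure_data()
        model = fit_logistic(features, y)
        # MLE coefficient of a single binary predictor is the log odds ratio
        assert model.coefficients[0] == pytest.approx(np.log(16), abs=1e-4)
        assert model.intercept == pytest.approx(np.log(2 / 8), abs=1e-4)

    def test_null_model_intercept_is_logit_prevalence(self):
        rng = np.random.default_rng(0)
        features = pd.DataFrame({"x": rng.normal(size=2000)})
        y = (rng.random(2000) < 0.3).astype(float)
        model = fit_logistic(features, y)
        assert model.coefficients[0] == pytest.approx(0.0, abs=0.12)
        prev = y.mean()
        assert model.intercept == pytest.approx(np.log(prev / (1 - prev)), abs=0.15)

    def test_perfect_separation_detected(self):
        features = pd.DataFrame({"x": np.r_[np.arange(10), np.arange(20, 30)]})
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(SeparationError):
            fit_logistic(features, y)

    def test_duplicated_feature_is_singular(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        features = pd.DataFrame({"a": x, "b": x})
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(SingularDesignError):
            fit_logistic(features, y)

    def test_constant_feature_rejected(self):
        features = pd.DataFrame({"a": np.ones(30)})
        with pytest.raises(SingularDesignError):
            fit_logistic(features, np.r_[np.ones(15), np.zeros(15)])


class TestLrTest:
    def test_g_statistic_on_two_by_two(self):
        features, y = _binary_exposure_data()
        model = fit_logistic(features, y)
        table = lr_test_drop_one(model, features, y).set_index("feature")
        # independent oracle: G = 2 sum O ln(O/E) on the 2x2 table
        observed = np.array([[8, 2], [2, 8]], dtype=float)
        expected = np.outer(observed.sum(1), observed.sum(0)) / observed.sum()
        g = 2 * (observed * np.log(observed / expected)).sum()
        assert g == pytest.approx(7.71, abs=0.01)
        assert table.loc["x", "lr_chisq"] == pytest.approx(g, abs=1e-3)
        assert table.loc["x", "lr_p"] == pytest.approx(
            stats.chi2.sf(g, 1), abs=1e-4
        )

    def test_full_ll_at_least_reduced_ll(self, rng):
        features = pd.DataFrame(rng.normal(size=(80, 3)), columns=list("abc"))
        y = (rng.random(80) < 0.5).astype(float)
        model = fit_logistic(features, y)
        table = lr_test_drop_one(model, features, y)
        assert (table["lr_chisq"] >= 0).all()

    def test_null_lr_mean_is_chi2_one(self):
        rng = np.random.default_rng(2)
        stats_ = []
        for _ in range(400):
            features = pd.DataFrame({"x": rng.normal(size=60)})
            y = (rng.random(60) < 0.5).astype(float)
            if y.sum() < 2 or y.sum() > 58:
                continue
            model = fit_logistic(features, y)
            table = lr_test_drop_one(model, features, y)
            stats_.append(table["lr_chisq"].iloc[0])
        mean = np.mean(stats_)
        se = np.sqrt(2 / len(stats_))  # Var(chi2_1) = 2
        assert mean == pytest.approx(1.0, abs=4 * se)


class TestSelectPanel:
    def test_alpha_one_keeps_everything(self, rng):
        features = pd.DataFrame(rng.normal(size=(120, 3)), columns=list("abc"))
        beta = np.array([1.0, 0.0, -1.0])
        eta = features.to_numpy() @ beta
        y = (rng.random(120) < 1 / (1 + np.exp(-eta))).astype(float)
        full, panel = select_panel(features, y, alpha=1.0)
        assert panel.feature_ids == full.feature_ids
        assert panel.log_likelihood == pytest.approx(full.log_likelihood)

    def test_empty_selection_warns_intercept_only(self, rng):
        features = pd.DataFrame(rng.normal(size=(60, 2)), columns=list("ab"))
        y = np.r_[np.ones(30), np.zeros(30)]
        rng.shuffle(y)
        with pytest.warns(UserWarning, match="intercept-only"):
            full, panel = select_panel(features, y, alpha=1e-9)
        assert panel.feature_ids == []

    def test_recovers_planted_informative_features(self):
        # 3 informative among 8 at n=100/100, 1-SD effects
        from mirqpcr.synthetic_data import (
            generate_validation_cohort,
            panel_recovery_config,
        )

        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cohort = generate_validation_cohort(panel_recovery_config(seed=seed))
            values = -cohort.ct.ct.drop(columns=["cel-miR-39"])  # log2 abundance
            y = (cohort.groups == "RA").astype(float).to_numpy()
            full, panel = select_panel(values, y)
            informative = {"miR-24", "miR-30c", "miR-125a-5p"}
            hits += informative <= set(panel.feature_ids)
        assert hits >= n_seeds - 1


class TestEpramScore:
    def _model(self, coefs, intercept=0.0):
        return EpramModel(
            feature_ids=[f"f{i}" for i in range(len(coefs))],
            coefficients=np.array(coefs, dtype=float),
            intercept=intercept,
            log_likelihood=0.0,
        )

    def test_x_zero_is_half(self):
        model = self._model([1.0])
        features = pd.DataFrame({"f0": [0.0]})
        assert epram_score(model, features).iloc[0] == 0.5

    @pytest.mark.parametrize("x,expected", [(np.log(3), 0.25), (-np.log(3), 0.75)])
    def test_closed_form_values(self, x, expected):
        # x is the negated linear predictor: eta = -x
        model = self._model([1.0], intercept=0.0)
        features = pd.DataFrame({"f0": [-x]})
        assert epram_score(model, features).iloc[0] == pytest.approx(expected)

    def test_logistic_symmetry(self, rng):
        model = self._model([1.0])
        eta = rng.normal(size=10)
        features = pd.DataFrame({"f0": eta})
        mirrored = pd.DataFrame({"f0": -eta})
        total = epram_score(model, features).to_numpy() + epram_score(
            model, mirrored
        ).to_numpy()
        assert total == pytest.approx(np.ones(10))

    def test_monotone_in_positive_coefficient_feature(self):
        model = self._model([2.0])
        features = pd.DataFrame({"f0": np.linspace(-3, 3, 20)})
        scores = epram_score(model, features)
        assert scores.is_monotonic_increasing

    def test_missing_feature_is_error(self):
        model = self._model([1.0])
        with pytest.raises(ValidationError, match="missing"):
            epram_score(model, pd.DataFrame({"other": [1.0]}))

    def test_unit_rescaling_invariance(self, rng):
        # pM -> fM rescale of one feature leaves probabilities and LR alone
        features = pd.DataFrame(rng.normal(size=(100, 2)), columns=["a", "b"])
        eta = features["a"] * 1.2 - features["b"]
        y = (rng.random(100) < 1 / (1 + np.exp(-eta))).astype(float)
        model1 = fit_logistic(features, y)
        scaled = features.assign(a=features["a"] * 1000.0)
        model2 = fit_logistic(scaled, y)
        p1 = epram_score(model1, features)
        p2 = epram_score(model2, scaled)
        np.testing.assert_allclose(p1, p2, atol=1e-6)
        lr1 = lr_test_drop_one(model1, features, y).set_index("feature")["lr_chisq"]
        lr2 = lr_test_drop_one(model2, scaled, y).set_index("feature")["lr_chisq"]
        np.testing.assert_allclose(lr1, lr2, atol=1e-5)


class TestSerialization:
    def test_round_trip_bit_for_bit_scores(self, rng):
        features = pd.DataFrame(rng.normal(size=(60, 2)), columns=["a", "b"])
        y = np.r_[np.ones(30), np.zeros(30)]
        model = fit_logistic(features, y)
        lr_test_drop_one(model, features, y)
        again = deserialize_model(serialize_model(model))
        s1 = epram_score(model, features)
        s2 = epram_score(again, features)
        assert (s1 == s2).all()
        assert again.lr_p == model.lr_p


class TestAdditionCheck:
    def test_redundant_feature_does_not_improve(self, rng):
        base = rng.normal(size=150)
        features = pd.DataFrame(
            {
                "signal": base,
                "copy": base + rng.normal(0, 0.1, 150),
                "noise": rng.normal(size=150),
            }
        )
        y = (rng.random(150) < 1 / (1 + np.exp(-2 * base))).astype(float)
        panel = fit_logistic(features[["signal"]], y)
        table = addition_check(panel, features, y).set_index("feature")
        assert not table.loc["noise", "improves"]
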