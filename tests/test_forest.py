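"""Forest engine: parameter resolution, OOB machinery, importance."""

import numpy as np
import pytest

from rfvarsel import (
    Dataset,
    RFParams,
    fit_forest,
    holdout_importance,
    oob_importance,
    resolve_params,
)

from conftest import make_classification, make_null_classification, make_regression


class TestResolveParams:
    @pytest.mark.parametrize(
        "mode, fraction, n, p, expected_mtry",
        [
            ("fraction", 0.33, 100, 5000, 1650),
            ("sqrt", None, 100, 100, 10),
            ("fraction", 0.33, 100, 1, 1),
        ],
    )
    def test_mtry_resolution(self, mode, fraction, n, p, expected_mtry):
        params = RFParams(mtry_mode=mode, mtry_fraction=fraction or 0.33)
        assert resolve_params(params, n, p).mtry == expected_mtry

    def test_nodesize_fraction(self):
        assert resolve_params(RFParams(), 100, 10).nodesize == 10

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError, match="mtry_fraction"):
            resolve_params(RFParams(mtry_fraction=1.5), 10, 10)

    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError):
            resolve_params(RFParams(), 0, 10)


class TestFitForest:
    def test_deterministic_oob_error(self):
        data = make_regression(seed=3)
        params = resolve_params(RFParams(ntree=100, seed=5), 60, 20)
        a = fit_forest(data, params)
        b = fit_forest(data, params)
        assert a.oob_error == b.oob_error

    def test_perfect_predictor_low_error(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(100, 10))
        y = (X[:, 0] > 0.5).astype(int)
        X[:, 3] = y  # outcome leaked as a predictor
        data = Dataset(X, y, [f"v{i}" for i in range(10)], "classification")
        fit = fit_forest(data, RFParams(ntree=200, nodesize=1, seed=1))
        assert fit.oob_error < 0.05

    def test_pure_noise_error_near_half(self):
        data = make_null_classification(n=100, p=20, seed=2)
        fit = fit_forest(data, RFParams(ntree=200, nodesize=1, seed=1))
        assert 0.4 <= fit.oob_error <= 0.6

    def test_oob_error_matches_sklearn(self):
        """Our bootstrap reconstruction must reproduce sklearn's own OOB score."""
        data = make_classification(n=80, p=10, seed=4)
        fit = fit_forest(data, RFParams(ntree=150, nodesize=1, seed=9))
        from sklearn.ensemble import RandomForestClassifier

        ref = RandomForestClassifier(
            n_estimators=150,
            max_features=fit.params.mtry,
            min_samples_leaf=1,
            oob_score=True,
            random_state=9,
            n_jobs=1,
        ).fit(data.X, data.y)
        assert fit.oob_error == pytest.approx(1.0 - ref.oob_score_, abs=1e-12)

    def test_every_row_oob_somewhere(self):
        data = make_regression(seed=1)
        fit = fit_forest(data, RFParams(ntree=50, seed=1))
        assert (fit.inbag_counts == 0).any(axis=0).all()

    def test_constant_regression_outcome_rejected(self):
        data = make_regression(seed=1)
        bad = Dataset(data.X, np.ones(data.n_individuals), data.var_names, "regression")
        with pytest.raises(ValueError, match="constant outcome"):
            fit_forest(bad, RFParams(ntree=10, seed=1))


class TestOOBImportance:
    def test_constant_variable_exactly_zero(self):
        data = make_regression(n=60, p=10, seed=5)
        X = data.X.copy()
        X[:, 7] = 0.5
        data = Dataset(X, data.y, data.var_names, "regression")
        fit = fit_forest(data, RFParams(ntree=100, seed=2))
        imp = oob_importance(fit, data)
        assert imp.values[7] == 0.0

    def test_outcome_copy_ranks_first(self):
        """A variable identical to y must beat every noise variable."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.uniform(size=(60, 15))
            y = (rng.random(60) > 0.5).astype(float)
            if len(np.unique(y)) < 2:
                y[0] = 1 - y[0]
            X[:, 4] = y
            data = Dataset(X, y.astype(int), [f"v{i}" for i in range(15)], "classification")
            fit = fit_forest(data, RFParams(ntree=100, nodesize=1, seed=seed))
            imp = oob_importance(fit, data)
            if np.argmax(imp.values) == 4 and (np.argsort(imp.values)[-1] == 4):
                wins += 1
        assert wins == 20

    def test_null_importance_mean_near_zero(self):
        values = []
        for seed in range(30):
            data = make_null_classification(n=50, p=10, seed=seed)
            fit = fit_forest(data, RFParams(ntree=100, nodesize=1, seed=seed))
            values.append(oob_importance(fit, data).values)
        assert abs(np.mean(values)) < 0.01

    def test_deterministic(self):
        data = make_regression(seed=8)
        params = resolve_params(RFParams(ntree=80, seed=3), 60, 20)
        a = oob_importance(fit_forest(data, params), data)
        b = oob_importance(fit_forest(data, params), data)
        assert np.array_equal(a.values, b.values)

    def test_redundant_copy_never_helps(self):
        """Adding a duplicate of an informative variable dilutes its importance."""
        diffs = []
        for seed in range(20):
            base = make_regression(n=60, p=10, strong=0, seed=seed)
            solo = oob_importance(
                fit_forest(base, RFParams(ntree=100, seed=seed)), base
            ).values[0]
            X_dup = np.hstack([base.X, base.X[:, [0]]])
            dup_data = Dataset(
                X_dup, base.y, base.var_names + ["v0_copy"], "regression"
            )
            dup = oob_importance(
                fit_forest(dup_data, RFParams(ntree=100, seed=seed)), dup_data
            ).values[0]
            diffs.append(solo - dup)
        assert np.mean(diffs) > 0


class TestHoldoutImportance:
    def test_deterministic_and_constant_zero(self):
        data = make_regression(n=60, p=10, seed=6)
        X = data.X.copy()
        X[:, 9] = 1.0
        data = Dataset(X, data.y, data.var_names, "regression")
        a = holdout_importance(data, RFParams(ntree=80), seed=11)
        b = holdout_importance(data, RFParams(ntree=80), seed=11)
        assert np.array_equal(a.values, b.values)
        assert a.values[9] == 0.0
        assert a.kind == "holdout"

    def test_needs_four_individuals(self):
        data = make_regression(n=60, p=5, seed=0)
        tiny = data.subset_rows(np.arange(3))
        with pytest.raises(ValueError, match="4 individuals"):
            holdout_importance(tiny, RFParams(ntree=10), seed=0)

    def test_stratification_failure(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(6, 4))
        y = np.array([0, 0, 0, 0, 0, 1])  # singleton class cannot appear in both halves
        data = Dataset(X, y, list("abcd"), "classification")
        with pytest.raises(ValueError, match="absent"):
            holdout_importance(data, RFParams(ntree=10), seed=0)

    def test_rank_agreement_with_oob(self):
        """Both importance flavours put a strong predictor first."""
        top = 0
        for seed in range(20):
            data = make_regression(n=80, p=12, strong=2, seed=seed)
            fit = fit_forest(data, RFParams(ntree=80, seed=seed))
            r_oob = np.argmax(oob_importance(fit, data).values)
            r_ho = np.argmax(
                holdout_importance(data, RFParams(ntree=80), seed=seed).values
            )
            top += int(r_oob == 2 and r_ho == 2)
        assert top >= 19
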