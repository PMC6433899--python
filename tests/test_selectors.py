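"""Selection procedures: decision rules, small end-to-end runs, invariants."""

import math

import numpy as np
import pandas as pd
import pytest

from rfvarsel import (
    Dataset,
    RFParams,
    select_altmann,
    select_boruta,
    select_perm,
    select_r2vim,
    select_rfe,
    select_vita,
)
from rfvarsel.selectors import (
    AltmannSelector,
    BorutaSelector,
    R2VIMSelector,
    RFESelector,
    VitaSelector,
    altmann_pvalues,
    boruta_decide,
    perm_pvalues,
    relative_importances,
    vita_pvalues,
)

from conftest import make_regression


# ---------------------------------------------------------------------------
# pure decision rules against brute-force oracles
# ---------------------------------------------------------------------------

def _binom_tail_ge(k, n):
    return sum(math.comb(n, i) for i in range(k, n + 1)) / 2**n


def _binom_tail_le(k, n):
    return sum(math.comb(n, i) for i in range(0, k + 1)) / 2**n


class TestBorutaDecisions:
    def test_single_run_all_tentative(self):
        out = boruta_decide([0, 1], n_runs=1, n_undecided=2, pvalue=0.01)
        assert list(out) == ["tentative", "tentative"]

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(0)
        for n_runs in (5, 10, 25):
            hits = rng.integers(0, n_runs + 1, size=5)
            got = boruta_decide(hits, n_runs, n_undecided=5, pvalue=0.05)
            for h, g in zip(hits, got):
                p_hi = min(1.0, _binom_tail_ge(int(h), n_runs) * 5)
                p_lo = min(1.0, _binom_tail_le(int(h), n_runs) * 5)
                expect = "tentative"
                if p_hi <= 0.05:
                    expect = "confirmed"
                if p_lo <= 0.05:
                    expect = "rejected"
                assert g == expect


class TestVitaPvalues:
    def test_mirroring_rule_hand_example(self):
        p = vita_pvalues([-0.2, 0.0, 0.3, 0.5])
        # null sample is {-0.2, 0, 0, 0.2}
        assert p[2] == 0.0 and p[3] == 0.0
        assert p[1] == pytest.approx(3 / 4)
        assert p[0] == pytest.approx(1.0)

    def test_all_nonpositive_selects_nothing(self):
        p = vita_pvalues([-1.0, -2.0, 0.0])
        assert (p > 0).all()

    def test_error_without_nonpositive_scores(self):
        with pytest.raises(ValueError, match="high-dimensional"):
            vita_pvalues([0.1, 0.2])


class TestRelativeImportances:
    def test_hand_example(self):
        rel = relative_importances([[6.0, -2.0, 1.0]])
        assert rel[0] == pytest.approx([3.0, -1.0, 0.5])

    def test_zero_min_falls_back_to_global_min(self):
        rel = relative_importances([[2.0, 0.0, 1.0], [4.0, -0.5, 1.0]])
        # first run's min is exactly 0 -> use |global min| = 0.5
        assert rel[0] == pytest.approx([4.0, 0.0, 2.0])
        assert rel[1] == pytest.approx([8.0, -1.0, 2.0])

    def test_all_zero_min_degenerate(self):
        with pytest.raises(ValueError, match="zero in every run"):
            relative_importances([[1.0, 0.0], [2.0, 0.0]])


class TestPermPvalues:
    def test_definitional_cases(self):
        null = np.array([[0.1, 0.5], [0.2, 0.6], [0.0, 0.7]])
        p = perm_pvalues([0.3, 0.6], null)
        assert p[0] == 0.0  # above all permutation values
        assert p[1] == pytest.approx(2 / 3)  # below its own permutation median

    def test_zero_attainable(self):
        assert perm_pvalues([1.0], [[0.5]])[0] == 0.0


class TestAltmannPvalues:
    def test_normal_mle_example(self):
        null = np.array([0.1, -0.1, 0.0, 0.2, -0.2]).reshape(-1, 1)
        p = altmann_pvalues([0.5], null)[0]
        # MLE: mean 0, sd sqrt(0.02) ~ 0.1414 -> z ~ 3.536
        assert p == pytest.approx(2.03e-4, rel=0.05)

    def test_equal_to_null_mean_gives_half(self):
        null = np.array([0.1, -0.1, 0.3, -0.3]).reshape(-1, 1)
        assert altmann_pvalues([0.0], null)[0] == pytest.approx(0.5)

    def test_degenerate_zero_variance(self):
        null = np.zeros((5, 2))
        p = altmann_pvalues([0.1, -0.1], null)
        assert p[0] == 0.0 and p[1] == 1.0

    def test_far_tail_underflows_to_zero(self):
        null = np.array([0.0, 0.001, -0.001, 0.0005, -0.0005]).reshape(-1, 1)
        assert altmann_pvalues([1.0], null)[0] == 0.0


# ---------------------------------------------------------------------------
# end-to-end selector behaviour on small data
# ---------------------------------------------------------------------------

def _leak_dataset(n=100, p=50, seed=0, leak=13):
    rng = np.random.default_rng(seed)
    X = rng.uniform(size=(n, p))
    y = np.repeat([0, 1], n // 2)
    y = rng.permutation(y)
    X[:, leak] = y  # outcome leaked into one column
    return Dataset(X, y, [f"v{i}" for i in range(p)], "classification")


class TestBorutaSelector:
    def test_confirms_outcome_copy(self):
        for seed in (1, 2):
            data = _leak_dataset(seed=seed)
            res = select_boruta(
                data, RFParams(ntree=200, seed=seed), random_state=seed, max_runs=30
            )
            assert "v13" in res.selected
            assert res.diagnostics.loc["v13", "status"] == "confirmed"

    def test_single_run_everything_tentative(self):
        data = _leak_dataset(seed=5)
        with pytest.warns(UserWarning, match="tentative"):
            res = select_boruta(
                data, RFParams(ntree=100, seed=5), random_state=5, max_runs=1
            )
        assert res.selected == []
        assert set(res.diagnostics["status"]) == {"tentative"}
        assert res.n_forests_trained == 1

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            BorutaSelector(ntree=10).fit(np.empty((10, 0)), np.repeat([0, 1], 5))


class TestVitaSelector:
    def test_selects_strong_predictor(self):
        data = make_regression(n=80, p=40, strong=3, seed=2)
        res = select_vita(data, RFParams(ntree=200, seed=2), random_state=2)
        assert "v3" in res.selected
        assert res.n_forests_trained == 2

    def test_monotone_in_threshold(self):
        data = make_regression(n=80, p=40, strong=3, seed=4)
        lo = select_vita(data, RFParams(ntree=100, seed=4), random_state=4,
                         p_threshold=0.0)
        hi = select_vita(data, RFParams(ntree=100, seed=4), random_state=4,
                         p_threshold=0.2)
        assert lo.selected_set <= hi.selected_set


class TestR2VIMSelector:
    def test_selects_strong_predictor_and_counts_forests(self):
        data = make_regression(n=80, p=30, strong=1, seed=3)
        res = select_r2vim(data, RFParams(ntree=150, seed=3), random_state=3, n_runs=5)
        assert "v1" in res.selected
        assert res.n_forests_trained == 5

    def test_monotone_in_factor(self):
        data = make_regression(n=80, p=30, strong=1, seed=6)
        strict = select_r2vim(data, RFParams(ntree=100, seed=6), random_state=6,
                              n_runs=3, factor=5.0)
        loose = select_r2vim(data, RFParams(ntree=100, seed=6), random_state=6,
                             n_runs=3, factor=2.0)
        assert strict.selected_set <= loose.selected_set


class TestPermAndAltmannSelectors:
    def test_leaked_outcome_selected(self):
        data = _leak_dataset(n=80, p=30, seed=7)
        rf = RFParams(ntree=100, seed=7)
        res_p = select_perm(data, rf, random_state=7, n_permutations=20)
        res_a = select_altmann(data, rf, random_state=7, n_permutations=20)
        assert "v13" in res_p.selected
        assert "v13" in res_a.selected
        assert res_p.n_forests_trained == 21
        assert res_a.n_forests_trained == 21

    def test_monotone_in_threshold(self):
        data = make_regression(n=60, p=20, seed=9)
        rf = RFParams(ntree=80, seed=9)
        lo = select_perm(data, rf, random_state=9, n_permutations=10, p_threshold=0.0)
        hi = select_perm(data, rf, random_state=9, n_permutations=10, p_threshold=0.3)
        assert lo.selected_set <= hi.selected_set


class TestRFESelector:
    def test_keeps_perfect_predictor_small_set(self):
        for seed in (1, 2, 3):
            data = _leak_dataset(n=80, p=10, seed=seed, leak=4)
            res = select_rfe(data, RFParams(ntree=150, seed=seed), random_state=seed)
            assert "v4" in res.selected
            assert len(res.selected) <= 5

    def test_step_sizes_follow_removal_fraction(self):
        data = make_regression(n=50, p=20, seed=5)
        res = select_rfe(data, RFParams(ntree=50, seed=5), random_state=5,
                         prop_remove=0.1)
        sizes = [s[0] for s in res.config["steps"]]
        assert sizes[0] == 20 and sizes[1] == 18  # floor(0.1 * 20) = 2 removed
        assert sizes[-1] == 1
        assert res.n_forests_trained == len(sizes)

    def test_zero_tolerance_returns_error_minimiser(self):
        data = make_regression(n=50, p=15, seed=8)
        res = select_rfe(data, RFParams(ntree=50, seed=8), random_state=8, tol_pct=0.0)
        assert res.config["chosen_error"] == res.config["min_error"]


class TestSelectorInvariants:
    def test_constant_column_never_selected(self):
        data = make_regression(n=60, p=15, strong=0, seed=11)
        X = np.hstack([data.X, np.full((60, 1), 2.5)])
        data = Dataset(X, data.y, data.var_names + ["const"], "regression")
        rf = RFParams(ntree=100, seed=11)
        for select, kwargs in (
            (select_vita, {}),
            (select_r2vim, {"n_runs": 5}),
            (select_boruta, {"max_runs": 25}),
        ):
            res = select(data, rf, random_state=11, **kwargs)
            assert "const" not in res.selected_set

    def test_diagnostics_cover_all_variables(self):
        data = make_regression(n=60, p=12, seed=13)
        res = select_vita(data, RFParams(ntree=80, seed=13), random_state=13)
        assert list(res.diagnostics.index) == data.var_names

    def test_sklearn_estimator_api(self):
        data = make_regression(n=60, p=12, strong=2, seed=14)
        frame = pd.DataFrame(data.X, columns=data.var_names)
        est = VitaSelector(ntree=100, random_state=14)
        est.fit(frame, data.y)
        assert est.support_.shape == (12,)
        assert est.get_support().dtype == bool
        reduced = est.transform(frame)
        assert reduced.shape[1] == len(est.selected_)
        assert "v2" in est.selected_
        params = est.get_params()
        assert params["ntree"] == 100
        clone_like = VitaSelector(**params)
        assert clone_like.get_params() == params
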