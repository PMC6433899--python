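"""Six random-forest variable-selection procedures.

Five of them aim at *all relevant* variables — every variable carrying
information about the outcome, including redundant correlated ones:

* :class:`BorutaSelector` — shadow-variable testing over repeated forests,
* :class:`VitaSelector` — empirical null from mirrored non-positive
  hold-out importances,
* :class:`R2VIMSelector` — recurrent relative importance over several runs,
* :class:`PermSelector` — nonparametric outcome-permutation test,
* :class:`AltmannSelector` — its parametric (normal-fit) variant.

:class:`RFESelector` instead searches for a *minimal* well-predicting set
by recursive feature elimination.

All are scikit-learn transformers (``fit``/``transform``/``get_support``)
and also accept a :class:`~rfvarsel.datatypes.Dataset` through
``select``, which preserves variable names. The ``select_*`` module
functions are thin wrappers over the estimators.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .datatypes import CLASSIFICATION, REGRESSION, Dataset, SelectionResult
from .forest import (
    RFParams,
    fit_forest,
    holdout_importance,
    oob_importance,
    resolve_params,
)

_SEED_MASK = 0x7FFFFFFF

# spawn-key namespaces so that different methods sharing one random_state
# still consume independent streams
_METHOD_KEY = {"boruta": 1, "vita": 2, "r2vim": 3, "perm": 4, "altmann": 5, "rfe": 6}


# ---------------------------------------------------------------------------
# pure decision rules (testable without training any forest)
# ---------------------------------------------------------------------------

def boruta_decide(hits, n_runs: int, n_undecided: int, pvalue: float):
    """Classify variables from shadow-comparison hit counts.

    Each undecided variable has scored ``hits`` successes ("importance
    above the best shadow") in ``n_runs`` independent runs. Under the null
    the hit count is Binomial(n_runs, 1/2); a one-sided tail in each
    direction, Bonferroni-corrected across the ``n_undecided`` variables
    still in play, confirms or rejects at level ``pvalue``.
    """
    hits = np.asarray(hits)
    p_hi = stats.binom.sf(hits - 1, n_runs, 0.5)
    p_lo = stats.binom.cdf(hits, n_runs, 0.5)
    out = np.full(hits.shape, "tentative", dtype=object)
    out[np.minimum(p_hi * n_undecided, 1.0) <= pvalue] = "confirmed"
    out[np.minimum(p_lo * n_undecided, 1.0) <= pvalue] = "rejected"
    return out


def vita_pvalues(importances) -> np.ndarray:
    """Empirical p-values from the mirrored non-positive importance null.

    The non-positive hold-out importance scores, together with their
    mirror images around zero, form a symmetric empirical null; each
    variable's p-value is the fraction of null values >= its score
    (so p = 0 means strictly above every null value).
    """
    imp = np.asarray(importances, dtype=np.float64)
    nonpos = imp[imp <= 0]
    if nonpos.size == 0:
        raise ValueError(
            "no non-positive importance scores: the mirrored-null approach "
            "is only applicable in the setting of high-dimensional data "
            "sets with many uninformative variables"
        )
    null = np.sort(np.concatenate([nonpos, -nonpos]))
    n = null.size
    return (n - np.searchsorted(null, imp, side="left")) / n


def perm_pvalues(original, null_matrix) -> np.ndarray:
    """Per-variable empirical p: fraction of permutation-run importances
    that reach the original importance. Uses r/N (not (r+1)/(N+1)) so
    p = 0 is attainable, which the p-threshold-0 default requires."""
    original = np.asarray(original)
    null = np.asarray(null_matrix)
    return np.mean(null >= original[None, :], axis=0)


def altmann_pvalues(original, null_matrix) -> np.ndarray:
    """Parametric p-values from a per-variable normal fit to the null.

    Mean and standard deviation are the maximum-likelihood estimates
    (N denominator); p is the upper-tail probability of the original
    importance. A zero-variance null degenerates to p = 0 if the original
    exceeds the null mean and 1 otherwise.
    """
    original = np.asarray(original, dtype=np.float64)
    null = np.asarray(null_matrix, dtype=np.float64)
    mu = null.mean(axis=0)
    sd = np.sqrt(np.mean((null - mu[None, :]) ** 2, axis=0))
    p = np.where(original > mu, 0.0, 1.0)
    ok = sd > 0
    p[ok] = stats.norm.sf(original[ok], loc=mu[ok], scale=sd[ok])
    return p


def relative_importances(importance_matrix) -> np.ndarray:
    """r2VIM relative importances, run by run.

    Each run's scores are divided by the absolute value of that run's
    minimal importance; a run whose minimum is exactly zero falls back to
    the minimal importance observed over all runs.
    """
    M = np.asarray(importance_matrix, dtype=np.float64)
    mins = M.min(axis=1)
    global_min = mins.min()
    if np.all(mins == 0):
        raise ValueError(
            "minimal importance is zero in every run: null scale cannot "
            "be estimated (degenerate data)"
        )
    denom = np.where(mins != 0, np.abs(mins), np.abs(global_min))
    return M / denom[:, None]


# ---------------------------------------------------------------------------
# shared machinery
# ---------------------------------------------------------------------------

def permutation_null_importances(
    data: Dataset, params: RFParams, n_perm: int, seed: int
):
    """Original OOB importance plus ``n_perm`` outcome-permutation nulls.

    Each permutation run shuffles the outcome, trains a fresh forest and
    computes OOB importance; the null matrix has one row per run. Perm and
    Altmann share this machinery (and in a benchmark, its output).
    """
    seed = int(seed) & _SEED_MASK
    ss = np.random.SeedSequence(seed, spawn_key=(0xC3,))
    state = ss.generate_state(n_perm + 1) & _SEED_MASK
    params = resolve_params(params, data.n_individuals, data.n_variables)
    from dataclasses import replace

    fit = fit_forest(data, replace(params, seed=int(state[0])))
    original = oob_importance(fit, data)
    perm_rng = np.random.default_rng(ss.spawn(1)[0])
    null = np.empty((n_perm, data.n_variables))
    for k in range(n_perm):
        y_perm = perm_rng.permutation(data.y)
        d_perm = Dataset(data.X, y_perm, data.var_names, data.task)
        fit_k = fit_forest(d_perm, replace(params, seed=int(state[k + 1])))
        null[k] = oob_importance(fit_k, d_perm).values
    return original, null


def _order_by(names: Sequence[str], score: np.ndarray, mask: np.ndarray) -> list:
    idx = np.flatnonzero(mask)
    return [names[i] for i in idx[np.argsort(-score[idx], kind="stable")]]


def _diagnostics(
    names,
    importance,
    selected_mask,
    p_value=None,
    relative_importance=None,
    status=None,
) -> pd.DataFrame:
    n = len(names)
    return pd.DataFrame(
        {
            "importance": np.asarray(importance, dtype=float),
            "p_value": np.full(n, np.nan) if p_value is None else p_value,
            "relative_importance": (
                np.full(n, np.nan)
                if relative_importance is None
                else relative_importance
            ),
            "status": ["" for _ in range(n)] if status is None else list(status),
            "selected": np.asarray(selected_mask, dtype=int),
        },
        index=pd.Index(names, name="variable"),
    )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class BaseRFSelector(SelectorMixin, BaseEstimator):
    """Common scaffolding: RF parameterization, task inference, fit plumbing.

    ``task="auto"`` treats an outcome with exactly two distinct values as
    classification and anything else as regression; pass the task
    explicitly for a binary-valued regression target.
    """

    _method = "base"

    def __init__(
        self,
        ntree=10_000,
        mtry_mode="fraction",
        mtry_fraction=0.33,
        nodesize=None,
        nodesize_fraction=0.10,
        task="auto",
        random_state=0,
    ):
        self.ntree = ntree
        self.mtry_mode = mtry_mode
        self.mtry_fraction = mtry_fraction
        self.nodesize = nodesize
        self.nodesize_fraction = nodesize_fraction
        self.task = task
        self.random_state = random_state

    # -- sklearn surface ----------------------------------------------------
    def fit(self, X, y):
        X_arr, y_arr = validate_data(self, X, y, dtype=np.float64)
        names = getattr(self, "feature_names_in_", None)
        if names is None:
            names = [f"V{i + 1}" for i in range(X_arr.shape[1])]
        task = self._resolve_task(y_arr)
        data = Dataset(X_arr, y_arr, list(names), task)
        result = self._run(data)
        self._set_fitted(data, result)
        return self

    def select(self, data: Dataset) -> SelectionResult:
        """Run on a named :class:`Dataset`; also leaves the estimator fitted."""
        result = self._run(data)
        self.n_features_in_ = data.n_variables
        self._set_fitted(data, result)
        return result

    def _set_fitted(self, data: Dataset, result: SelectionResult) -> None:
        chosen = result.selected_set
        self.support_ = np.array([v in chosen for v in data.var_names])
        self.selected_ = list(result.selected)
        self.diagnostics_ = result.diagnostics
        self.n_forests_trained_ = result.n_forests_trained
        self.result_ = result

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def _resolve_task(self, y) -> str:
        if self.task in (CLASSIFICATION, REGRESSION):
            return self.task
        if self.task != "auto":
            raise ValueError(f"unknown task {self.task!r}")
        return CLASSIFICATION if len(np.unique(y)) == 2 else REGRESSION

    # -- RF plumbing --------------------------------------------------------
    def _nodesize_for(self, task: str):
        return self.nodesize

    def _rf_template(self, task: str, seed: int) -> RFParams:
        return RFParams(
            ntree=self.ntree,
            mtry_mode=self.mtry_mode,
            mtry_fraction=self.mtry_fraction,
            nodesize=self._nodesize_for(task),
            nodesize_fraction=self.nodesize_fraction,
            seed=int(seed) & _SEED_MASK,
        )

    def _seed_state(self, n: int) -> np.ndarray:
        ss = np.random.SeedSequence(
            int(self.random_state) & _SEED_MASK,
            spawn_key=(_METHOD_KEY.get(self._method, 0),),
        )
        return ss.generate_state(n) & _SEED_MASK

    def _run(self, data: Dataset) -> SelectionResult:  # pragma: no cover
        raise NotImplementedError


class BorutaSelector(BaseRFSelector):
    """All-relevant selection by comparison with shadow variables.

    In every run each undecided variable gets a shadow copy whose values
    are freshly permuted across observations; a run counts as a hit for a
    variable when its OOB importance exceeds the best shadow importance.
    Binomial tests on the hit counts (Bonferroni-corrected across the
    undecided variables) confirm or reject variables at level ``pvalue``;
    rejected variables and all shadows are dropped and the procedure
    repeats until everything is classified or ``max_runs`` is reached.

    Defaults follow the method's reference implementation: mtry = sqrt(p)
    and terminal nodes of 1 (classification) / 5 (regression).
    """

    _method = "boruta"

    def __init__(
        self,
        pvalue=0.01,
        max_runs=100,
        ntree=10_000,
        mtry_mode="sqrt",
        mtry_fraction=0.33,
        nodesize=None,
        nodesize_fraction=0.10,
        task="auto",
        random_state=0,
    ):
        super().__init__(
            ntree=ntree,
            mtry_mode=mtry_mode,
            mtry_fraction=mtry_fraction,
            nodesize=nodesize,
            nodesize_fraction=nodesize_fraction,
            task=task,
            random_state=random_state,
        )
        self.pvalue = pvalue
        self.max_runs = max_runs

    def _nodesize_for(self, task: str):
        if self.nodesize is not None:
            return self.nodesize
        return 1 if task == CLASSIFICATION else 5

    def _run(self, data: Dataset) -> SelectionResult:
        if data.n_variables == 0:
            raise ValueError("no variables to select from")
        names = list(data.var_names)
        n = data.n_individuals
        undecided = list(names)
        confirmed: list = []
        rejected: list = []
        hits = dict.fromkeys(names, 0)
        last_p = dict.fromkeys(names, np.nan)
        imp_sum = dict.fromkeys(names, 0.0)
        imp_runs = dict.fromkeys(names, 0)
        col = {v: i for i, v in enumerate(names)}

        ss = np.random.SeedSequence(
            int(self.random_state) & _SEED_MASK, spawn_key=(_METHOD_KEY["boruta"],)
        )
        state = ss.generate_state(2 * self.max_runs) & _SEED_MASK
        shadow_rng = np.random.default_rng(ss.spawn(1)[0])

        runs = 0
        while undecided and runs < self.max_runs:
            runs += 1
            active = confirmed + undecided
            X_active = data.X[:, [col[v] for v in active]]
            X_und = data.X[:, [col[v] for v in undecided]]
            perm = np.argsort(shadow_rng.random((n, len(undecided))), axis=0)
            shadows = X_und[perm, np.arange(len(undecided))]
            X_run = np.hstack([X_active, shadows])
            run_names = active + [f"__shadow_{v}" for v in undecided]
            d_run = Dataset(X_run, data.y, run_names, data.task)
            params = resolve_params(
                self._rf_template(data.task, state[2 * runs - 2]),
                d_run.n_individuals,
                d_run.n_variables,
            )
            fit = fit_forest(d_run, params)
            imp = oob_importance(fit, d_run, seed=int(state[2 * runs - 1]))
            n_active = len(active)
            shadow_max = imp.values[n_active:].max()
            real_imp = dict(zip(active, imp.values[:n_active]))
            for v in undecided:
                if real_imp[v] > shadow_max:
                    hits[v] += 1
            for v in active:
                imp_sum[v] += real_imp[v]
                imp_runs[v] += 1

            hit_counts = np.array([hits[v] for v in undecided])
            decisions = boruta_decide(hit_counts, runs, len(undecided), self.pvalue)
            p_hi = stats.binom.sf(hit_counts - 1, runs, 0.5)
            for v, p in zip(undecided, p_hi):
                last_p[v] = p
            still = []
            for v, d in zip(undecided, decisions):
                if d == "confirmed":
                    confirmed.append(v)
                elif d == "rejected":
                    rejected.append(v)
                else:
                    still.append(v)
            undecided = still

        if undecided:
            warnings.warn(
                f"Boruta stopped after {runs} runs with "
                f"{len(undecided)} tentative variables",
                stacklevel=2,
            )
        status = {v: "confirmed" for v in confirmed}
        status.update({v: "rejected" for v in rejected})
        status.update({v: "tentative" for v in undecided})
        mean_imp = np.array(
            [imp_sum[v] / imp_runs[v] if imp_runs[v] else 0.0 for v in names]
        )
        mask = np.array([status[v] == "confirmed" for v in names])
        diagnostics = _diagnostics(
            names,
            mean_imp,
            mask,
            p_value=np.array([min(1.0, last_p[v]) if np.isfinite(last_p[v]) else np.nan for v in names]),
            status=[status[v] for v in names],
        )
        return SelectionResult(
            selected=_order_by(names, mean_imp, mask),
            diagnostics=diagnostics,
            method="boruta",
            config={
                "pvalue": self.pvalue,
                "max_runs": self.max_runs,
                "ntree": self.ntree,
                "runs": runs,
            },
            n_forests_trained=runs,
        )


class VitaSelector(BaseRFSelector):
    """All-relevant selection from the hold-out importance null.

    Computes hold-out permutation importance once (two forests, each
    scored on the opposite half of the data) and forms an empirical null
    that is symmetric around zero by mirroring the non-positive scores.
    Variables whose empirical p-value is at most ``p_threshold`` (default
    0: strictly above every null value) are selected.
    """

    _method = "vita"

    def __init__(
        self,
        p_threshold=0.0,
        ntree=10_000,
        mtry_mode="fraction",
        mtry_fraction=0.33,
        nodesize=None,
        nodesize_fraction=0.10,
        task="auto",
        random_state=0,
    ):
        super().__init__(
            ntree=ntree,
            mtry_mode=mtry_mode,
            mtry_fraction=mtry_fraction,
            nodesize=nodesize,
            nodesize_fraction=nodesize_fraction,
            task=task,
            random_state=random_state,
        )
        self.p_threshold = p_threshold

    def _run(self, data: Dataset) -> SelectionResult:
        seed = int(self._seed_state(1)[0])
        imp = holdout_importance(data, self._rf_template(data.task, seed), seed)
        p = vita_pvalues(imp.values)
        mask = p <= self.p_threshold
        diagnostics = _diagnostics(data.var_names, imp.values, mask, p_value=p)
        return SelectionResult(
            selected=_order_by(list(data.var_names), imp.values, mask),
            diagnostics=diagnostics,
            method="vita",
            config={"p_threshold": self.p_threshold, "ntree": self.ntree},
            n_forests_trained=2,
        )


class R2VIMSelector(BaseRFSelector):
    """All-relevant selection by recurrent relative importance.

    Trains ``n_runs`` forests differing only in their random seed; each
    run's importances are scaled by the absolute value of the run's
    minimal importance (an estimate of the null scale). A variable is
    selected when its smallest relative importance over runs is at least
    ``factor``.
    """

    _method = "r2vim"

    def __init__(
        self,
        n_runs=20,
        factor=3.0,
        ntree=10_000,
        mtry_mode="fraction",
        mtry_fraction=0.33,
        nodesize=None,
        nodesize_fraction=0.10,
        task="auto",
        random_state=0,
    ):
        super().__init__(
            ntree=ntree,
            mtry_mode=mtry_mode,
            mtry_fraction=mtry_fraction,
            nodesize=nodesize,
            nodesize_fraction=nodesize_fraction,
            task=task,
            random_state=random_state,
        )
        self.n_runs = n_runs
        self.factor = factor

    def _run(self, data: Dataset) -> SelectionResult:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        state = self._seed_state(2 * self.n_runs)
        M = np.empty((self.n_runs, data.n_variables))
        for k in range(self.n_runs):
            from dataclasses import replace

            params = self._rf_template(data.task, state[2 * k])
            fit = fit_forest(data, params)
            M[k] = oob_importance(fit, data, seed=int(state[2 * k + 1])).values
        rel = relative_importances(M)
        min_rel = rel.min(axis=0)
        mask = min_rel >= self.factor
        diagnostics = _diagnostics(
            data.var_names, M.mean(axis=0), mask, relative_importance=min_rel
        )
        return SelectionResult(
            selected=_order_by(list(data.var_names), min_rel, mask),
            diagnostics=diagnostics,
            method="r2vim",
            config={"n_runs": self.n_runs, "factor": self.factor, "ntree": self.ntree},
            n_forests_trained=self.n_runs,
        )


class PermSelector(BaseRFSelector):
    """All-relevant selection by an outcome-permutation test.

    The outcome is permuted ``n_permutations`` times; each permutation
    trains a fresh forest, giving every variable its own null sample of
    importances. Variables whose empirical p-value (fraction of null
    importances reaching the original) is at most ``p_threshold`` are
    selected — at the default threshold 0 this selects variables whose
    original importance beats all of their permutation importances.
    """

    _method = "perm"

    def __init__(
        self,
        n_permutations=500,
        p_threshold=0.0,
        ntree=10_000,
        mtry_mode="fraction",
        mtry_fraction=0.33,
        nodesize=None,
        nodesize_fraction=0.10,
        task="auto",
        random_state=0,
    ):
        super().__init__(
            ntree=ntree,
            mtry_mode=mtry_mode,
            mtry_fraction=mtry_fraction,
            nodesize=nodesize,
            nodesize_fraction=nodesize_fraction,
            task=task,
            random_state=random_state,
        )
        self.n_permutations = n_permutations
        self.p_threshold = p_threshold

    def _run(self, data: Dataset) -> SelectionResult:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        seed = int(self._seed_state(1)[0])
        original, null = permutation_null_importances(
            data, self._rf_template(data.task, seed), self.n_permutations, seed
        )
        return perm_result_from_null(
            original.values,
            null,
            list(data.var_names),
            p_threshold=self.p_threshold,
            config={"n_permutations": self.n_permutations, "ntree": self.ntree},
        )


class AltmannSelector(BaseRFSelector):
    """Parametric variant of the permutation test.

    Uses the same outcome-permutation null as :class:`PermSelector` but
    fits a normal distribution per variable by maximum likelihood and
    takes the upper-tail probability of the original importance as
    p-value, so far fewer permutations are needed (default 50). At the
    default threshold 0, selection requires the tail probability to
    underflow to exactly zero in double precision (z above roughly 39).
    """

    _method = "altmann"

    def __init__(
        self,
        n_permutations=50,
        p_threshold=0.0,
        ntree=10_000,
        mtry_mode="fraction",
        mtry_fraction=0.33,
        nodesize=None,
        nodesize_fraction=0.10,
        task="auto",
        random_state=0,
    ):
        super().__init__(
            ntree=ntree,
            mtry_mode=mtry_mode,
            mtry_fraction=mtry_fraction,
            nodesize=nodesize,
            nodesize_fraction=nodesize_fraction,
            task=task,
            random_state=random_state,
        )
        self.n_permutations = n_permutations
        self.p_threshold = p_threshold

    def _run(self, data: Dataset) -> SelectionResult:
        if self.n_permutations < 2:
            raise ValueError("the normal fit needs at least 2 permutations")
        seed = int(self._seed_state(1)[0])
        original, null = permutation_null_importances(
            data, self._rf_template(data.task, seed), self.n_permutations, seed
        )
        return altmann_result_from_null(
            original.values,
            null,
            list(data.var_names),
            p_threshold=self.p_threshold,
            config={"n_permutations": self.n_permutations, "ntree": self.ntree},
        )


class RFESelector(BaseRFSelector):
    """Minimal-set selection by recursive feature elimination.

    Repeatedly fits a forest, records its OOB error, and removes the
    ``prop_remove`` least important fraction of the remaining variables
    (importance re-computed at every step) until one variable is left.
    The smallest variable set whose OOB error is within ``tol_pct`` percent
    of the minimal error over all steps is returned.
    """

    _method = "rfe"

    def __init__(
        self,
        prop_remove=0.1,
        tol_pct=10.0,
        ntree=10_000,
        mtry_mode="fraction",
        mtry_fraction=0.33,
        nodesize=None,
        nodesize_fraction=0.10,
        task="auto",
        random_state=0,
    ):
        super().__init__(
            ntree=ntree,
            mtry_mode=mtry_mode,
            mtry_fraction=mtry_fraction,
            nodesize=nodesize,
            nodesize_fraction=nodesize_fraction,
            task=task,
            random_state=random_state,
        )
        self.prop_remove = prop_remove
        self.tol_pct = tol_pct

    def _run(self, data: Dataset) -> SelectionResult:
        if not 0 < self.prop_remove < 1:
            raise ValueError("prop_remove must be in (0, 1)")
        if self.tol_pct < 0:
            raise ValueError("tol_pct must be >= 0")
        names = list(data.var_names)
        col = {v: i for i, v in enumerate(names)}
        current = list(names)
        state = self._seed_state(2 * (data.n_variables + 1))
        steps = []  # (variable list, oob_error, importance dict)
        removal_imp = dict.fromkeys(names, np.nan)
        k = 0
        while True:
            sub = Dataset(
                data.X[:, [col[v] for v in current]], data.y, current, data.task
            )
            params = resolve_params(
                self._rf_template(data.task, state[2 * k]),
                sub.n_individuals,
                sub.n_variables,
            )
            fit = fit_forest(sub, params)
            imp = oob_importance(fit, sub, seed=int(state[2 * k + 1]))
            steps.append((list(current), fit.oob_error, dict(zip(current, imp.values))))
            if len(current) == 1:
                break
            n_drop = max(1, math.floor(self.prop_remove * len(current)))
            order = np.argsort(imp.values, kind="stable")
            dropped = [current[i] for i in order[:n_drop]]
            for v in dropped:
                removal_imp[v] = steps[-1][2][v]
            current = [v for v in current if v not in set(dropped)]
            k += 1

        errors = np.array([s[1] for s in steps])
        best = errors.min()
        tol = best * (1 + self.tol_pct / 100.0)
        chosen_idx = max(i for i, e in enumerate(errors) if e <= tol)
        chosen_vars, chosen_err, chosen_imp = steps[chosen_idx]
        mask = np.array([v in set(chosen_vars) for v in names])
        final_imp = np.array(
            [chosen_imp.get(v, removal_imp[v]) for v in names], dtype=float
        )
        diagnostics = _diagnostics(names, final_imp, mask)
        selected = sorted(chosen_vars, key=lambda v: -chosen_imp[v])
        return SelectionResult(
            selected=selected,
            diagnostics=diagnostics,
            method="rfe",
            config={
                "prop_remove": self.prop_remove,
                "tol_pct": self.tol_pct,
                "ntree": self.ntree,
                "steps": [(len(s[0]), float(s[1])) for s in steps],
                "chosen_error": float(chosen_err),
                "min_error": float(best),
            },
            n_forests_trained=len(steps),
        )


# ---------------------------------------------------------------------------
# results from precomputed permutation nulls (shared by Perm and Altmann)
# ---------------------------------------------------------------------------

def perm_result_from_null(
    original, null, var_names, p_threshold=0.0, config=None
) -> SelectionResult:
    p = perm_pvalues(original, null)
    mask = p <= p_threshold
    diagnostics = _diagnostics(var_names, original, mask, p_value=p)
    return SelectionResult(
        selected=_order_by(var_names, np.asarray(original), mask),
        diagnostics=diagnostics,
        method="perm",
        config={"p_threshold": p_threshold, **(config or {})},
        n_forests_trained=np.asarray(null).shape[0] + 1,
    )


def altmann_result_from_null(
    original, null, var_names, p_threshold=0.0, config=None
) -> SelectionResult:
    p = altmann_pvalues(original, null)
    mask = p <= p_threshold
    diagnostics = _diagnostics(var_names, original, mask, p_value=p)
    return SelectionResult(
        selected=_order_by(var_names, np.asarray(original), mask),
        diagnostics=diagnostics,
        method="altmann",
        config={"p_threshold": p_threshold, **(config or {})},
        n_forests_trained=np.asarray(null).shape[0] + 1,
    )


# ---------------------------------------------------------------------------
# function wrappers over the estimators
# ---------------------------------------------------------------------------

_SELECTOR_CLASSES = {
    "boruta": BorutaSelector,
    "vita": VitaSelector,
    "r2vim": R2VIMSelector,
    "perm": PermSelector,
    "altmann": AltmannSelector,
    "rfe": RFESelector,
}


def make_selector(method: str, rf: Optional[RFParams] = None, **cfg) -> BaseRFSelector:
    """Instantiate a selector estimator from RF parameters plus method config."""
    if method not in _SELECTOR_CLASSES:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_SELECTOR_CLASSES)}")
    kwargs = dict(cfg)
    if rf is not None:
        kwargs.setdefault("ntree", rf.ntree)
        kwargs.setdefault("random_state", rf.seed)
        if method != "boruta":  # Boruta keeps its own sqrt-mtry defaults
            kwargs.setdefault("mtry_mode", rf.mtry_mode)
            kwargs.setdefault("mtry_fraction", rf.mtry_fraction)
            kwargs.setdefault("nodesize", rf.nodesize)
            kwargs.setdefault("nodesize_fraction", rf.nodesize_fraction)
    return _SELECTOR_CLASSES[method](**kwargs)


def _select(method, data, rf=None, **cfg) -> SelectionResult:
    est = make_selector(method, rf, task=data.task, **cfg)
    return est.select(data)


def select_boruta(data, rf=None, **cfg):
    return _select("boruta", data, rf, **cfg)


def select_vita(data, rf=None, **cfg):
    return _select("vita", data, rf, **cfg)


def select_r2vim(data, rf=None, **cfg):
    return _select("r2vim", data, rf, **cfg)


def select_perm(data, rf=None, **cfg):
    return _select("perm", data, rf, **cfg)


def select_altmann(data, rf=None, **cfg):
    return _select("altmann", data, rf, **cfg)


def select_rfe(data, rf=None, **cfg):
    return _select("rfe", data, rf, **cfg)
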