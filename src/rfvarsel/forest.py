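"""Random-forest training and permutation variable importance.

Forests are grown with scikit-learn; everything the selection methods
consume on top — per-tree bootstrap bookkeeping, out-of-bag (OOB) error,
OOB permutation importance and the hold-out (half-split) importance
variant — is computed here from the fitted tree structures.

Importance is the raw (unscaled) mean decrease in prediction performance
after permuting one variable's values on a tree's evaluation rows,
averaged over trees: accuracy for classification, negative mean squared
error for regression, so relevant variables score positive either way.
The Z-score-scaled variant is deliberately not offered; its null
distribution is not normal, which would invalidate the parametric
(Altmann) p-values downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from ._trees import (
    predict_leaf,
    tree_arrays,
    tree_permutation_drops,
    used_features,
)
from .datatypes import CLASSIFICATION, Dataset, ImportanceVector

_SEED_MASK = 0x7FFFFFFF


@dataclass
class RFParams:
    """Forest hyperparameters, possibly given as fractions.

    ``mtry_mode="fraction"`` resolves mtry to ``round(mtry_fraction * p)``;
    ``"sqrt"`` to ``floor(sqrt(p))``. ``nodesize`` (minimal terminal-node
    size) resolves to ``round(nodesize_fraction * n)`` unless given as an
    absolute integer. Benchmark defaults: 33% of variables per split and
    10% of the sample size per terminal node.
    """

    ntree: int = 10_000
    mtry_mode: str = "fraction"
    mtry_fraction: float = 0.33
    mtry: Optional[int] = None
    nodesize_fraction: float = 0.10
    nodesize: Optional[int] = None
    seed: int = 0

    def is_resolved(self) -> bool:
        return self.mtry is not None and self.nodesize is not None


def resolve_params(params: RFParams, n_individuals: int, n_variables: int) -> RFParams:
    """Resolve fractional mtry / nodesize to integers for a given shape."""
    if n_individuals <= 0 or n_variables <= 0:
        raise ValueError("counts must be positive")
    if params.ntree < 1:
        raise ValueError("ntree must be >= 1")
    if params.mtry is not None:
        mtry = int(params.mtry)
    elif params.mtry_mode == "fraction":
        if not 0 < params.mtry_fraction <= 1:
            raise ValueError("mtry_fraction must be in (0, 1]")
        mtry = max(1, round(params.mtry_fraction * n_variables))
    elif params.mtry_mode == "sqrt":
        mtry = max(1, math.floor(math.sqrt(n_variables)))
    else:
        raise ValueError(f"unknown mtry_mode {params.mtry_mode!r}")
    if not 0 < mtry <= n_variables:
        raise ValueError(f"resolved mtry {mtry} outside (0, {n_variables}]")
    if params.nodesize is not None:
        nodesize = int(params.nodesize)
    else:
        if not 0 < params.nodesize_fraction <= 1:
            raise ValueError("nodesize_fraction must be in (0, 1]")
        nodesize = max(1, round(params.nodesize_fraction * n_individuals))
    if nodesize < 1:
        raise ValueError("nodesize must be >= 1")
    return replace(params, mtry=mtry, nodesize=nodesize)


@dataclass
class ForestFit:
    """A trained forest plus the bootstrap bookkeeping needed for OOB work."""

    params: RFParams
    forest: object
    inbag_counts: np.ndarray  # (ntree, n) bootstrap multiplicities
    oob_error: float
    task: str

    _arrays: Optional[list] = None

    def tree_structures(self) -> list:
        if self._arrays is None:
            self._arrays = [tree_arrays(est) for est in self.forest.estimators_]
        return self._arrays

    def encode_y(self, y: np.ndarray) -> np.ndarray:
        if self.task == CLASSIFICATION:
            return np.searchsorted(self.forest.classes_, y)
        return np.asarray(y, dtype=np.float64)


def _inbag_counts(forest, n: int) -> np.ndarray:
    # sklearn draws each tree's bootstrap as RandomState(tree_seed).randint(0, n, n);
    # reconstructing it gives exact per-tree in-bag multiplicities.
    counts = np.empty((len(forest.estimators_), n), dtype=np.int32)
    for t, est in enumerate(forest.estimators_):
        idx = np.random.RandomState(est.random_state).randint(0, n, n)
        counts[t] = np.bincount(idx, minlength=n)
    return counts


def fit_forest(data: Dataset, params: RFParams) -> ForestFit:
    """Train a forest and compute its OOB error.

    Bootstrap samples of size n are drawn with replacement; splits use the
    Gini index (classification) or variance reduction (regression). The
    OOB error is the misclassification rate / mean squared error of the
    OOB-aggregated predictions.
    """
    params = params if params.is_resolved() else resolve_params(
        params, data.n_individuals, data.n_variables
    )
    if data.task == CLASSIFICATION:
        if len(np.unique(data.y)) < 2:
            raise ValueError("classification outcome has a single class")
        cls = RandomForestClassifier
    else:
        if np.ptp(data.y) == 0:
            raise ValueError("constant outcome: regression forest is degenerate")
        cls = RandomForestRegressor
    forest = cls(
        n_estimators=params.ntree,
        max_features=params.mtry,
        min_samples_leaf=params.nodesize,
        bootstrap=True,
        random_state=int(params.seed) & _SEED_MASK,
        n_jobs=1,
    ).fit(data.X, data.y)
    fit = ForestFit(
        params=params,
        forest=forest,
        inbag_counts=_inbag_counts(forest, data.n_individuals),
        oob_error=np.nan,
        task=data.task,
    )
    fit.oob_error = _oob_error(fit, data)
    return fit


def _oob_error(fit: ForestFit, data: Dataset) -> float:
    n = data.n_individuals
    arrays = fit.tree_structures()
    oob = fit.inbag_counts == 0
    if fit.task == CLASSIFICATION:
        proba = np.zeros((n, len(fit.forest.classes_)))
    else:
        proba = np.zeros(n)
    n_trees_per_row = np.zeros(n, dtype=np.int64)
    for t, arr in enumerate(arrays):
        rows = np.flatnonzero(oob[t])
        if rows.size == 0:
            continue
        leaves = predict_leaf(arr, data.X, rows)
        proba[rows] += arr[4][leaves]
        n_trees_per_row[rows] += 1
    covered = n_trees_per_row > 0
    if not covered.any():
        return float("nan")
    if fit.task == CLASSIFICATION:
        pred = np.argmax(proba[covered], axis=1)
        truth = fit.encode_y(data.y)[covered]
        return float(np.mean(pred != truth))
    pred = proba[covered] / n_trees_per_row[covered]
    return float(np.mean((pred - data.y[covered]) ** 2))


def _permutation_importance(
    arrays_list, inbag_counts, X, y_enc, task, rng
) -> np.ndarray:
    """Mean per-tree performance drop after permuting each variable.

    ``inbag_counts`` restricts each tree to its OOB rows; pass ``None`` to
    evaluate every tree on all rows (the hold-out variant). Trees without
    evaluation rows are skipped; a variable unused by a tree contributes
    exactly zero for that tree, and one fresh permutation is drawn per
    tree and variable.
    """
    p = X.shape[1]
    sums = np.zeros(p)
    n_contrib = 0
    all_rows = np.arange(X.shape[0])
    for t, arr in enumerate(arrays_list):
        if inbag_counts is not None:
            rows = np.flatnonzero(inbag_counts[t] == 0)
            if rows.size == 0:
                continue
        else:
            rows = all_rows
        variables = used_features(arr)
        if variables.size:
            drops = tree_permutation_drops(
                arr, X, rows, y_enc[rows], task, variables, rng
            )
            sums[variables] += drops
        n_contrib += 1
    if n_contrib == 0:
        raise ValueError("no tree had evaluation rows")
    return sums / n_contrib


def oob_importance(
    fit: ForestFit, data: Dataset, seed: Optional[int] = None
) -> ImportanceVector:
    """OOB permutation importance of every variable of ``data``.

    For each tree, performance on the tree's OOB rows is compared before
    and after permuting a variable's OOB values; differences are averaged
    over trees.
    """
    run_seed = int(fit.params.seed if seed is None else seed) & _SEED_MASK
    rng = np.random.default_rng(np.random.SeedSequence(run_seed, spawn_key=(0xA1,)))
    values = _permutation_importance(
        fit.tree_structures(),
        fit.inbag_counts,
        data.X,
        fit.encode_y(data.y),
        data.task,
        rng,
    )
    return ImportanceVector(values, data.var_names, kind="oob", run_seed=run_seed)


def _stratified_halves(data: Dataset, rng) -> tuple:
    n = data.n_individuals
    if n < 4:
        raise ValueError("hold-out importance needs at least 4 individuals")
    if data.task == CLASSIFICATION:
        half_a = []
        for level in np.unique(data.y):
            idx = np.flatnonzero(data.y == level)
            idx = rng.permutation(idx)
            half_a.extend(idx[: idx.size // 2])
        half_a = np.sort(np.asarray(half_a))
    else:
        idx = rng.permutation(n)
        half_a = np.sort(idx[: n // 2])
    half_b = np.setdiff1d(np.arange(n), half_a)
    if data.task == CLASSIFICATION:
        for half in (half_a, half_b):
            if len(np.unique(data.y[half])) < 2:
                raise ValueError("a class is absent from one half of the split")
    return half_a, half_b


def holdout_importance(
    data: Dataset, params: RFParams, seed: int
) -> ImportanceVector:
    """Hold-out (half-split) permutation importance.

    The data are split once into two equal halves (stratified by class for
    classification); a forest trained on each half is scored by
    permutation importance on the other, independent half, and the two
    per-variable scores are averaged. Unlike the OOB variant, the null
    distribution of these scores is symmetric around zero, which is what
    the Vita selector exploits.
    """
    seed = int(seed) & _SEED_MASK
    ss = np.random.SeedSequence(seed, spawn_key=(0xB2,))
    split_rng = np.random.default_rng(ss.spawn(1)[0])
    half_a, half_b = _stratified_halves(data, split_rng)
    scores = []
    for k, (train, heldout) in enumerate(((half_a, half_b), (half_b, half_a))):
        sub = data.subset_rows(train)
        fit_params = resolve_params(
            replace(params, mtry=None if params.mtry is None else params.mtry,
                    seed=int(ss.generate_state(2)[k]) & _SEED_MASK),
            sub.n_individuals,
            sub.n_variables,
        )
        fit = fit_forest(sub, fit_params)
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(0xB2, 0x10 + k))
        )
        scores.append(
            _permutation_importance(
                fit.tree_structures(),
                None,
                data.X[heldout],
                fit.encode_y(data.y[heldout]),
                data.task,
                rng,
            )
        )
    values = (scores[0] + scores[1]) / 2.0
    return ImportanceVector(values, data.var_names, kind="holdout", run_seed=seed)
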