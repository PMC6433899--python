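"""Evaluation criteria and the benchmark orchestrator.

Per-replicate criteria: false discovery rate (false positives among the
selected variables), sensitivity (recovered fraction of the causal set),
and a downstream prediction error from a forest refit on the selected
variables only (RMSE for regression, misclassification rate for
classification). Across replicates: per-variable empirical power and
pairwise selection stability via the Jaccard index (optionally the
modified variant dividing by the smaller set size).

Conventions, chosen where the criteria are undefined: the FDR of an empty
selection is 0 (no discovery, no false discovery), and the Jaccard index
of two empty sets is 1 (identical selections). Under a null model (empty
truth) sensitivity is undefined and the falsely-selected count is
reported instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import CLASSIFICATION, Dataset, ReplicateSet, SelectionResult
from .forest import RFParams, fit_forest, resolve_params
from .selectors import (
    altmann_result_from_null,
    make_selector,
    perm_result_from_null,
    permutation_null_importances,
)

logger = logging.getLogger("rfvarsel")


def fdr(selected: set, truth: set) -> float:
    """Fraction of selected variables that are not causal (0 if none selected)."""
    selected = set(selected)
    if not selected:
        return 0.0
    return len(selected - set(truth)) / len(selected)


def sensitivity(selected: set, truth: set) -> float:
    """Fraction of causal variables recovered. Undefined for empty truth."""
    truth = set(truth)
    if not truth:
        raise ValueError(
            "sensitivity is undefined for an empty causal set; report the "
            "falsely-selected count under a null model instead"
        )
    return len(set(selected) & truth) / len(truth)


def empirical_power(selections: Sequence[set], truth: set) -> pd.Series:
    """Per causal variable, the fraction of replicates selecting it."""
    if not selections:
        raise ValueError("at least one selection is required")
    truth = sorted(truth)
    counts = np.zeros(len(truth))
    for sel in selections:
        sel = set(sel)
        counts += np.array([v in sel for v in truth], dtype=float)
    return pd.Series(counts / len(selections), index=truth, name="power")


def jaccard(a: set, b: set, modified: bool = False) -> float:
    """Jaccard index of two selections; ``modified`` divides by min size.

    Two empty sets count as perfectly stable (index 1).
    """
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    inter = len(a & b)
    denom = min(len(a), len(b)) if modified else len(a | b)
    if denom == 0:  # one empty, one not
        return 0.0
    return inter / denom


def jaccard_stability(selections: Sequence[set], modified: bool = False) -> float:
    """Mean Jaccard index over all unordered pairs of selections."""
    if len(selections) < 2:
        raise ValueError("stability needs at least 2 selection sets")
    vals = [jaccard(a, b, modified) for a, b in combinations(selections, 2)]
    return float(np.mean(vals))


def downstream_error(
    train: Dataset,
    test: Dataset,
    selected: Sequence[str],
    params: RFParams,
) -> float:
    """Prediction error of a forest refit on the selected variables only.

    Trains on ``train`` restricted to ``selected`` and scores ``test``:
    RMSE for regression, misclassification rate for classification. An
    empty selection falls back to the trivial predictor (outcome mean or
    majority class) as a baseline.
    """
    if train.var_names != test.var_names:
        raise ValueError("train and test replicates must share variable names")
    if train.task != test.task:
        raise ValueError("train and test tasks differ")
    selected = list(selected)
    if not selected:
        logger.warning("empty selection: reporting baseline predictor error")
        if train.task == CLASSIFICATION:
            levels, counts = np.unique(train.y, return_counts=True)
            majority = levels[np.argmax(counts)]
            return float(np.mean(test.y != majority))
        return float(np.sqrt(np.mean((test.y - train.y.mean()) ** 2)))
    sub_train = train.subset_variables(selected)
    sub_test = test.subset_variables(selected)
    fit = fit_forest(
        sub_train,
        resolve_params(params, sub_train.n_individuals, sub_train.n_variables),
    )
    pred = fit.forest.predict(sub_test.X)
    if train.task == CLASSIFICATION:
        return float(np.mean(pred != sub_test.y))
    return float(np.sqrt(np.mean((pred - sub_test.y) ** 2)))


@dataclass
class EvalReport:
    """Benchmark output: tidy per-replicate records plus aggregates."""

    records: pd.DataFrame
    power: pd.DataFrame
    stability: pd.DataFrame
    summary: pd.DataFrame
    selections: Dict[str, List[set]]

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / "records.tsv", sep="\t", index=False)
        self.power.to_csv(outdir / "power.tsv", sep="\t")
        self.stability.to_csv(outdir / "stability.tsv", sep="\t", index=False)
        self.summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)


def _iqr(x: pd.Series) -> float:
    x = x.dropna()
    if x.empty:
        return float("nan")
    return float(np.percentile(x, 75) - np.percentile(x, 25))


def run_selectors_on_replicate(
    data: Dataset,
    methods: Sequence[str],
    rf: RFParams,
    cfgs: Optional[dict] = None,
    seed: int = 0,
) -> Dict[str, SelectionResult]:
    """Run several selectors on one replicate.

    When both ``perm`` and ``altmann`` are requested with the same number
    of permutations, the outcome-permutation forests are trained once and
    both results are derived from the shared null.
    """
    cfgs = cfgs or {}
    results: Dict[str, SelectionResult] = {}
    todo = list(methods)
    perm_cfg = dict(cfgs.get("perm", {}))
    alt_cfg = dict(cfgs.get("altmann", {}))
    if (
        "perm" in todo
        and "altmann" in todo
        and perm_cfg.get("n_permutations", 500) == alt_cfg.get("n_permutations", 50)
    ):
        n_perm = perm_cfg.get("n_permutations", 500)
        base = replace(rf, seed=int(seed) & 0x7FFFFFFF)
        original, null = permutation_null_importances(data, base, n_perm, seed)
        results["perm"] = perm_result_from_null(
            original.values, null, list(data.var_names),
            p_threshold=perm_cfg.get("p_threshold", 0.0),
            config={"n_permutations": n_perm, "ntree": rf.ntree},
        )
        results["altmann"] = altmann_result_from_null(
            original.values, null, list(data.var_names),
            p_threshold=alt_cfg.get("p_threshold", 0.0),
            config={"n_permutations": n_perm, "ntree": rf.ntree},
        )
        todo = [m for m in todo if m not in ("perm", "altmann")]
    for method in todo:
        cfg = dict(cfgs.get(method, {}))
        cfg.setdefault("random_state", seed)
        est = make_selector(method, replace(rf, seed=int(seed) & 0x7FFFFFFF),
                            task=data.task, **cfg)
        results[method] = est.select(data)
    return results


def run_benchmark(
    replicates: ReplicateSet,
    methods: Sequence[str],
    rf: RFParams,
    cfgs: Optional[dict] = None,
    pairing_mode: str = "independent",
    test_replicates: Optional[ReplicateSet] = None,
    seed: int = 0,
) -> EvalReport:
    """Select and evaluate each method on each replicate.

    ``independent`` mode evaluates prediction error against the
    same-index replicate of ``test_replicates`` (if given); ``paired``
    mode cross-evaluates within consecutive pairs and requires an even
    replicate count. A method failing on a replicate is logged and
    recorded as missing; the remaining replicates continue.
    """
    if pairing_mode not in ("independent", "paired"):
        raise ValueError("pairing_mode must be 'independent' or 'paired'")
    if pairing_mode == "paired" and len(replicates) % 2 != 0:
        raise ValueError("paired mode needs an even number of replicates")
    truth = replicates.truth_names
    # per-replicate seeds derive from the replicate's content, not its
    # position, so aggregates are invariant to replicate ordering
    import zlib

    seed_state = [
        (zlib.crc32(rep.X.tobytes()) ^ (int(seed) & 0x7FFFFFFF)) & 0x7FFFFFFF
        for rep in replicates.replicates
    ]

    rows = []
    selections: Dict[str, List[Optional[set]]] = {m: [] for m in methods}
    for r, data in enumerate(replicates.replicates):
        try:
            results = run_selectors_on_replicate(
                data, methods, rf, cfgs, seed=int(seed_state[r])
            )
        except Exception:
            logger.exception("selection failed on replicate %d", r)
            for m in methods:
                selections[m].append(None)
            continue
        for m in methods:
            res = results[m]
            sel = res.selected_set
            selections[m].append(sel)
            row = {
                "method": m,
                "replicate": r,
                "n_selected": len(sel),
                "n_forests_trained": res.n_forests_trained,
            }
            if truth:
                row["fdr"] = fdr(sel, truth)
                row["sensitivity"] = sensitivity(sel, truth)
            else:
                row["false_selected"] = len(sel)
            rows.append(row)

    records = pd.DataFrame(rows)

    # prediction error
    err_rows = []
    if pairing_mode == "independent" and test_replicates is not None:
        for r, data in enumerate(replicates.replicates):
            if r >= len(test_replicates):
                break
            for m in methods:
                sel = selections[m][r]
                if sel is None:
                    continue
                err_rows.append(
                    {
                        "method": m,
                        "replicate": r,
                        "error": downstream_error(
                            data, test_replicates.replicates[r], sorted(sel), rf
                        ),
                        "baseline": len(sel) == 0,
                    }
                )
    elif pairing_mode == "paired":
        for a in range(0, len(replicates), 2):
            b = a + 1
            for m in methods:
                sa, sb = selections[m][a], selections[m][b]
                if sa is None or sb is None:
                    continue
                e_ab = downstream_error(
                    replicates.replicates[a], replicates.replicates[b], sorted(sa), rf
                )
                e_ba = downstream_error(
                    replicates.replicates[b], replicates.replicates[a], sorted(sb), rf
                )
                # the pair's mean cross-evaluation error sits on its first replicate
                err_rows.append(
                    {
                        "method": m,
                        "replicate": a,
                        "error": (e_ab + e_ba) / 2.0,
                        "baseline": len(sa) == 0 or len(sb) == 0,
                    }
                )
    if err_rows:
        records = records.merge(
            pd.DataFrame(err_rows)[["method", "replicate", "error"]],
            on=["method", "replicate"],
            how="left",
        )

    # stability + power across replicates
    stab_rows, power_frames = [], {}
    for m in methods:
        ok = [s for s in selections[m] if s is not None]
        if len(ok) >= 2:
            stab_rows.append(
                {
                    "method": m,
                    "jaccard": jaccard_stability(ok, modified=False),
                    "jaccard_modified": jaccard_stability(ok, modified=True),
                }
            )
        if truth and ok:
            power_frames[m] = empirical_power(ok, truth)
    stability = pd.DataFrame(stab_rows)
    power = pd.DataFrame(power_frames)

    # aggregate medians and IQRs per method
    metrics = [c for c in ("fdr", "sensitivity", "false_selected", "n_selected", "error")
               if c in records.columns]
    summary_rows = []
    for m in methods:
        sub = records[records["method"] == m]
        row = {"method": m}
        for c in metrics:
            row[f"{c}_median"] = float(sub[c].median()) if not sub.empty else float("nan")
            row[f"{c}_iqr"] = _iqr(sub[c]) if not sub.empty else float("nan")
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)

    return EvalReport(
        records=records,
        power=power,
        stability=stability,
        summary=summary,
        selections={m: [s if s is not None else set() for s in selections[m]]
                    for m in methods},
    )
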