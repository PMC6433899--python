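"""Core containers shared across the package.

A :class:`Dataset` is an individuals-by-variables matrix with a single
outcome (binary label for classification, real-valued for regression).
Selection procedures return a :class:`SelectionResult`; importance
computations return an :class:`ImportanceVector`; the simulators return a
:class:`ReplicateSet` carrying ground-truth causal labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

CLASSIFICATION = "classification"
REGRESSION = "regression"


@dataclass
class Dataset:
    """Feature matrix plus outcome.

    Parameters
    ----------
    X : ndarray of shape (n_individuals, n_variables)
        Real-valued predictor matrix, no missing values.
    y : ndarray of shape (n_individuals,)
        Outcome; exactly two distinct levels for classification, real
        values for regression.
    var_names : sequence of str
        Unique variable identifiers, one per column.
    task : {"classification", "regression"}
    """

    X: np.ndarray
    y: np.ndarray
    var_names: Sequence[str]
    task: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        self.var_names = list(map(str, self.var_names))
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n, p = self.X.shape
        if n < 2:
            raise ValueError("at least 2 individuals are required")
        if len(self.y) != n:
            raise ValueError(f"outcome length {len(self.y)} != {n} rows of X")
        if len(self.var_names) != p:
            raise ValueError("var_names length must equal the number of columns")
        if len(set(self.var_names)) != p:
            raise ValueError("var_names must be unique")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains missing or non-finite values")
        if self.task not in (CLASSIFICATION, REGRESSION):
            raise ValueError(f"unknown task {self.task!r}")
        if self.task == CLASSIFICATION:
            if len(np.unique(self.y)) != 2:
                raise ValueError("classification outcome must have exactly 2 levels")
        else:
            self.y = self.y.astype(np.float64)
            if not np.isfinite(self.y).all():
                raise ValueError("y contains missing or non-finite values")

    @property
    def n_individuals(self) -> int:
        return self.X.shape[0]

    @property
    def n_variables(self) -> int:
        return self.X.shape[1]

    def subset_variables(self, names: Sequence[str]) -> "Dataset":
        """Return a dataset restricted to ``names`` (in the given order)."""
        index = {v: i for i, v in enumerate(self.var_names)}
        missing = [v for v in names if v not in index]
        if missing:
            raise KeyError(f"unknown variables: {missing[:5]}")
        cols = [index[v] for v in names]
        return Dataset(self.X[:, cols], self.y, list(names), self.task)

    def subset_rows(self, rows: np.ndarray) -> "Dataset":
        return Dataset(self.X[rows], self.y[rows], self.var_names, self.task)


@dataclass
class ImportanceVector:
    """Per-variable permutation importance with provenance."""

    values: np.ndarray
    var_names: Sequence[str]
    kind: str  # "oob" or "holdout"
    run_seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != len(self.var_names):
            raise ValueError("values and var_names must align")
        if not np.isfinite(self.values).all():
            raise ValueError("importance values must be finite")
        if self.kind not in ("oob", "holdout"):
            raise ValueError(f"unknown importance kind {self.kind!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": list(self.var_names),
                "importance": self.values,
                "kind": self.kind,
                "seed": self.run_seed,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SelectionResult:
    """Outcome of one variable-selection procedure.

    ``selected`` is ordered by decreasing evidence (method-specific score).
    ``diagnostics`` has one row per input variable with columns
    ``importance``, ``p_value``, ``relative_importance``, ``status`` and
    ``selected``.
    """

    selected: list
    diagnostics: pd.DataFrame
    method: str
    config: dict
    n_forests_trained: int

    def __post_init__(self) -> None:
        missing = set(self.selected) - set(self.diagnostics.index)
        if missing:
            raise ValueError(f"selected variables missing from diagnostics: {missing}")
        pv = self.diagnostics.get("p_value")
        if pv is not None:
            ok = pv.dropna().between(0.0, 1.0).all()
            if not ok:
                raise ValueError("p-values must lie in [0, 1]")

    @property
    def selected_set(self) -> set:
        return set(self.selected)

    def to_tsv(self, path) -> None:
        out = self.diagnostics.copy()
        out.insert(0, "variable", out.index)
        out.to_csv(path, sep="\t", index=False)

    def meta(self) -> dict:
        return {
            "method": self.method,
            "config": _jsonable(self.config),
            "n_forests_trained": int(self.n_forests_trained),
            "n_selected": len(self.selected),
        }

    def write(self, outdir, stem: Optional[str] = None) -> None:
        """Write ``<stem>.tsv`` (diagnostics) and ``<stem>.json`` (metadata)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stem = stem or self.method
        self.to_tsv(outdir / f"{stem}.tsv")
        (outdir / f"{stem}.json").write_text(json.dumps(self.meta(), indent=2))


@dataclass
class ReplicateSet:
    """Simulated replicates plus ground truth.

    ``truth`` maps each causal variable name to an annotation (group label
    for the correlated-groups design, numeric effect size for the
    multivariate-normal design). ``pairing`` assigns a pair index per
    replicate when replicates are simulated in pairs.
    """

    replicates: list = field(default_factory=list)
    truth: dict = field(default_factory=dict)
    pairing: Optional[list] = None

    def __post_init__(self) -> None:
        if self.replicates:
            names = self.replicates[0].var_names
            for rep in self.replicates[1:]:
                if rep.var_names != names:
                    raise ValueError("replicates must share identical var_names")
            unknown = set(self.truth) - set(names)
            if unknown:
                raise ValueError(f"truth names not among variables: {sorted(unknown)[:5]}")
        if self.pairing is not None and len(self.pairing) != len(self.replicates):
            raise ValueError("pairing must have one entry per replicate")

    @property
    def truth_names(self) -> set:
        return set(self.truth)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variable": list(self.truth), "effect": list(self.truth.values())}
        )

    def __len__(self) -> int:
        return len(self.replicates)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
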