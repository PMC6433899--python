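"""Tabular readers/writers and generic preprocessing transforms.

Datasets travel as delimited text: a feature table with a header row of
variable names (TSV or CSV by extension) and the outcome either as a
named column of that table or as a separate single-column file.

The preprocessing transforms are the generic ones used for omics
predictor matrices: quartile binning of per-variable values into four
ordinal groups (methylation beta values), per-variable standardization to
mean 0 / sd 1 (cross-platform expression comparison) and the log2(x+1)
count transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CLASSIFICATION, REGRESSION, Dataset

logger = logging.getLogger("rfvarsel")


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_dataset(path_X, path_y=None, task=REGRESSION, outcome_column=None) -> Dataset:
    """Read a dataset from delimited text.

    ``path_X`` must have a header row of unique variable names. The
    outcome comes either from ``outcome_column`` of the same table or
    from ``path_y``, a single-column file (with or without a header).
    """
    path_X = Path(path_X)
    try:
        X = pd.read_csv(path_X, sep=_sep_for(path_X))
    except pd.errors.ParserError as exc:
        raise ValueError(f"cannot parse {path_X}: {exc}") from exc
    if outcome_column is not None:
        if outcome_column not in X.columns:
            raise ValueError(f"outcome column {outcome_column!r} not in {path_X}")
        y = X.pop(outcome_column).to_numpy()
    elif path_y is not None:
        y_frame = pd.read_csv(path_y, sep=_sep_for(path_y))
        if y_frame.shape[1] != 1:
            raise ValueError(f"{path_y} must contain exactly one column")
        y = y_frame.iloc[:, 0].to_numpy()
    else:
        raise ValueError("provide either path_y or outcome_column")
    bad = X.columns[X.isna().any()]
    if len(bad):
        row = int(X[bad[0]].isna().idxmax())
        raise ValueError(f"missing value in column {bad[0]!r}, row {row}")
    non_numeric = [c for c in X.columns if not np.issubdtype(X[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric predictor columns: {non_numeric[:5]}")
    if task == CLASSIFICATION and len(pd.unique(y)) != 2:
        raise ValueError(
            f"classification outcome must have 2 levels, found {len(pd.unique(y))}"
        )
    return Dataset(X.to_numpy(dtype=np.float64), y, list(X.columns), task)


def write_dataset(data: Dataset, path_X, path_y) -> None:
    frame = pd.DataFrame(data.X, columns=list(data.var_names))
    frame.to_csv(path_X, sep=_sep_for(path_X), index=False)
    pd.DataFrame({"outcome": data.y}).to_csv(path_y, sep=_sep_for(path_y), index=False)


def quartile_bin(values) -> np.ndarray:
    """Bin values into four ordinal groups {1, 2, 3, 4} by their quartiles.

    Cut points are the linearly interpolated quartiles; bins are
    lower-closed (ties fall in the lower bin), so the map is monotone. A
    constant vector maps to all 1 with a warning.
    """
    values = np.asarray(values, dtype=np.float64)
    if np.ptp(values) == 0:
        warnings.warn("constant vector: all values assigned to bin 1", stacklevel=2)
        return np.ones(values.shape, dtype=np.int64)
    q1, q2, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return 1 + (values > q1).astype(np.int64) + (values > q2) + (values > q3)


def standardize(values) -> np.ndarray:
    """Center to mean 0 and scale to (population) standard deviation 1."""
    values = np.asarray(values, dtype=np.float64)
    sd = values.std()  # N denominator, matching the normal MLE convention
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (values - values.mean()) / sd


def log2p1(values) -> np.ndarray:
    """log2(x + 1) transform for non-negative counts."""
    values = np.asarray(values, dtype=np.float64)
    if (values < 0).any():
        raise ValueError("log2(x + 1) requires non-negative values")
    return np.log2(values + 1.0)


@dataclass
class RunConfig:
    """A full run description: forest defaults plus per-method settings.

    Loaded from YAML/JSON of the form::

        rf: {ntree: 500, mtry_fraction: 0.33, nodesize_fraction: 0.10}
        boruta: {pvalue: 0.01, max_runs: 100}
        perm: {n_permutations: 500}
        seed: 1
        out_dir: results/
        n_workers: 1

    Results are independent of ``n_workers``: every forest and
    permutation stream is seeded per task, never per worker.
    """

    rf: dict = field(default_factory=dict)
    selectors: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."
    n_workers: int = 1

    _METHODS = ("boruta", "vita", "r2vim", "perm", "altmann", "rfe")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        selectors = {m: raw.pop(m) for m in cls._METHODS if m in raw}
        return cls(
            rf=raw.pop("rf", {}),
            selectors=selectors,
            simulation=raw.pop("simulation", {}),
            seed=int(raw.pop("seed", 0)),
            out_dir=str(raw.pop("out_dir", ".")),
            n_workers=int(raw.pop("n_workers", 1)),
        )

    def rf_params(self):
        from .forest import RFParams

        return RFParams(**self.rf, seed=self.seed)


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
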