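"""Synthetic benchmark data generators with known causal structure.

Two designs are provided. The correlated-groups design
(:func:`simulate_sim1`) is a nonlinear regression problem: six latent
uniform base variables each spawn a group of noisy copies with
within-group correlation decaying along the group, the quantitative
outcome depends nonlinearly on the first three base variables (so groups
1-3 are causal and groups 4-6 are correlated decoys), and the remaining
predictors are independent uniform noise. A null variant makes the
outcome independent of every predictor.

The multivariate-normal design (:func:`simulate_sim2`) is a
classification problem emulating gene-expression data: predictors are
drawn from a zero-mean MVN with a user-supplied covariance (or the
block-exchangeable stand-in from :func:`standin_covariance`), and a
random subset of variables gets a mean shift per class, 25 variables for
each effect size in {-3, -2, -1, -0.5, 0.5, 1, 2, 3}. Replicates come in
pairs sharing identical causal variables and effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datatypes import CLASSIFICATION, REGRESSION, Dataset, ReplicateSet

_SEED_MASK = 0x7FFFFFFF


@dataclass
class Sim1Config:
    """Correlated-groups regression design.

    ``group_size`` copies per latent base variable (6 groups), noise
    multiplier c_j = 0.01 + 0.5 (j-1)/(group_size-1) scaling N(0, 0.3)
    draws, outcome noise N(0, 0.2). ``null_model=True`` decouples the
    outcome from all predictors (truth is empty).
    """

    group_size: int = 10
    n_individuals: int = 100
    n_total_vars: int = 5000
    noise_sd_outcome: float = 0.2
    noise_sd_group: float = 0.3
    null_model: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_size < 2:
            raise ValueError("group_size must be >= 2 (noise multiplier needs j-1 over group_size-1)")
        if 6 * self.group_size > self.n_total_vars:
            raise ValueError("n_total_vars must be at least 6 * group_size")
        if self.noise_sd_outcome <= 0 or self.noise_sd_group <= 0:
            raise ValueError("noise standard deviations must be positive")


@dataclass
class Sim2Config:
    """Multivariate-normal classification design (paired replicates)."""

    covariance: np.ndarray = None
    n_individuals: int = 200
    effect_sizes: Sequence[float] = (-3, -2, -1, -0.5, 0.5, 1, 2, 3)
    n_causal_per_effect: int = 25
    n_pairs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.covariance is None:
            raise ValueError("a covariance matrix is required (see standin_covariance)")
        self.covariance = np.asarray(self.covariance, dtype=np.float64)
        p = self.covariance.shape[0]
        if self.covariance.shape != (p, p):
            raise ValueError("covariance must be square")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        n_causal = len(self.effect_sizes) * self.n_causal_per_effect
        if n_causal > p:
            raise ValueError(
                f"{n_causal} causal variables do not fit into {p} predictors"
            )
        if self.n_individuals % 2 != 0:
            raise ValueError("n_individuals must be even (balanced classes)")


def sim1_response(x1, x2, x3):
    """Noise-free nonlinear response of the correlated-groups design."""
    return 0.25 * np.exp(4 * np.asarray(x1)) + 4 / (
        1 + np.exp(-20 * (np.asarray(x2) - 0.5))
    ) + 3 * np.asarray(x3)


def sim1_group_noise_multiplier(j: int, group_size: int) -> float:
    """c_j = 0.01 + 0.5 (j-1)/(n-1): scales the N(0, 0.3) group noise."""
    return 0.01 + 0.5 * (j - 1) / (group_size - 1)


def sim1_var_names(cfg: Sim1Config) -> list:
    names = [
        f"g{i}_v{j:03d}"
        for i in range(1, 7)
        for j in range(1, cfg.group_size + 1)
    ]
    names += [f"noise_{k:05d}" for k in range(1, cfg.n_total_vars - 6 * cfg.group_size + 1)]
    return names


def simulate_sim1(cfg: Sim1Config, n_replicates: int = 1) -> ReplicateSet:
    """Simulate ``n_replicates`` correlated-groups regression replicates.

    The latent base variables x1..x6 are not included as predictors; the
    causal truth is groups 1-3 (3 * group_size variables) in the effect
    model and empty under the null model, where the outcome is the sum of
    three independent N(0, 0.2) draws.
    """
    names = sim1_var_names(cfg)
    gs = cfg.group_size
    c = np.array([sim1_group_noise_multiplier(j, gs) for j in range(1, gs + 1)])
    children = np.random.SeedSequence(int(cfg.seed) & _SEED_MASK).spawn(n_replicates)
    replicates = []
    for child in children:
        rng = np.random.default_rng(child)
        n = cfg.n_individuals
        x = rng.uniform(size=(n, 6))
        groups = x[:, :, None] + c[None, None, :] * rng.normal(
            scale=cfg.noise_sd_group, size=(n, 6, gs)
        )
        noise = rng.uniform(size=(n, cfg.n_total_vars - 6 * gs))
        X = np.hstack([groups.reshape(n, 6 * gs), noise])
        if cfg.null_model:
            y = rng.normal(scale=cfg.noise_sd_outcome, size=(n, 3)).sum(axis=1)
        else:
            y = sim1_response(x[:, 0], x[:, 1], x[:, 2]) + rng.normal(
                scale=cfg.noise_sd_outcome, size=n
            )
        replicates.append(Dataset(X, y, names, REGRESSION))
    truth = {} if cfg.null_model else {
        f"g{i}_v{j:03d}": f"group{i}"
        for i in (1, 2, 3)
        for j in range(1, gs + 1)
    }
    return ReplicateSet(replicates=replicates, truth=truth)


def standin_covariance(
    p: int,
    block_sizes: Sequence[int],
    within_block_corr: float,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Block-diagonal exchangeable-correlation matrix with unit variances.

    A stand-in for a covariance estimated from real expression data:
    variables within a block share correlation ``within_block_corr``,
    blocks are independent. Positive semi-definite by construction. The
    construction is deterministic; ``seed`` is accepted for interface
    uniformity with the samplers and ignored.
    """
    if not 0 <= within_block_corr < 1:
        raise ValueError("within_block_corr must be in [0, 1)")
    if sum(block_sizes) != p:
        raise ValueError(f"block sizes sum to {sum(block_sizes)}, expected {p}")
    cov = np.zeros((p, p))
    start = 0
    for size in block_sizes:
        cov[start : start + size, start : start + size] = within_block_corr
        start += size
    np.fill_diagonal(cov, 1.0)
    return cov


def _check_psd(cov: np.ndarray) -> None:
    eigmin = float(np.linalg.eigvalsh(cov).min())
    if eigmin < -1e-8 * max(1.0, abs(cov).max()):
        raise ValueError(
            f"covariance is not positive semi-definite (min eigenvalue {eigmin:.3g}); "
            "project onto the PSD cone first, e.g. clip negative eigenvalues to zero"
        )


def simulate_sim2(cfg: Sim2Config) -> ReplicateSet:
    """Simulate paired MVN classification replicates.

    Each replicate draws ``n_individuals`` MVN vectors, assigns half of
    the individuals (a seeded shuffle) to class 1, and shifts the means of
    the causal variables by their effect size in class 1. Both replicates
    of a pair share the causal variables and effect sizes; draws are
    independent.
    """
    _check_psd(cfg.covariance)
    p = cfg.covariance.shape[0]
    names = [f"gene_{k:05d}" for k in range(1, p + 1)]
    master = np.random.default_rng(
        np.random.SeedSequence(int(cfg.seed) & _SEED_MASK, spawn_key=(0xD4,))
    )
    causal_idx = master.choice(p, size=len(cfg.effect_sizes) * cfg.n_causal_per_effect,
                               replace=False)
    effects = np.repeat(np.asarray(cfg.effect_sizes, dtype=float), cfg.n_causal_per_effect)
    try:
        chol = np.linalg.cholesky(cfg.covariance)
        method = "cholesky"
    except np.linalg.LinAlgError:
        chol, method = None, "eigh"
    n = cfg.n_individuals
    replicates, pairing = [], []
    for pair in range(cfg.n_pairs):
        for _ in range(2):
            if method == "cholesky":
                X = master.normal(size=(n, p)) @ chol.T
            else:
                X = master.multivariate_normal(np.zeros(p), cfg.covariance, size=n,
                                               method="eigh")
            labels = np.zeros(n, dtype=int)
            labels[master.permutation(n)[: n // 2]] = 1
            X[np.ix_(labels == 1, causal_idx)] += effects[None, :]
            replicates.append(Dataset(X, labels, names, CLASSIFICATION))
            pairing.append(pair)
    truth = {names[i]: float(e) for i, e in zip(causal_idx, effects)}
    return ReplicateSet(replicates=replicates, truth=truth, pairing=pairing)
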