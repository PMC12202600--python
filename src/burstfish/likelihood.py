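"""Observation likelihood and log-posterior for the bursting model.

The likelihood factorizes as L = L1 * L2:

* L1 — per cell, the polyploid joint probability of observing ``k`` active of
  ``K`` alleles together with a total mature-mRNA count ``m`` (cells
  independent).
* L2 — per detected active transcription site, the Gamma density of the
  measured exon fluorescence ``z``, whose mean ``nu`` is predicted by the
  mechanistic nascent-RNA model (rejection sampling; a Monte-Carlo estimate
  shared by all T terms and recomputed with common random numbers per
  parameter value) and whose variance is the free parameter ``beta``.

The posterior uses an improper uniform prior on the linear (non-negative)
parameter scale while sampling runs in log coordinates, so the Jacobian of the
exp transform (sum of the log-parameters) is added; a flag switches to a
uniform-in-log prior for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .nascent import (
    GeneModel,
    InfeasibleParameterError,
    gamma_intensity_loglik,
    mean_active_ts_intensity,
)
from .telegraph import (
    CellObservation,
    KummerError,
    PmfTruncation,
    TelegraphParams,
    TruncationError,
    default_truncation,
    polyploid_joint_pmf,
)

__all__ = [
    "TSObservation",
    "Dataset",
    "LikelihoodConfig",
    "log_l1",
    "log_l2",
    "log_posterior",
]

NEG_INF = float("-inf")
# log-parameters outside +/- LOG_BOUND correspond to rates beyond any
# physically meaningful scale and are assigned zero posterior mass outright.
LOG_BOUND = 40.0


@dataclass(frozen=True)
class TSObservation:
    """One detected active TS: measured exon fluorescence in mature-RNA equivalents."""

    cell_id: str
    z: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.z) and self.z > 0):
            raise ValueError(f"TS intensity must be positive and finite, got {self.z!r}")


@dataclass(frozen=True)
class Dataset:
    """Observations for one (gene, condition, time point) group."""

    cells: tuple[CellObservation, ...]
    active_ts: tuple[TSObservation, ...]
    gene: GeneModel
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(self.cells))
        object.__setattr__(self, "active_ts", tuple(self.active_ts))
        by_id = {c.cell_id: c for c in self.cells}
        if len(by_id) != len(self.cells):
            raise ValueError("duplicate cell_id in dataset")
        counts: dict[str, int] = {}
        for ts in self.active_ts:
            if ts.cell_id not in by_id:
                raise ValueError(f"TS observation references unknown cell_id {ts.cell_id!r}")
            counts[ts.cell_id] = counts.get(ts.cell_id, 0) + 1
        for cid, n in counts.items():
            if n > by_id[cid].k:
                raise ValueError(
                    f"cell {cid!r} has {n} TS intensity records but only k={by_id[cid].k} active TSs"
                )

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([ts.z for ts in self.active_ts])


@dataclass(frozen=True)
class LikelihoodConfig:
    """Knobs of the posterior evaluation.

    ``intensity_seed`` fixes the common random numbers used for the per-proposal
    Monte-Carlo estimate of the mean TS intensity, so the log-posterior is a
    deterministic function of the parameters within one chain.
    """

    tail_tol: float = 1e-10
    n_intensity_samples: int = 1000
    intensity_seed: int = 1234
    use_l1: bool = True
    use_l2: bool = True
    log_uniform_prior: bool = False


def log_l1(
    params: TelegraphParams,
    cells: Sequence[CellObservation],
    trunc: PmfTruncation | None = None,
    tail_tol: float = 1e-10,
) -> float:
    """Count/active-TS log-likelihood: sum_c log P(k_c, m_c | K_c, theta).

    The joint pmf is computed once per distinct ploidy K on its full convolved
    support (so an observed count beyond the single-allele truncation indexes
    the exact convolution rather than being clipped). A cell whose probability
    underflows to zero contributes -inf, never an exception.
    """
    if trunc is None:
        trunc = default_truncation(params, tail_tol)
    total = 0.0
    by_K: dict[int, list[CellObservation]] = {}
    for c in cells:
        by_K.setdefault(c.K, []).append(c)
    for K, group in by_K.items():
        max_m = max(c.m for c in group)
        t = trunc
        if max_m > K * trunc.m_max:
            # observation beyond the convolved support: expand the truncation
            t = PmfTruncation(m_max=max_m, tail_tol=trunc.tail_tol)
        joint = polyploid_joint_pmf(params, K, t, full_support=True)
        with np.errstate(divide="ignore"):
            log_joint = np.log(joint)
        for c in group:
            total += log_joint[c.k, c.m]
    return float(total)


def log_l2(
    params: TelegraphParams,
    active_ts: Sequence[TSObservation],
    gene: GeneModel,
    n_samples: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Intensity log-likelihood: sum_t log Gamma(z_t; mean nu, variance beta).

    The mean nu is estimated once per parameter value by rejection sampling
    from the mechanistic nascent model and shared across all T terms. An
    infeasible-parameter error from the sampler (vanishing acceptance) maps to
    -inf rather than propagating.
    """
    if not active_ts:
        return 0.0
    try:
        est = mean_active_ts_intensity(params, gene, n_samples=n_samples, rng=rng)
    except InfeasibleParameterError:
        return NEG_INF
    if est.mean_intensity <= 0:
        return NEG_INF
    z = np.array([ts.z for ts in active_ts])
    return float(np.sum(gamma_intensity_loglik(z, est.mean_intensity, params.beta)))


def log_posterior(
    log_params: np.ndarray,
    dataset: Dataset,
    config: LikelihoodConfig = LikelihoodConfig(),
) -> float:
    """Log-posterior density over the natural-log parameter vector.

    log L1 + log L2 + sum_i log theta_i; the last term is the Jacobian of the
    exp transform, making the sampled target the stated uniform-in-linear
    prior expressed in log coordinates. Underflow maps to -inf.
    """
    log_params = np.asarray(log_params, dtype=float)
    if log_params.shape != (5,):
        raise ValueError("log_params must be a 5-vector (log lam, gam, mu, delta, beta)")
    if not np.all(np.isfinite(log_params)) or np.any(np.abs(log_params) > LOG_BOUND):
        return NEG_INF
    try:
        params = TelegraphParams.from_array(np.exp(log_params))
    except ValueError:
        return NEG_INF

    total = 0.0 if config.log_uniform_prior else float(log_params.sum())
    if config.use_l1:
        try:
            total += log_l1(params, dataset.cells, tail_tol=config.tail_tol)
        except (TruncationError, KummerError):
            # the truncated support (or the hypergeometric series budget)
            # cannot hold the proposed scale: zero posterior mass
            return NEG_INF
    if config.use_l2:
        rng = np.random.default_rng(config.intensity_seed)
        total += log_l2(
            params,
            dataset.active_ts,
            dataset.gene,
            n_samples=config.n_intensity_samples,
            rng=rng,
        )
    if np.isnan(total):
        return NEG_INF
    return total
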