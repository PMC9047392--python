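"""Boltzmann similarity weights over a counterpart pool.

A treated individual i is matched against every untreated counterpart j
through the kernel

    sim(i, j) = exp(-|P_i - P_j| / k*tau),     W(i, j) = sim(i, j) / sum_j sim(i, j)

where P are basal risk projections and the product k*tau acts as a
temperature/bandwidth: k*tau -> infinity gives uniform weights over the
pool, k*tau -> 0 concentrates all mass on the nearest counterpart(s).  The
two hyperparameters only ever appear as their product, so a single ``k_tau``
is exposed; ``"auto"`` uses the empirical standard deviation of the pool's
projections (an adaptive bandwidth, recomputed per covariate block).

Clinical and genetic weight vectors are combined by elementwise product and,
by default, renormalized so each individual again distributes exactly one
unit of weight over its pool — this keeps the Bernoulli-trial reading of the
downstream Beta update intact regardless of pool size.  The verbatim
(unrenormalized) product is available via ``renormalize=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class SimilarityWeights:
    """Weights of one individual over a counterpart pool.

    ``normalized`` is True for every kernel output (weights sum to 1 within
    1e-9); it is False only for the verbatim unrenormalized product of two
    weight vectors, whose total is at most 1.
    """

    index_i: str
    pool_ids: tuple[str, ...]
    weights: np.ndarray
    k_tau: float
    normalized: bool = True

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if len(self.pool_ids) != w.shape[0]:
            raise ValueError("pool_ids and weights length mismatch")
        if (w < 0).any():
            raise ValueError("similarity weights must be non-negative")
        if self.normalized and abs(w.sum() - 1.0) > _NORM_TOL:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")


def resolve_k_tau(k_tau: float | str, pool_projections: np.ndarray) -> float:
    """Turn the ``k_tau`` config value ('auto' or a positive real) into a number."""
    if isinstance(k_tau, str):
        if k_tau != "auto":
            raise ValueError(f"k_tau must be 'auto' or a positive real, got {k_tau!r}")
        sd = float(np.std(np.asarray(pool_projections, dtype=float)))
        return sd if sd > 0 else 1.0
    k_tau = float(k_tau)
    if k_tau <= 0:
        raise ValueError(f"k_tau must be positive, got {k_tau}")
    return k_tau


def boltzmann_weight_matrix(
    p_rows: np.ndarray, p_cols: np.ndarray, k_tau: float
) -> np.ndarray:
    """Row-normalized Boltzmann weights between two projection vectors.

    Entry (i, j) is proportional to exp(-|p_rows[i] - p_cols[j]| / k_tau);
    every row sums to 1.  The row minimum distance is subtracted before
    exponentiation so tiny temperatures cannot underflow all entries at once.
    """
    if k_tau <= 0:
        raise ValueError(f"k_tau must be positive, got {k_tau}")
    p_rows = np.asarray(p_rows, dtype=float)
    p_cols = np.asarray(p_cols, dtype=float)
    if p_cols.size == 0:
        raise ValueError("counterpart pool is empty")
    dist = np.abs(p_rows[:, None] - p_cols[None, :])
    dist -= dist.min(axis=1, keepdims=True)
    sim = np.exp(-dist / k_tau)
    return sim / sim.sum(axis=1, keepdims=True)


def boltzmann_weights(
    p_i: float,
    p_pool: Sequence[float] | np.ndarray,
    k_tau: float,
    index_i: str = "i",
    pool_ids: Sequence[str] | None = None,
) -> SimilarityWeights:
    """Similarity weights of one individual over a pool of counterparts."""
    p_pool = np.asarray(p_pool, dtype=float)
    if p_pool.size == 0:
        raise ValueError("counterpart pool is empty")
    w = boltzmann_weight_matrix(np.array([p_i]), p_pool, k_tau)[0]
    ids = tuple(pool_ids) if pool_ids is not None else tuple(
        f"j{k}" for k in range(p_pool.size)
    )
    return SimilarityWeights(index_i=index_i, pool_ids=ids, weights=w, k_tau=float(k_tau))


def combine_weights(
    w_clinical: SimilarityWeights,
    w_genetic: SimilarityWeights,
    renormalize: bool = True,
) -> SimilarityWeights:
    """Elementwise product of clinical and genetic weights over the same pool.

    With ``renormalize=True`` (default) the product is rescaled to sum to 1;
    a uniform factor then cancels exactly.  ``renormalize=False`` keeps the
    raw product, whose total is at most 1.
    """
    if w_clinical.pool_ids != w_genetic.pool_ids:
        raise ValueError("clinical and genetic weights cover different pools")
    prod = w_clinical.weights * w_genetic.weights
    total = prod.sum()
    if total <= 0:
        raise ValueError("combined weights vanished; pools degenerate")
    if renormalize:
        return SimilarityWeights(
            w_clinical.index_i, w_clinical.pool_ids, prod / total,
            k_tau=w_clinical.k_tau,
        )
    return SimilarityWeights(
        w_clinical.index_i, w_clinical.pool_ids, prod,
        k_tau=w_clinical.k_tau, normalized=False,
    )
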