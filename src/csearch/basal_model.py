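"""Basal risk models: scalar projections approximating the survival state.

The similarity between a treated individual and an untreated counterpart is
not measured in raw covariate space but between one-dimensional risk
projections, one per covariate block: P(Y|V) from the clinical covariates
and P(Y|G) from the binary gene matrix.  Each projection is the linear risk
score of a ridge-penalized Cox proportional-hazards fit; the genetic block
is wide, binary and sparse, so the small default penalty (0.1) is what keeps
that fit well-posed.

The fit includes treatment as an adjustment covariate so the projection
reflects baseline risk rather than treatment received, but the treatment
coefficient is excluded from the projection itself.  Only projection
*differences* |P_i - P_j| are consumed downstream, so the projection is
defined up to an additive constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .data_model import EVENT, TIME, TREATMENT, Cohort, Individual

logger = logging.getLogger(__name__)

Block = Literal["clinical", "genetic"]


class BasalFitError(RuntimeError):
    """The basal regression could not be fit (no events, non-convergence)."""


@dataclass
class BasalModel:
    """Fitted scalar risk projection for one covariate block."""

    covariate_block: Block
    coefficients: pd.Series       # indexed by covariate name, treatment excluded
    fit_metadata: dict = field(default_factory=dict)

    def project(self, individual: Individual) -> float:
        """Risk projection for a single individual (dot product with coefficients)."""
        x = individual.V if self.covariate_block == "clinical" else individual.G
        x = np.asarray(x, dtype=float)
        if x.shape != (len(self.coefficients),):
            raise ValueError(
                f"covariate dimension {x.shape} does not match model "
                f"({len(self.coefficients)} {self.covariate_block} coefficients)"
            )
        return float(x @ self.coefficients.to_numpy())

    def project_cohort(self, cohort: Cohort) -> np.ndarray:
        """Vectorized projection for every individual, in cohort order."""
        X = cohort.V if self.covariate_block == "clinical" else cohort.G
        missing = [c for c in self.coefficients.index if c not in X.columns]
        if missing:
            raise ValueError(f"cohort lacks model covariates {missing[:5]}")
        return X[self.coefficients.index].to_numpy(dtype=float) @ self.coefficients.to_numpy()


def _block_frame(cohort: Cohort, block: Block) -> pd.DataFrame:
    return cohort.V if block == "clinical" else cohort.G.astype(float)


def fit_basal(
    cohort: Cohort,
    block: Block,
    ridge: float = 0.1,
    fit_pool: Literal["all", "untreated"] = "all",
    adjust_treatment: bool = True,
) -> BasalModel:
    """Fit the basal risk projection for one covariate block.

    ``fit_pool="all"`` (default) fits on the whole cohort with treatment as
    an adjustment covariate — stabler at small n; ``"untreated"`` fits on
    the untreated arm only, in which case no adjustment is needed.  If the
    partial-likelihood fit fails to converge, a logistic regression of
    event-by-median-follow-up stands in as the projection (logged loudly) —
    any monotone risk score yields usable similarities.
    """
    pool = cohort if fit_pool == "all" else cohort.subset(cohort.ids[cohort.treatment == 0])
    if pool.event.sum() < 2:
        raise BasalFitError(
            f"basal fit needs >= 2 events in the fitting pool, got {int(pool.event.sum())}"
        )
    X = _block_frame(pool, block)
    covs = list(X.columns)
    # constant columns carry no risk information and break the fit
    keep = [c for c in covs if X[c].nunique() > 1]
    dropped = sorted(set(covs) - set(keep))
    if dropped:
        logger.warning("basal fit (%s): dropped %d constant columns", block, len(dropped))

    df = X[keep].copy()
    df[TIME] = pool.time
    df[EVENT] = pool.event
    if adjust_treatment and fit_pool == "all":
        df[TREATMENT] = pool.treatment

    meta = {
        "block": block, "ridge": ridge, "fit_pool": fit_pool,
        "n": pool.n, "n_events": int(pool.event.sum()),
        "dropped_constant": dropped, "family": "cox",
    }
    try:
        cph = CoxPHFitter(penalizer=ridge)
        cph.fit(df, duration_col=TIME, event_col=EVENT)
        coefs = cph.params_.drop(labels=[TREATMENT], errors="ignore")
        meta["converged"] = True
    except (ConvergenceError, ValueError) as err:
        logger.warning(
            "basal Cox fit (%s) failed (%s); falling back to logistic "
            "event-by-median-follow-up", block, err,
        )
        coefs = _logistic_fallback(pool, df, keep)
        meta.update(family="logistic_fallback", converged=True, cox_error=str(err))

    # re-insert dropped columns with zero weight so projection dims match the block
    full = pd.Series(0.0, index=covs)
    full[coefs.index.intersection(covs)] = coefs[coefs.index.intersection(covs)]
    return BasalModel(covariate_block=block, coefficients=full, fit_metadata=meta)


def _logistic_fallback(pool: Cohort, df: pd.DataFrame, covs: list[str]) -> pd.Series:
    from sklearn.linear_model import LogisticRegression

    median_fu = float(np.median(pool.time))
    # event observed by median follow-up; censored earlier than that is ambiguous
    # but rare in the regimes where the Cox fit fails, coded as 0
    y = ((pool.time <= median_fu) & (pool.event == 1)).astype(int)
    if len(np.unique(y)) < 2:  # pragma: no cover
        raise BasalFitError("fallback outcome is constant; cannot fit basal model")
    lr = LogisticRegression(C=10.0, max_iter=1000)
    lr.fit(df[covs].to_numpy(dtype=float), y)
    return pd.Series(lr.coef_[0], index=covs)
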