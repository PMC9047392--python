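"""Treatment-assignment propensities, IPW gene posteriors, and PS matching.

Propensities e(V) = P(T=1|V) and e(G) = P(T=1|G) are logistic-regression
fits per covariate block (ridge-penalized for the wide genetic block) with
probabilities clipped away from 0 and 1, since inverse weights explode at
the boundaries.  The clipped propensities feed two consumers:

* the IPW aggregation of individual win probabilities into a per-gene Beta
  posterior, where each carrier's win evidence is inflated by
  1 / (e(V) e(G)) on the win side and 1 / ((1-e(V))(1-e(G))) on the loss
  side.  Taken verbatim this yields pseudo-count totals far beyond the
  number of carriers, so a ``stabilized`` mode rescales the added counts to
  total one pseudo-observation per contributing individual while leaving
  the posterior mean of the added evidence unchanged;
* greedy 1:1 nearest-neighbor matching on the logit propensity without
  replacement, caliper 0.2 SD of the logit, used by the log-rank comparator
  and the Kaplan-Meier policy contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .data_model import Cohort
from .win_probability import BetaPosterior, WinPosterior

logger = logging.getLogger(__name__)

Block = Literal["clinical", "genetic"]

DEFAULT_CLIP = (0.05, 0.95)


class PropensityFitError(RuntimeError):
    pass


@dataclass
class PropensityModel:
    """Fitted logistic treatment-assignment model for one covariate block."""

    block: Block
    coefficients: pd.Series      # includes "(intercept)"
    clip_bounds: tuple[float, float] = DEFAULT_CLIP
    n_clipped: int = 0

    def predict(self, cohort: Cohort) -> np.ndarray:
        """Clipped propensity for every individual, in cohort order."""
        X = cohort.V if self.block == "clinical" else cohort.G
        covs = [c for c in self.coefficients.index if c != "(intercept)"]
        missing = [c for c in covs if c not in X.columns]
        if missing:
            raise ValueError(f"cohort lacks propensity covariates {missing[:5]}")
        eta = (
            X[covs].to_numpy(dtype=float) @ self.coefficients[covs].to_numpy()
            + self.coefficients["(intercept)"]
        )
        raw = 1.0 / (1.0 + np.exp(-eta))
        return np.clip(raw, *self.clip_bounds)

    def logit(self, cohort: Cohort) -> np.ndarray:
        p = self.predict(cohort)
        return np.log(p / (1.0 - p))


def fit_propensity(
    cohort: Cohort,
    block: Block,
    ridge: float = 1.0,
    clip_bounds: tuple[float, float] = DEFAULT_CLIP,
) -> PropensityModel:
    """Logistic-link regression of treatment on one covariate block.

    Constant columns are dropped with a warning (intercept-only in the
    degenerate all-constant case).  ``ridge`` is the L2 strength (sklearn
    C = 1/ridge); the penalty also precludes divergence under perfect
    separation, which is instead reported when fitted probabilities pin to
    the clip bounds for every individual.
    """
    t = cohort.treatment
    if t.sum() in (0, len(t)):
        raise PropensityFitError("both treatment arms are required")
    X = cohort.V if block == "clinical" else cohort.G.astype(float)
    keep = [c for c in X.columns if X[c].nunique() > 1]
    dropped = sorted(set(X.columns) - set(keep))
    if dropped:
        logger.warning("propensity fit (%s): dropped %d constant columns", block, len(dropped))

    if keep:
        lr = LogisticRegression(C=1.0 / ridge, max_iter=2000)
        lr.fit(X[keep].to_numpy(dtype=float), t)
        coefs = pd.Series(lr.coef_[0], index=keep)
        intercept = float(lr.intercept_[0])
    else:
        coefs = pd.Series(dtype=float)
        intercept = float(np.log(t.mean() / (1.0 - t.mean())))

    full = pd.Series(0.0, index=list(X.columns) + ["(intercept)"])
    if len(coefs):
        full.loc[coefs.index] = coefs.values
    full["(intercept)"] = intercept
    model = PropensityModel(block=block, coefficients=full, clip_bounds=clip_bounds)

    raw_eta = (
        X.to_numpy(dtype=float) @ full[list(X.columns)].to_numpy() + intercept
    )
    raw = 1.0 / (1.0 + np.exp(-raw_eta))
    n_clipped = int(((raw < clip_bounds[0]) | (raw > clip_bounds[1])).sum())
    if n_clipped:
        logger.warning(
            "propensity fit (%s): %d/%d probabilities clipped to %s",
            block, n_clipped, len(raw), clip_bounds,
        )
    model.n_clipped = n_clipped
    if n_clipped == len(raw):
        raise PropensityFitError(
            f"propensity fit ({block}) is degenerate: every probability outside "
            f"{clip_bounds} — near-perfect separation despite the penalty"
        )
    return model


def ipw_gene_posterior(
    win_list: Sequence[WinPosterior],
    e_v: np.ndarray,
    e_g: np.ndarray,
    prior: BetaPosterior,
    stabilized: bool = False,
) -> BetaPosterior:
    """Inverse-propensity-weighted Beta posterior over a carrier list.

    wins  += sum_i Pw_i / (e(V_i) e(G_i))
    losses += sum_i (1 - Pw_i) / ((1 - e(V_i)) (1 - e(G_i)))

    ``stabilized`` rescales the two added totals so they sum to the number
    of contributing individuals (posterior mean of the added evidence is
    unchanged); with all propensities at 0.5 this reduces exactly to the
    unweighted accumulation.
    """
    contributing = [w for w in win_list if not w.no_evidence]
    if not contributing:
        return prior
    keep = np.array([not w.no_evidence for w in win_list], dtype=bool)
    e_v = np.asarray(e_v, float)[keep]
    e_g = np.asarray(e_g, float)[keep]
    pw = np.array([w.pw for w in contributing])
    if ((e_v <= 0) | (e_v >= 1) | (e_g <= 0) | (e_g >= 1)).any():
        raise ValueError("propensities must be strictly inside (0,1); clip first")
    wins = float((pw / (e_v * e_g)).sum())
    losses = float(((1.0 - pw) / ((1.0 - e_v) * (1.0 - e_g))).sum())
    if stabilized:
        scale = len(contributing) / (wins + losses)
        wins, losses = wins * scale, losses * scale
    return prior.updated(wins, losses)


@dataclass(frozen=True)
class MatchResult:
    """1:1 propensity-matched pairs and the resulting balanced sub-cohort."""

    pairs: tuple[tuple[str, str], ...]   # (treated_id, control_id)
    unmatched_treated: tuple[str, ...]
    caliper: float

    @property
    def matched_ids(self) -> list[str]:
        return [i for pair in self.pairs for i in pair]


def propensity_match(
    cohort: Cohort,
    model: PropensityModel,
    caliper_sd: float = 0.2,
) -> tuple[Cohort, MatchResult]:
    """Greedy 1:1 nearest-neighbor matching on the logit propensity.

    Treated individuals are processed in ascending id order (deterministic
    tie-break); each receives the nearest untreated neighbor, without
    replacement, within a caliper of ``caliper_sd`` standard deviations of
    the logit propensity.  Treated individuals with no neighbor in the
    caliper are left unmatched and logged.
    """
    logit = model.logit(cohort)
    t = cohort.treatment
    ids = cohort.ids.astype(str)
    sd = float(np.std(logit))
    caliper = caliper_sd * sd if sd > 0 else np.inf

    treated = sorted(
        ((ids[k], logit[k]) for k in np.where(t == 1)[0]), key=lambda x: x[0]
    )
    controls = {ids[k]: logit[k] for k in np.where(t == 0)[0]}
    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []
    for tid, tl in treated:
        if not controls:
            unmatched.append(tid)
            continue
        # nearest control; ties broken by ascending id
        best = min(controls.items(), key=lambda kv: (abs(kv[1] - tl), kv[0]))
        if abs(best[1] - tl) <= caliper:
            pairs.append((tid, best[0]))
            del controls[best[0]]
        else:
            unmatched.append(tid)
    if not pairs:
        raise PropensityFitError("propensity matching found zero pairs within the caliper")
    if unmatched:
        logger.info("propensity matching: %d treated left unmatched", len(unmatched))
    result = MatchResult(tuple(pairs), tuple(unmatched), caliper)
    return cohort.subset(result.matched_ids), result


def standardized_mean_differences(cohort: Cohort) -> pd.Series:
    """Absolute standardized mean difference of each clinical covariate across arms."""
    t = cohort.treatment == 1
    V = cohort.V
    out = {}
    for c in V.columns:
        x = V[c].to_numpy(dtype=float)
        m1, m0 = x[t].mean(), x[~t].mean()
        s = np.sqrt((x[t].var(ddof=1) + x[~t].var(ddof=1)) / 2.0)
        out[c] = abs(m1 - m0) / s if s > 0 else 0.0
    return pd.Series(out)
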