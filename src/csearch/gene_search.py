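"""Per-gene aggregation of win posteriors and the causal-gene decision rule.

For every gene g_k the treated individuals split into carriers (g_k = 1)
and non-carriers (g_k = 0).  Each side's individual win probabilities Pw_i
are pooled as fractional Bernoulli outcomes into a Beta posterior for
P("win" | g_k = 1) and P("win" | g_k = 0) — optionally inverse-propensity
weighted to balance observed confounders.  A gene is flagged causal when
the 95% equal-tailed credible interval of the carrier posterior lies
entirely above that of the non-carrier posterior: the decision demands
interval separation, not just a higher mean.

Genes are ranked by the separation margin (carrier lower bound minus
non-carrier upper bound), which is the scalar the decision rule thresholds
at zero; flagged genes always rank above unflagged ones, ties broken by
carrier count then name.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .basal_model import fit_basal
from .data_model import Cohort
from .propensity import fit_propensity, ipw_gene_posterior
from .win_probability import (
    UNIFORM_PRIOR,
    BetaPosterior,
    WinPosterior,
    all_win_posteriors,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CSearchConfig:
    """Hyperparameters of one discovery run, serialized with every result."""

    k_tau: float | str = "auto"          # similarity bandwidth; "auto" = pool SD
    prior_alpha: float = 1.0
    prior_beta: float = 1.0
    basal_ridge: float = 0.1
    basal_fit_pool: str = "all"          # "all" | "untreated"
    incomparable: str = "drop"           # "drop" | "half"
    ipw: bool = False                    # IPW the per-gene aggregation (see docs)
    stabilized_ipw: bool = False
    propensity_clip: tuple[float, float] = (0.05, 0.95)
    ci_level: float = 0.95
    k: int = 10                          # size of the suggested gene list

    @property
    def prior(self) -> BetaPosterior:
        return BetaPosterior(self.prior_alpha, self.prior_beta)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GeneResult:
    gene: str
    posterior_carrier: BetaPosterior
    posterior_noncarrier: BetaPosterior
    ci_carrier: tuple[float, float]
    ci_noncarrier: tuple[float, float]
    separation: float
    decided_causal: bool
    n_carriers: int
    flagged_no_carriers: bool = False


@dataclass(frozen=True)
class DiscoveryResult:
    per_gene: tuple[GeneResult, ...]
    suggested: tuple[str, ...]
    config_snapshot: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.per_gene:
            rows.append({
                "gene": g.gene,
                "alpha_carrier": g.posterior_carrier.alpha,
                "beta_carrier": g.posterior_carrier.beta,
                "alpha_noncarrier": g.posterior_noncarrier.alpha,
                "beta_noncarrier": g.posterior_noncarrier.beta,
                "mean_carrier": g.posterior_carrier.mean,
                "mean_noncarrier": g.posterior_noncarrier.mean,
                "ci_low_carrier": g.ci_carrier[0],
                "ci_high_carrier": g.ci_carrier[1],
                "ci_low_noncarrier": g.ci_noncarrier[0],
                "ci_high_noncarrier": g.ci_noncarrier[1],
                "separation": g.separation,
                "decided_causal": g.decided_causal,
                "n_carriers": g.n_carriers,
            })
        df = pd.DataFrame(rows).set_index("gene")
        return df.loc[list(self.suggested) + [g for g in df.index if g not in self.suggested]]


def gene_posterior(
    win_list: Sequence[WinPosterior],
    carrier_mask: np.ndarray,
    prior: BetaPosterior = UNIFORM_PRIOR,
    ipw: tuple[np.ndarray, np.ndarray] | None = None,
    stabilized: bool = False,
) -> tuple[BetaPosterior, BetaPosterior]:
    """Carrier and non-carrier win posteriors for one gene.

    ``win_list`` covers all treated individuals; ``carrier_mask`` is aligned
    to it.  Without IPW each Pw_i adds (Pw_i, 1-Pw_i) pseudo-counts; with
    ``ipw=(e_v, e_g)`` the accumulation is inverse-propensity weighted.
    Individuals flagged as carrying no evidence contribute nothing.  A side
    with zero members returns the prior.
    """
    carrier_mask = np.asarray(carrier_mask, dtype=bool)
    if len(carrier_mask) != len(win_list):
        raise ValueError("carrier mask not aligned to win list")

    def side(mask: np.ndarray) -> BetaPosterior:
        members = [w for w, m in zip(win_list, mask) if m]
        if not members:
            return prior
        if ipw is not None:
            e_v, e_g = ipw
            return ipw_gene_posterior(
                members, np.asarray(e_v)[mask], np.asarray(e_g)[mask],
                prior, stabilized=stabilized,
            )
        pw = np.array([w.pw for w in members if not w.no_evidence])
        return prior.updated(float(pw.sum()), float(len(pw) - pw.sum()))

    return side(carrier_mask), side(~carrier_mask)


def decide_causal(
    carrier: BetaPosterior,
    noncarrier: BetaPosterior,
    level: float = 0.95,
) -> tuple[bool, float]:
    """Interval-separation rule: carrier CI entirely above non-carrier CI.

    Returns (decision, separation margin); the margin is the carrier lower
    bound minus the non-carrier upper bound, positive exactly when decided.
    """
    lo_c, _ = carrier.credible_interval(level)
    _, hi_n = noncarrier.credible_interval(level)
    margin = lo_c - hi_n
    return margin > 0, float(margin)


def suggest_genes(per_gene: Sequence[GeneResult], k: int) -> list[str]:
    """Top-k genes: decided ones first, then by separation margin descending.

    Ties break by carrier count descending, then gene name ascending.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(per_gene):
        logger.warning("k=%d exceeds the %d scored genes; returning all", k, len(per_gene))
        k = len(per_gene)
    ranked = sorted(
        per_gene,
        key=lambda g: (-int(g.decided_causal), -g.separation, -g.n_carriers, g.gene),
    )
    return [g.gene for g in ranked[:k]]


def run_csearch(cohort: Cohort, config: CSearchConfig | None = None) -> DiscoveryResult:
    """Full discovery run: basal fits, win posteriors, per-gene decisions.

    Deterministic given the cohort and config.  Stages are annotated in any
    propagated error so failures name where they occurred.
    """
    cfg = config or CSearchConfig()
    if cohort.genes is None:
        raise ValueError("discovery requires a cohort with genetic data")

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise RuntimeError(f"C-search failed at stage '{name}': {err}") from err

    basal_v = stage("basal clinical fit", fit_basal, cohort, "clinical",
                    ridge=cfg.basal_ridge, fit_pool=cfg.basal_fit_pool)
    basal_g = stage("basal genetic fit", fit_basal, cohort, "genetic",
                    ridge=cfg.basal_ridge, fit_pool=cfg.basal_fit_pool)
    win_list = stage(
        "win posteriors", all_win_posteriors, cohort, basal_v, basal_g,
        prior=cfg.prior, k_tau=cfg.k_tau, incomparable=cfg.incomparable,
    )

    treated_ids = [w.i_id for w in win_list]
    treated = cohort.subset(treated_ids)
    G_treated = treated.G.loc[treated_ids]  # align rows to win_list order

    ipw_inputs = None
    if cfg.ipw:
        e_v_model = stage("clinical propensity fit", fit_propensity, cohort,
                          "clinical", clip_bounds=cfg.propensity_clip)
        e_g_model = stage("genetic propensity fit", fit_propensity, cohort,
                          "genetic", clip_bounds=cfg.propensity_clip)
        ipw_inputs = (
            e_v_model.predict(treated), e_g_model.predict(treated),
        )

    results = []
    carrier_matrix = G_treated.to_numpy()
    for col, gene in enumerate(treated.gene_names):
        mask = carrier_matrix[:, col] == 1
        post_c, post_n = gene_posterior(
            win_list, mask, prior=cfg.prior, ipw=ipw_inputs,
            stabilized=cfg.stabilized_ipw,
        )
        decided, margin = decide_causal(post_c, post_n, cfg.ci_level)
        n_k = int(mask.sum())
        if n_k == 0:
            logger.info("gene %s has zero treated carriers; prior returned", gene)
        results.append(GeneResult(
            gene=gene,
            posterior_carrier=post_c,
            posterior_noncarrier=post_n,
            ci_carrier=post_c.credible_interval(cfg.ci_level),
            ci_noncarrier=post_n.credible_interval(cfg.ci_level),
            separation=margin,
            decided_causal=decided,
            n_carriers=n_k,
            flagged_no_carriers=n_k == 0,
        ))

    suggested = suggest_genes(results, cfg.k)
    return DiscoveryResult(tuple(results), tuple(suggested), cfg.to_dict())
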