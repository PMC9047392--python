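"""Benchmark cohort simulator: planted treatment modulators + hidden confounders.

The generator emulates the discovery benchmark this package is validated
on: 300 binary genes of which 10 (unknown to the algorithms) positively
modulate the treatment effect, 10 hidden confounders that drive both
treatment assignment and baseline hazard, and right-censored exponential
survival times.  The confounders are withheld from the cohort handed to the
discovery algorithms — they see only age, sex, treatment, the gene matrix
and the censored outcome — so the benchmark probes robustness to unobserved
confounding, not just to noise.

Generative model (per individual, all draws independent given the seed):

* genes        g_k ~ Bernoulli(gene_prevalence), i.i.d. over 300 genes
* confounders  C ~ N(0, I) over 10 hidden dimensions
* clinical     age ~ N(60, 10) years, sex ~ Bernoulli(0.5)
* treatment    T ~ Bernoulli(logistic(alpha_confounder * sum(C) + offset))
* hazard       h = h0 * exp(b_age * z_age + b_sex * sex
                             + beta_confounder * sum(C)
                             + T * (beta_treatment
                                    + gamma_modulation * sum_{k in truth} g_k)
                             + main_effect_causal * sum_{k in truth} g_k)
* outcome      time ~ Exponential(h), censored administratively at censor_time

gamma_modulation < 0 makes carriers of planted genes benefit from treatment
(lower hazard when treated); beta/alpha_confounder != 0 makes treated
patients systematically sicker, the classic confounding-by-indication
pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import EVENT, TIME, TREATMENT, Cohort


class SimulationError(RuntimeError):
    """Degenerate scenario: no events or a single treatment arm."""


@dataclass(frozen=True)
class SimulationScenario:
    """Parameter set for one simulated cohort.

    Defaults reproduce the package's benchmark conditions: 300 genes with
    10 planted positive modulators at 10% prevalence, 10 hidden confounders
    with moderate effects on both treatment assignment and hazard
    (0.3 each), no main treatment effect, a protective treatment-by-gene
    interaction of -1.0 on the log-hazard per planted gene carried, and an
    administrative censoring horizon of 60 months giving roughly two-thirds
    observed events.
    """

    n: int = 1000
    n_genes: int = 300
    n_causal: int = 10
    n_hidden_confounders: int = 10
    gene_prevalence: float = 0.1
    baseline_hazard: float = 0.03        # events per month at covariate zero
    beta_treatment: float = 0.0          # main treatment log-hazard effect
    gamma_modulation: float = -1.0       # per-causal-gene treatment interaction
    beta_confounder: float = 0.3         # confounder -> log hazard, each
    alpha_confounder: float = 0.3        # confounder -> treatment log-odds, each
    beta_age: float = 0.3                # per SD of age
    beta_sex: float = 0.2
    main_effect_causal: float = 0.0      # prognostic main effect of planted genes
    treatment_offset: float = 0.0        # intercept of the assignment logit
    censor_time: float = 60.0            # months
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_causal <= self.n_genes:
            raise ValueError("need 0 < n_causal <= n_genes")
        if not 0.0 < self.gene_prevalence < 1.0:
            raise ValueError("gene_prevalence must lie in (0,1)")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be positive")
        if self.n < 2:
            raise ValueError("n must be at least 2")


@dataclass(frozen=True)
class SimulatedCohort:
    """A generated cohort plus the ground truth withheld from discovery."""

    cohort: Cohort
    truth: frozenset[str]
    confounders: np.ndarray  # n x n_hidden, diagnostics only

    @property
    def scenario(self) -> SimulationScenario:
        return self._scenario

    def __init__(self, cohort: Cohort, truth: frozenset[str], confounders: np.ndarray,
                 scenario: SimulationScenario):
        object.__setattr__(self, "cohort", cohort)
        object.__setattr__(self, "truth", frozenset(truth))
        object.__setattr__(self, "confounders", confounders)
        object.__setattr__(self, "_scenario", scenario)


def _gene_names(n_genes: int) -> list[str]:
    width = len(str(n_genes))
    return [f"g{str(k + 1).zfill(width)}" for k in range(n_genes)]


def simulate_cohort(scenario: SimulationScenario) -> SimulatedCohort:
    """Draw one cohort from the scenario; bit-identical given the seed."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    names = _gene_names(sc.n_genes)

    G = rng.binomial(1, sc.gene_prevalence, size=(sc.n, sc.n_genes)).astype(np.int8)
    causal_idx = rng.choice(sc.n_genes, size=sc.n_causal, replace=False)
    truth = frozenset(names[k] for k in causal_idx)
    C = rng.standard_normal((sc.n, sc.n_hidden_confounders))

    age = rng.normal(60.0, 10.0, sc.n)
    sex = rng.binomial(1, 0.5, sc.n)

    assign_logit = sc.treatment_offset + sc.alpha_confounder * C.sum(axis=1)
    T = rng.binomial(1, 1.0 / (1.0 + np.exp(-assign_logit)))

    n_causal_carried = G[:, causal_idx].sum(axis=1)
    log_hazard = (
        sc.beta_age * (age - 60.0) / 10.0
        + sc.beta_sex * sex
        + sc.beta_confounder * C.sum(axis=1)
        + sc.main_effect_causal * n_causal_carried
        + T * (sc.beta_treatment + sc.gamma_modulation * n_causal_carried)
    )
    hazard = sc.baseline_hazard * np.exp(log_hazard)
    latent = rng.exponential(1.0 / hazard)
    event = (latent <= sc.censor_time).astype(int)
    time = np.minimum(latent, sc.censor_time)

    if event.sum() == 0:
        raise SimulationError(
            f"scenario produced zero events (n={sc.n}, censor_time={sc.censor_time})"
        )
    if T.sum() in (0, sc.n):
        raise SimulationError(
            f"scenario produced a single treatment arm ({int(T.sum())}/{sc.n} treated)"
        )

    width = len(str(sc.n))
    ids = [f"S{str(k + 1).zfill(width)}" for k in range(sc.n)]
    clinical = pd.DataFrame(
        {"age": age, "sex": sex, TREATMENT: T, TIME: time, EVENT: event},
        index=pd.Index(ids, name="sample_id"),
    )
    genes = pd.DataFrame(G, index=clinical.index, columns=names)
    return SimulatedCohort(Cohort(clinical, genes), truth, C, sc)


def scenario_grid(
    n_values: Sequence[int],
    base: SimulationScenario | None = None,
    master_seed: int | None = None,
) -> list[SimulationScenario]:
    """Scenarios identical to ``base`` except for n, with reproducible child seeds.

    Child seeds are spawned from ``master_seed`` (default: the base
    scenario's seed) via :class:`numpy.random.SeedSequence`, so the grid is
    deterministic without the cohorts at different n sharing draws.
    """
    if any(n <= 0 for n in n_values):
        raise ValueError("cohort sizes must be positive")
    base = base or SimulationScenario()
    root = np.random.SeedSequence(master_seed if master_seed is not None else base.seed)
    children = root.spawn(len(n_values))
    return [
        replace(base, n=int(n), seed=int(child.generate_state(1)[0] % (2**31)))
        for n, child in zip(n_values, children)
    ]


#: the cohort sizes of the benchmark discovery-versus-n curve
DEFAULT_N_GRID = (100, 200, 500, 1000, 1500, 2000, 2500, 3000, 3500, 4000)
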