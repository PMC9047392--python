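import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

# property tests must behave identically on every run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from csearch.data_model import EVENT, TIME, TREATMENT, Cohort
from csearch.synthetic_data import SimulationScenario, simulate_cohort


def build_cohort(
    times,
    events,
    treatment,
    genes: dict[str, list[int]] | None = None,
    age=None,
    sex=None,
) -> Cohort:
    """Hand-build a small cohort with ids P01, P02, ... in input order."""
    n = len(times)
    ids = [f"P{str(k + 1).zfill(2)}" for k in range(n)]
    clin = pd.DataFrame(
        {
            "age": age if age is not None else np.linspace(40, 70, n),
            "sex": sex if sex is not None else [k % 2 for k in range(n)],
            TREATMENT: treatment,
            TIME: times,
            EVENT: events,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    gene_df = None
    if genes is not None:
        gene_df = pd.DataFrame(genes, index=clin.index)
    return Cohort(clin, gene_df)


@pytest.fixture(scope="session")
def small_sim():
    """One modest benchmark cohort reused by read-only tests."""
    return simulate_cohort(SimulationScenario(n=600, seed=42))


@pytest.fixture
def toy_cohort():
    """10 patients, 5 treated / 5 untreated, no censoring, 2 genes."""
    rng = np.random.default_rng(7)
    times = rng.uniform(1, 50, 10).round(1)
    return build_cohort(
        times=times,
        events=[1] * 10,
        treatment=[1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
        genes={"gA": [1, 0, 1, 0, 1, 0, 1, 0, 1, 0],
               "gB": [0, 1, 0, 1, 0, 1, 0, 1, 0, 1]},
    )
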