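import numpy as np
import pytest

from episcreen.cohort import (CohortConfig, DiseaseModel, InteractionTerm,
                              SnpSpec, simulate_case_control)


def null_model(prevalence: float = 0.1) -> DiseaseModel:
    return DiseaseModel(intercept=float(np.log(prevalence / (1 - prevalence))))


def interaction_model(gamma: float, model: str = "addxadd",
                      prevalence: float = 0.1,
                      snp_a: str = "s0", snp_b: str = "s1") -> DiseaseModel:
    return DiseaseModel(
        intercept=float(np.log(prevalence / (1 - prevalence))),
        interaction_terms=(InteractionTerm(snp_a, snp_b, model, gamma),))


def make_cohort(n_cases=400, n_controls=400, mafs=(0.3, 0.3), model=None,
                seed=0, **kwargs):
    specs = tuple(SnpSpec(f"s{i}", m) for i, m in enumerate(mafs))
    cfg = CohortConfig(n_cases, n_controls, specs,
                       model or null_model(), seed=seed, **kwargs)
    return simulate_case_control(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Two independent null SNPs, 400+400 subjects."""
    return make_cohort(seed=11)


@pytest.fixture(scope="session")
def interacting_cohort():
    """Strong additive x additive interaction (OR 2), 1500+1500 subjects."""
    return make_cohort(1500, 1500, model=interaction_model(np.log(2.0)), seed=7)
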