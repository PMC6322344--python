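import numpy as np
import pytest

import dentalrisk as dr
from dentalrisk import reference


@pytest.fixture(scope="session")
def small_cohort() -> dr.Cohort:
    return dr.Cohort(
        {
            "outcome": [1, 0, 1],
            "gender": ["Female", "Male", "Female"],
            "residence": ["Urban", "Rural", "Urban"],
            "region": ["Others", "SNNPR", "Others"],
            "age_group": ["<18", "18-25", ">=35"],
            "clean_teeth": ["No", "Yes", "No"],
        }
    )


@pytest.fixture(scope="session")
def default_cohort() -> dr.Cohort:
    """The default synthetic cohort: n = 6007, published marginals and
    coefficients, fixture seed."""
    return dr.generate_cohort(dr.GeneratorConfig())


@pytest.fixture(scope="session")
def default_mle(default_cohort) -> dr.ClassicalResults:
    return dr.LogisticModel.from_cohort(default_cohort).fit()


@pytest.fixture(scope="session")
def default_posterior(default_cohort) -> dr.PosteriorResults:
    """Full default MCMC run (3 chains, thin 50) on the default cohort;
    shared by the Bayesian/MLE agreement and convergence checks."""
    model = dr.BayesianLogit.from_cohort(default_cohort)
    return model.fit(dr.ChainConfig())


@pytest.fixture(scope="session")
def intercept_only_design():
    """5229 natural-caries outcomes of 6007, intercept only — the study's
    marginal prevalence, with a closed-form MLE."""
    y = np.concatenate(
        [
            np.ones(reference.N_NATURAL),
            np.zeros(reference.N_PATIENTS - reference.N_NATURAL),
        ]
    )
    X = np.ones((reference.N_PATIENTS, 1))
    return y, X


@pytest.fixture(scope="session")
def gender_counts():
    return reference.CROSSTAB_COUNTS["gender"]
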