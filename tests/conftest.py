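import numpy as np
import pytest

import mrdflow as m


@pytest.fixture(scope="session")
def small_cohort():
    """40-subject default-archetype cohort with clinical outcomes (seed 7)."""
    specs = m.default_archetypes()
    config = m.default_config(n_subjects=40, seed=7)
    cohort, labels = m.generate_cohort(specs, config)
    cohort.clinical = m.generate_survival(labels, specs, config)
    return m.filter_cohort(cohort, 2), labels


@pytest.fixture(scope="session")
def fitted_four_cluster():
    """One 4-cluster fit on an 80-subject cohort, shared across tests."""
    specs = m.default_archetypes()
    config = m.default_config(n_subjects=80, seed=11)
    cohort, labels = m.generate_cohort(specs, config)
    cohort.clinical = m.generate_survival(labels, specs, config)
    cohort = m.filter_cohort(cohort, 3)
    fit = m.fit_fcm(cohort, G=4, p=5, n_starts=3, seed=11)
    return fit, cohort, labels


def toy_two_cluster_model(sigma2=0.25, priors=(0.5, 0.5), t_span=(0.0, 10.0)):
    """Hand-built 2-cluster model on a linear (p=2) basis with no random
    effect: cluster means are straight lines, so every posterior quantity
    has a closed form."""
    basis = m.NaturalCubicBasis(np.array(t_span))
    eta = np.array([[-6.0, 0.0], [-2.0, -0.3]])  # intercept, slope
    pi = np.asarray(priors, dtype=float)
    lambda0 = pi @ eta
    B = eta - lambda0
    U, D, Vt = np.linalg.svd(np.sqrt(pi)[:, None] * B, full_matrices=False)
    Lambda = Vt[:1].T
    alpha = B @ Lambda
    return m.FcmModel(
        basis=basis, G=2, h=1, lambda0=lambda0, Lambda=Lambda, alpha=alpha,
        Gamma=np.zeros((2, 2)), sigma2=sigma2, priors=pi,
    )
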