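import numpy as np
import pytest

from robustbayes import BayesModel, GaussianComponent

# printed population parameters used throughout the worked examples
GIRLS = (149.8081, 0.5843)
BOYS = (151.0295, 0.5108)
PATIENTS = (74.3881, 36.2643)
CONTROLS = (86.8806, 29.8202)


@pytest.fixture
def height_model() -> BayesModel:
    """Two univariate Gaussians for 11-year-olds' heights, equal priors."""
    return BayesModel([
        GaussianComponent("girls", GIRLS[0], GIRLS[1], 0.5),
        GaussianComponent("boys", BOYS[0], BOYS[1], 0.5),
    ])


@pytest.fixture
def c18cer_model() -> BayesModel:
    """C18Cer serum concentration model: patients vs healthy controls."""
    return BayesModel([
        GaussianComponent("patients", PATIENTS[0], PATIENTS[1], 0.5),
        GaussianComponent("controls", CONTROLS[0], CONTROLS[1], 0.5),
    ])


def random_model(rng: np.random.Generator, d: int = 1, c: int = 3) -> BayesModel:
    """A random valid model for property tests."""
    w = rng.dirichlet(np.ones(c))
    comps = []
    for k in range(c):
        mean = rng.normal(0, 5, size=d)
        if d == 1:
            disp = float(rng.uniform(0.3, 3.0))
        else:
            A = rng.normal(0, 1, size=(d, d))
            disp = A @ A.T + np.eye(d) * 0.2
        comps.append(GaussianComponent(k, mean, disp, float(w[k])))
    # weights from dirichlet sum to 1 up to float error; renormalise hard
    total = sum(cp.weight for cp in comps)
    for cp in comps:
        cp.weight /= total
    return BayesModel(comps)
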