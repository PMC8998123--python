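import numpy as np
import pytest

from mixtox.models import ParameterVector, get_family

# one well-behaved parameter set per family; each reaches 50% extra risk
# inside the standard zebrafish grid (top concentration 100 µM)
TRUE_PARAMS = {
    "quantal_linear": (0.02, 0.05),
    "weibull": (0.02, 1.5, 0.005),
    "gamma": (0.02, 2.0, 0.15),
    "multistage2": (0.02, 0.01, 0.001),
    "logistic": (-3.0, 0.15),
    "probit": (-1.8, 0.09),
    "log_logistic": (0.02, -6.0, 2.0),
    "log_probit": (0.02, -4.0, 1.5),
}


@pytest.fixture(scope="session")
def true_params():
    return {name: ParameterVector(get_family(name), vals)
            for name, vals in TRUE_PARAMS.items()}


def random_parameter_vector(rng: np.random.Generator, family_name: str
                            ) -> ParameterVector:
    """Random valid parameters with a genuine dose response (positive slope)
    and background below 0.5, spanning BMCs across several decades."""
    fam = get_family(family_name)
    g = rng.uniform(0.0, 0.4)
    scale = 10.0 ** rng.uniform(-1.0, 2.0)  # characteristic concentration
    if family_name == "quantal_linear":
        vals = (g, np.log(2.0) / scale)
    elif family_name == "weibull":
        a = rng.uniform(1.0, 4.0)
        vals = (g, a, np.log(2.0) / scale ** a)
    elif family_name == "gamma":
        a = rng.uniform(1.0, 4.0)
        vals = (g, a, a / scale)
    elif family_name == "multistage2":
        b1 = rng.uniform(0.0, 1.0) * np.log(2.0) / scale
        b2 = (np.log(2.0) - b1 * scale) / scale**2
        vals = (g, b1, max(b2, 0.0))
    elif family_name == "logistic":
        vals = (rng.uniform(-5.0, -1.0), rng.uniform(0.5, 4.0) / scale)
    elif family_name == "probit":
        vals = (rng.uniform(-3.0, -0.5), rng.uniform(0.3, 2.0) / scale)
    elif family_name in ("log_logistic", "log_probit"):
        b = rng.uniform(1.0, 6.0)
        vals = (g, -b * np.log(scale), b)
    else:
        raise KeyError(family_name)
    return ParameterVector(fam, vals)
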