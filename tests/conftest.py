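import numpy as np
import pytest

from delogistic import ModelParameters, PRESETS


@pytest.fixture(scope="session")
def ref_params() -> ModelParameters:
    """The reference parameter set used in the worked examples."""
    return PRESETS["reference"]


def random_valid_params(rng: np.random.Generator) -> ModelParameters:
    """A random strictly positive parameter set (log-uniform in [0.1, 3])."""
    vals = 10.0 ** rng.uniform(-1.0, np.log10(3.0), size=10)
    names = ["d1", "d2", "r", "K", "a1", "a2", "c", "b", "a", "l"]
    return ModelParameters(**dict(zip(names, vals)))


def random_hopf_params(rng: np.random.Generator) -> ModelParameters:
    """A random parameter set inside the Hopf regime a2 <= a1 < a2 + b c K/(a r).

    a1 is placed a random fraction of the way across the admissible band, so
    mode 0 always admits a purely imaginary characteristic root.
    """
    p = random_valid_params(rng)
    width = p.b * p.c * p.K / (p.a * p.r)
    a1 = p.a2 + rng.uniform(0.05, 0.9) * width
    return p.replace(a1=a1)
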