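import numpy as np
import pytest

from cortexwave.params import FullModelParams, ModelParams


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def full_params() -> FullModelParams:
    return FullModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_valid_params(rng: np.random.Generator) -> ModelParams:
    """Random perturbation of the defaults within a factor-of-2 band.

    Samples are rejected (and redrawn) when the kinetics have no
    non-negative uniform fixed point — e.g. when the sampled
    autocatalysis outruns the maximal inactivation, so activation grows
    without bound and no steady state exists to test against.
    """
    from cortexwave.model import uniform_steady_state

    base = ModelParams().to_dict()
    for _ in range(100):
        factors = {k: float(np.exp(rng.uniform(-0.7, 0.7))) for k in base}
        out = {k: v * factors[k] for k, v in base.items()}
        out["D_RT"] = min(out["D_RT"], out["D_RD"])
        p = ModelParams(**out)
        try:
            uniform_steady_state(p)
        except RuntimeError:
            continue
        return p
    raise RuntimeError("could not sample a parameter set with a steady state")
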