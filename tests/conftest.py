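import numpy as np
import pytest

import haksym as hx


@pytest.fixture(scope="session")
def params() -> hx.KineticParams:
    """The calibrated default parameter set (computed once per session)."""
    return hx.default_params()


@pytest.fixture(scope="session")
def random_params_factory():
    """Factory for random positive parameter sets with derived k43_0."""

    def make(rng: np.random.Generator, N: float = 1e8) -> hx.KineticParams:
        k12_0, k21, k23_0, k32, k34, k14_0, k41_0 = 10.0 ** rng.uniform(0, 6, 7)
        return hx.KineticParams(k12_0=k12_0, k21=k21, k23_0=k23_0, k32=k32,
                                k34=k34, k14_0=k14_0, k41_0=k41_0, N=N)

    return make


@pytest.fixture(scope="session")
def random_conditions_factory():
    """Factory for random but physiological-ish conditions."""

    def make(rng: np.random.Generator) -> hx.Conditions:
        return hx.Conditions(
            V_mV=rng.uniform(-180, 60),
            K_out_M=10.0 ** rng.uniform(-6, -1),
            H_out_M=10.0 ** rng.uniform(-8, -4),
            K_in_M=10.0 ** rng.uniform(-3, 0),
            H_in_M=10.0 ** rng.uniform(-8, -6),
        )

    return make
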