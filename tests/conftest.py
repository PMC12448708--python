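import numpy as np
import pandas as pd
import pytest

from photoacclim.fvcb import LightParams, fvcb_anet, load_kinetics
from photoacclim.simulate import CA_SEQUENCE


@pytest.fixture(scope="session")
def tobacco():
    return load_kinetics("tobacco")


@pytest.fixture(scope="session")
def light():
    return LightParams()


@pytest.fixture(scope="session")
def make_curve(tobacco, light):
    """Factory for forward-model A/Ci curves on the instrument Ca sequence."""

    def _make(
        vcmax=50.0,
        jmax=100.0,
        rl=1.0,
        tleaf=25.0,
        ci_ca=0.72,
        noise_sd=0.0,
        rng=None,
        ca_sequence=CA_SEQUENCE,
    ):
        ca = np.asarray(ca_sequence, dtype=float)
        ci = ci_ca * ca
        kin_t = tobacco.at_leaf_temperature(tleaf)
        anet, _ = fvcb_anet(vcmax, jmax, ci, 210_000.0, kin_t, rl, light)
        if noise_sd > 0:
            anet = anet + (rng or np.random.default_rng(0)).normal(0, noise_sd, ca.size)
        return pd.DataFrame(
            {
                "ca": ca,
                "ci": ci,
                "anet": anet,
                "t_leaf": tleaf,
                "gs": 0.2,
                "q": light.q,
                "step_index": np.arange(ca.size),
            }
        )

    return _make
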