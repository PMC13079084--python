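import numpy as np
import pytest

from peatmix.mixing import EndMember, MixingProblem, MixtureObs


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def outgassing_problem():
    """Two-source F14C-only problem with noise on the mixture only."""
    return MixingProblem(
        model="outgassing",
        sources=(
            EndMember("peat", -28.0, 0.0, 0.4, 0.0),
            EndMember("modern", -29.0, 0.0, 1.0, 0.0),
        ),
        mixture=MixtureObs(d13c_mean=-25.0, d13c_sd=0.0,
                           f14c_mean=0.76, f14c_sd=0.02),
    )


@pytest.fixture
def equilibration_problem():
    return MixingProblem(
        model="equilibration",
        sources=(
            EndMember("peat", -28.0, 1.0, 0.35, 0.15),
            EndMember("modern", -29.0, 1.0, 1.02, 0.02),
            EndMember("atmosphere", -9.80, 0.10, 1.01, 0.01),
        ),
        mixture=MixtureObs(d13c_mean=-26.68, d13c_sd=0.8,
                           f14c_mean=0.751, f14c_sd=0.06),
    )
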