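import numpy as np
import pytest
from hypothesis import settings

import sweepvep as sv

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def adult_protocol():
    return sv.SweepProtocol.adult()


@pytest.fixture(scope="session")
def montage32():
    return sv.make_montage(32)


@pytest.fixture(scope="session")
def montage128():
    return sv.make_montage(128)


@pytest.fixture(scope="session")
def inphase_cond():
    return sv.ConditionSpec(interocular_phase="in_phase")


@pytest.fixture(scope="session")
def antiphase_cond():
    return sv.ConditionSpec(interocular_phase="anti_phase")


@pytest.fixture(scope="session")
def noiseless_trial(adult_protocol, montage32, antiphase_cond):
    """Noiseless anti-phase trial (1F, 2F, 4F planted) on a 32-channel montage."""
    truth = sv.default_ground_truth(antiphase_cond, montage32, adult_protocol)
    return sv.synthesize_trial(
        antiphase_cond, adult_protocol, truth, montage32, noise=sv.NoiseSpec.silent(), seed=11
    )


def flat_truth(cond, montage, params, harmonic=2, phase=0.0):
    """Ground truth with a single harmonic on a flat (all-ones) topography."""
    from sweepvep.synth import GroundTruthResponse, HarmonicTruth

    return GroundTruthResponse(
        components={
            harmonic: HarmonicTruth(
                params=params, phase=phase, topography=np.ones(montage.n_channels)
            )
        },
        condition=cond,
    )
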