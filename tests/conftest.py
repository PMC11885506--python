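import numpy as np
import pytest

from respirisk import (BreathingParameters, ResponseSurfaceSpec,
                       SyntheticStudySpec, build_airway_geometry)
from respirisk.statespace import StateSpaceConfig


@pytest.fixture(scope="session")
def breathing():
    return BreathingParameters()


@pytest.fixture(scope="session")
def geometry(breathing):
    return build_airway_geometry(breathing)


@pytest.fixture
def desk_config():
    def make(seed=0, **overrides):
        return StateSpaceConfig.desk_scale(seed=seed, **overrides)
    return make


@pytest.fixture
def study_spec():
    """Factory for the standard synthetic study design (3 concs + vehicle)."""

    def make(amplitude=1.0, seed=1, noise_sd=0.1, hill=2.0, ec50=1.0,
             onset_day=0.0, direction="increase",
             concentrations=(0.1, 1.0, 10.0), n_replicates=3):
        return SyntheticStudySpec(
            materials=(("mat", ResponseSurfaceSpec(
                amplitude=amplitude, ec50=ec50, hill=hill,
                onset_day=onset_day, noise_sd=noise_sd,
                direction=direction)),),
            concentrations=tuple(concentrations),
            n_replicates=n_replicates, seed=seed,
        )

    return make
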