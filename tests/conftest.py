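import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.reference imports

from rnvgphase import synthetic_data as sd
from rnvgphase.io_formats import ROIMask
from rnvgphase.phase_extraction import PhaseImage


@pytest.fixture(scope="session")
def lv_roi():
    return sd.make_lv_roi()


@pytest.fixture(scope="session")
def normal_phase(lv_roi):
    return sd.preset("normal", lv_roi, seed=0)


@pytest.fixture(scope="session")
def mi_phase(lv_roi):
    return sd.preset("mi", lv_roi, seed=0)


@pytest.fixture(scope="session")
def uniform_amp(lv_roi):
    return sd.uniform_amplitude(lv_roi)


@pytest.fixture(scope="session")
def noiseless_study(normal_phase, uniform_amp):
    return sd.make_gated_study(normal_phase, uniform_amp, noise="none")


def full_mask(shape):
    return ROIMask(grid=np.ones(shape, dtype=bool))


def phase_image(values):
    values = np.asarray(values, dtype=float)
    return PhaseImage(phase=values, valid=np.ones_like(values, dtype=bool))
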