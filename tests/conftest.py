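import numpy as np
import pytest

from corticalmap import synthetic as syn
from corticalmap.gridmap import GridSpec
from corticalmap.pipeline import process_specimen


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(M=25, K=50)


@pytest.fixture(scope="session")
def constant_tube():
    """Coaxial cylinders: outer R = 10 mm, wall 3 mm (inner r = 7 mm)."""
    spec = syn.TubeSpec(axial_resolution=80, angular_resolution=48)
    pair, lm = syn.make_tube_specimen(spec, "const")
    return spec, pair, lm


@pytest.fixture(scope="session")
def bumpy_specimen():
    """One 1 mm thickening at axial fraction 0.5, a quarter turn from LM1."""
    spec = syn.TubeSpec(bumps=(syn.Bump(0.5, 0.25, 1.0, 0.10, 0.08),),
                        axial_resolution=80, angular_resolution=48)
    pair, lm = syn.make_tube_specimen(spec, "bumpy")
    return spec, pair, lm


@pytest.fixture(scope="session")
def bumpy_result(bumpy_specimen):
    spec, pair, lm = bumpy_specimen
    return spec, process_specimen(pair, lm)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
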