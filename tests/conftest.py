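import numpy as np
import pytest

from voxvol import CalcParams, run_calculation
from voxvol import testkit as tk


@pytest.fixture(scope="session")
def acetylene():
    return tk.acetylene()


@pytest.fixture(scope="session")
def acetylene_run(acetylene):
    """Default-parameter acetylene run (g 0.2, probe 1.2, surfaces on)."""
    params = CalcParams(grid_resolution=0.2, r_probe_small=1.2,
                        compute_surfaces=True)
    return run_calculation(acetylene, params)


@pytest.fixture(scope="session")
def single_h():
    return tk.make_fixture(tk.FixtureSpec("single_sphere", {"radius": 1.2}))


@pytest.fixture
def rng():
    return np.random.default_rng(20220623)
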