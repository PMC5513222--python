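import numpy as np
import pytest

import gielisleaf as gl


@pytest.fixture
def lanceolate():
    """A typical mid-range lanceolate leaf."""
    return gl.GielisParams(l=10.0, n=0.06)


@pytest.fixture
def pose():
    return gl.PoseParams(x0=3.0, y0=-2.0, theta=0.4)


@pytest.fixture
def noiseless_curve(lanceolate, pose):
    return gl.boundary(lanceolate, num_points=2000, pose=pose)


@pytest.fixture
def small_panel_config():
    return gl.SynthConfig(
        species=(
            gl.SpeciesSpec("narrow", n=0.03, weibull_k=2.0, weibull_lam=18.0),
            gl.SpeciesSpec("broad", n=0.08, weibull_k=2.5, weibull_lam=10.0),
        ),
        seed=11,
        lengths_per_species=200,
        leaves_per_species=4,
        noise_sd=0.005,
        num_points=800,
    )
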