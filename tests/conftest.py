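"""Shared fixtures: small simulated scenes and movies, generated at test time."""

import numpy as np
import pytest

from granuletrack import synthetic


@pytest.fixture(scope="session")
def small_geometry():
    return synthetic.make_geometry(1)


@pytest.fixture(scope="session")
def small_movie(small_geometry):
    """A 300-frame rendered movie with ground truth (session-scoped, ~3 s)."""
    motion = synthetic.MotionModel(activation_rate=2.0)
    truth = synthetic.simulate_emitters(small_geometry, motion, 300, seed=11)
    cam = synthetic.CameraModel(control_interval=100)
    stacks = synthetic.render_movie(truth, small_geometry, cam, seed=12)
    return {"truth": truth, "geometry": small_geometry, "camera": cam, "stacks": stacks}


def render_single_spot(x_px, y_px, shape=(40, 40), amplitude=800.0, background=100.0, sigma=1.0):
    """Noise-free frame with one Gaussian spot at a sub-pixel position."""
    ii, jj = np.mgrid[0 : shape[0], 0 : shape[1]]
    return background + amplitude * np.exp(
        -(((jj + 0.5 - x_px) ** 2) + ((ii + 0.5 - y_px) ** 2)) / (2 * sigma**2)
    )
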