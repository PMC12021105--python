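import numpy as np
import pytest
from hypothesis import settings

from nirphasor import camera, optics, synth

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def window():
    return optics.SpectralWindow(900.0, 1200.0)


@pytest.fixture
def grid(window):
    return window.grid()


@pytest.fixture
def ideal_curves(window, grid):
    return {k: optics.ideal_filter_curve(window, k, grid=grid)
            for k in ("sine", "cosine", "total")}


@pytest.fixture
def cam():
    return camera.CameraModel()


@pytest.fixture
def two_band_scene(window, grid):
    """Two-disk scene of distinct emission bands on a shared grid."""
    s1 = synth.fluorophore_spectrum(985.0, 30.0, total_flux=1e11, grid=grid)
    s2 = synth.fluorophore_spectrum(1025.0, 28.0, total_flux=1e11, grid=grid)
    return synth.SceneSpec(
        (64, 64),
        [synth.Region(("disk", (32, 20), 10), s1, label=1),
         synth.Region(("disk", (32, 45), 10), s2, label=2)],
    )
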