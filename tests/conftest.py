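import math

import numpy as np
import pytest

from pwmillusion import (FIG_PARAMS, SourceImage, ViewingGeometry,
                         make_silhouette, render)


@pytest.fixture(scope="session")
def experiment_geometry():
    """The live study's geometry: 300 cm, 0.025 cm pixel pitch (~209 px/deg)."""
    return ViewingGeometry(distance_cm=300.0, pixel_pitch_cm=0.025)


@pytest.fixture(scope="session")
def sim_geometry():
    """Coarser geometry (40 px/deg) so a 256-px image spans ~6.4 deg and
    carriers of 1-12 cpd are renderable."""
    pitch = 2 * 100.0 * math.tan(math.radians(0.5)) / 40.0
    return ViewingGeometry(distance_cm=100.0, pixel_pitch_cm=pitch)


@pytest.fixture(scope="session")
def disc_silhouette():
    return make_silhouette("disc", 256)


@pytest.fixture(scope="session")
def disc_stimulus(disc_silhouette):
    return render(disc_silhouette, FIG_PARAMS)


def pearson(a, b):
    a = np.asarray(a, float).ravel() - np.mean(a)
    b = np.asarray(b, float).ravel() - np.mean(b)
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))
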