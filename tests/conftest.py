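import numpy as np
import pytest

from nanofret import PhotophysicsParams, SphereSpec


@pytest.fixture
def study_params() -> PhotophysicsParams:
    """Dye pair used throughout the study: R0_DD = 4.6 nm, R0_DA = 5 nm."""
    return PhotophysicsParams(r0_dd=4.6, r0_da=5.0)


@pytest.fixture
def time_grid() -> np.ndarray:
    return np.geomspace(0.01, 5.0, 25)


def place_on_sphere(radius: float, chord: float) -> np.ndarray:
    """Two points on a sphere of given radius separated by a given chord distance."""
    # polar angle between the radius vectors from chord = 2 R sin(theta/2)
    theta = 2.0 * np.arcsin(chord / (2.0 * radius))
    return np.array(
        [
            [0.0, 0.0, radius],
            [radius * np.sin(theta), 0.0, radius * np.cos(theta)],
        ]
    )


@pytest.fixture
def two_site_config_factory():
    """Configuration factory: one donor + one acceptor at a chosen chord distance."""
    from nanofret import Configuration

    def make(radius: float, chord: float) -> "Configuration":
        spec = SphereSpec(radius=radius, n_donors=1, n_acceptors=1)
        return Configuration(positions=place_on_sphere(radius, chord), spec=spec)

    return make
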