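import numpy as np
import pytest

from biomag.cli_io import load_preset


@pytest.fixture(scope="session")
def preset():
    """Packaged instrument preset (three tangent 5 cm electromagnets, etc.)."""
    return load_preset("biomag1")


@pytest.fixture(scope="session")
def electromagnet(preset):
    return preset.electromagnet


@pytest.fixture(scope="session")
def array(preset):
    return preset.array


def biot_savart_loop(a, current, center, p, n_segments=10_000):
    """Brute-force Biot-Savart line integral over a discretized circular loop.

    Independent oracle for the elliptic-integral loop solution; midpoint rule
    over ``n_segments`` straight segments.
    """
    theta = (np.arange(n_segments) + 0.5) * 2.0 * np.pi / n_segments
    pts = np.stack(
        [
            center[0] + a * np.cos(theta),
            center[1] + a * np.sin(theta),
            np.full(n_segments, center[2]),
        ],
        axis=1,
    )
    dl = (
        np.stack([-a * np.sin(theta), a * np.cos(theta), np.zeros(n_segments)], axis=1)
        * (2.0 * np.pi / n_segments)
    )
    r = np.asarray(p, dtype=float) - pts
    rn = np.linalg.norm(r, axis=1)
    db = np.cross(dl, r) / rn[:, None] ** 3
    return 1.0e-7 * current * db.sum(axis=0)
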