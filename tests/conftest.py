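"""Shared fixtures: small grids and cached expensive simulations."""

from __future__ import annotations

import numpy as np
import pytest

from paxel.simulate import Medium, TimeConfig, make_semicircle_array


@pytest.fixture(scope="session")
def medium64() -> Medium:
    return Medium(grid_shape=(64, 64))


@pytest.fixture(scope="session")
def tcfg64(medium64) -> TimeConfig:
    return TimeConfig.for_medium(medium64)


@pytest.fixture(scope="session")
def geo16(medium64):
    return make_semicircle_array(16, medium64)


@pytest.fixture(scope="session")
def blob_phantom64() -> np.ndarray:
    """Two smooth blobs and a soft line segment on a 64 x 64 grid."""
    yy, xx = np.mgrid[:64, :64]
    img = np.clip(1 - (np.hypot(yy - 30, xx - 25) / 8) ** 2, 0, 1)
    img = img + 0.7 * np.clip(1 - (np.hypot(yy - 42, xx - 40) / 5) ** 2, 0, 1)
    img = img + 0.5 * np.exp(-((yy - 20) - 0.8 * (xx - 20)) ** 2 / 3) * ((xx > 15) & (xx < 50))
    return np.clip(img, 0, 1)
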