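import math

import numpy as np
import pytest

from spinflux import EmitterParams, Exposure, IlluminationSequence, OpticalConfig, PixelGrid
from spinflux.configurations import default_emitter, default_optical_config


@pytest.fixture(scope="session")
def ref_config() -> OpticalConfig:
    """Representative optics: sigma_psf 93.3 nm, sigma_illum 85 nm, 65 nm pixels, 10x10 ROI."""
    return default_optical_config()


@pytest.fixture(scope="session")
def ref_emitter() -> EmitterParams:
    """Centered emitter with 2000 signal photons, 8 background photons/pixel."""
    return default_emitter()


@pytest.fixture(scope="session")
def ref_grid(ref_config) -> PixelGrid:
    return PixelGrid(ref_config.pixel_size, ref_config.roi_nx, ref_config.roi_ny)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240117)


def random_sequence(rng, config, k_max=3, allow_infinite=True) -> IlluminationSequence:
    """A random valid exposure sequence near the ROI center (test helper)."""
    k = int(rng.integers(1, k_max + 1))
    exposures = []
    for _ in range(k):
        kind = rng.choice(["gaussian", "donut"])
        radius = (
            math.inf
            if (allow_infinite and rng.random() < 0.25)
            else float(rng.uniform(1.0, 4.0) * config.sigma_psf)
        )
        exposures.append(
            Exposure(
                kind=str(kind),
                xp=float(rng.uniform(-150, 150)),
                yp=float(rng.uniform(-150, 150)),
                pinhole_radius=radius,
            )
        )
    scenario = str(rng.choice(["exhaust_budget", "fixed_power"]))
    bg = str(rng.choice(["pattern_dependent", "overlap_area"]))
    return IlluminationSequence(tuple(exposures), scenario, bg)
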