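import dataclasses

import numpy as np
import pytest

from dlifkit.imaging_core import FrameSchedule, build_frame_schedule, truncate_schedule
from dlifkit.phantom import default_phantom, scaled_phantom, simulate_scan


@pytest.fixture(scope="session")
def schedule44() -> FrameSchedule:
    return build_frame_schedule([(24, 5), (9, 20), (11, 300)])


@pytest.fixture(scope="session")
def schedule41(schedule44) -> FrameSchedule:
    return truncate_schedule(schedule44, 2700)


@pytest.fixture(scope="session")
def clean_scan():
    """Full-resolution phantom without blur or noise (forward model only)."""
    spec = dataclasses.replace(default_phantom(seed=1), psf_fwhm_mm=0.0, noise_scale=0.0)
    return simulate_scan(spec)


@pytest.fixture(scope="session")
def blurred_scan():
    """Full-resolution phantom with default PSF, no noise."""
    spec = dataclasses.replace(default_phantom(seed=2), noise_scale=0.0)
    return simulate_scan(spec)


@pytest.fixture(scope="session")
def noisy_scan():
    """Full-resolution phantom with default PSF and noise."""
    return simulate_scan(default_phantom(seed=3))


@pytest.fixture(scope="session")
def coarse_scan():
    """Coarse-grid phantom for fast tests."""
    return simulate_scan(scaled_phantom(seed=4))


def organ_label(scan, name: str) -> int:
    return [o.name for o in scan.spec.organs].index(name) + 1


def organ_mask(scan, name: str) -> np.ndarray:
    return scan.labels == organ_label(scan, name)
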