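"""Shared fixtures: one phantom, its reference features and simulated sweeps.

Everything heavy is session-scoped so the phantom is synthesized and the
reference processed exactly once per test run.
"""

import numpy as np
import pytest

from probemap import (PipelineConfig, PhantomSpec, colocalize,
                      default_calibrations, generate_phantom, init_reference,
                      simulate_surface_stream)
from probemap.phantom import NoiseConfig, make_margin_path

SWEEP_FRAMES = 50


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def calibs():
    return default_calibrations()


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def ref_features(phantom, cfg):
    return init_reference(phantom.image, cfg)


@pytest.fixture(scope="session")
def sweep(phantom):
    """Noise-free 50-frame margin sweep with ground-truth poses."""
    path = make_margin_path(phantom, SWEEP_FRAMES, seed=3, jitter_deg=2.0)
    return simulate_surface_stream(phantom, path, seed=3)


@pytest.fixture(scope="session")
def sweep_noisy(phantom):
    """Same sweep with additive Gaussian pixel noise, sigma = 5/255."""
    path = make_margin_path(phantom, SWEEP_FRAMES, seed=3, jitter_deg=2.0)
    return simulate_surface_stream(
        phantom, path, NoiseConfig(gaussian_sigma=5.0 / 255.0), seed=3)


def _register_stream(stream, ref_features, phantom, cfg, calibs):
    surf = calibs["surface"]
    return [colocalize(f, ref_features, surf, phantom.calibration, cfg)
            for f in stream.frames]


@pytest.fixture(scope="session")
def sweep_registrations(sweep, ref_features, phantom, cfg, calibs):
    """RegistrationResult per frame of the noise-free sweep."""
    return _register_stream(sweep, ref_features, phantom, cfg, calibs)


@pytest.fixture(scope="session")
def sweep_noisy_registrations(sweep_noisy, ref_features, phantom, cfg, calibs):
    return _register_stream(sweep_noisy, ref_features, phantom, cfg, calibs)


def angle_diff_deg(a, b):
    d = (a - b + np.pi) % (2 * np.pi) - np.pi
    return abs(np.degrees(d))
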