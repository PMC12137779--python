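"""Shared fixtures: small synthetic scenes and protocol-scale phantoms.

Heavy multi-registration fixtures are session-scoped so several tests can
share one computation.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from cdti.phantom import PhantomParams, make_phantom

logging.getLogger("cdti").setLevel(logging.ERROR)


def smooth_lv_image(shape=(128, 48), center=(64, 24), r_endo=7, r_epi=16):
    """A simple smooth short-axis-like test image (body + wall + blood pool)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    r = np.hypot(rr - center[0], cc - center[1])
    img = np.zeros(shape)
    body = ((rr - center[0]) / 45) ** 2 + ((cc - center[1]) / 22) ** 2 <= 1
    img[body] = 0.5
    img[r < r_epi] = 1.0
    img[r < r_endo] = 0.8
    return gaussian_filter(img, 1.0)


@pytest.fixture(scope="session")
def lv_image():
    return smooth_lv_image()


@pytest.fixture(scope="session")
def lv_mask():
    rr, cc = np.mgrid[0:128, 0:48].astype(float)
    r = np.hypot(rr - 64, cc - 24)
    return (r > 7) & (r < 16)


@pytest.fixture(scope="session")
def still_phantom():
    """Noiseless, motion-free protocol-scale phantom (108 frames)."""
    params = PhantomParams(snr=np.inf, motion_amplitude_px=0.0, seed=0)
    series, truth = make_phantom(params)
    return params, series, truth


@pytest.fixture(scope="session")
def small_still_phantom():
    """Noiseless, motion-free reduced phantom (1 high-b average, 24 frames)."""
    params = PhantomParams(snr=np.inf, motion_amplitude_px=0.0, n_averages_high=1, seed=0)
    series, truth = make_phantom(params)
    return params, series, truth


@pytest.fixture(scope="session")
def moving_phantom():
    """Noisy moving phantom at reduced frame count (2 high-b averages)."""
    params = PhantomParams(snr=20.0, motion_amplitude_px=5.0, n_averages_high=2, seed=1)
    series, truth = make_phantom(params)
    return params, series, truth
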