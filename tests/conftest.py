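"""Shared fixtures: small synthetic scenes and analytic tube images."""

from __future__ import annotations

import numpy as np
import pytest

from vwp.gradients import compute_gradient
from vwp.image import GreyImage
from vwp.preprocess import correct_illumination, smooth
from vwp.synthetic import SceneConfig, generate_scene


def make_tube(
    width: float = 16.0,
    angle_deg: float = 0.0,
    size: int = 200,
    contrast: float = 60.0,
    background: float = 90.0,
    profile: str = "gaussian",
) -> tuple[GreyImage, np.ndarray]:
    """Straight noiseless tube through the image centre; returns (image, gt).

    The tube's configured width is the distance between the profile's
    inflection points (gaussian) or wall transitions (sigmoid), matching the
    scene generator's convention.
    """
    th = np.deg2rad(angle_deg)
    yy, xx = np.mgrid[:size, :size].astype(float)
    c = (size - 1) / 2.0
    d = np.abs(-np.sin(th) * (xx - c) + np.cos(th) * (yy - c))
    if profile == "gaussian":
        vals = background + contrast * np.exp(-(d**2) / (2.0 * (width / 2.0) ** 2))
    else:  # sigmoid walls
        vals = background + contrast / (1.0 + np.exp((d - width / 2.0) / (width / 8.0)))
    return GreyImage(np.clip(vals, 0, 255)), d <= width / 2.0


def preprocess_small(img: GreyImage, kernel: int = 8, bg_sigma: float = 30.0) -> GreyImage:
    return correct_illumination(smooth(img, kernel), background_sigma=bg_sigma)


@pytest.fixture(scope="session")
def small_scene():
    """256x256 four-vessel scene with drusen and moderate noise."""
    cfg = SceneConfig(
        height=256, width=256, n_vessels=4, width_range=(6, 20), n_drusen=3,
        drusen_radius_range=(4, 10), noise_sigma=3, seed=7,
    )
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def small_scene_pre(small_scene):
    return preprocess_small(small_scene.image)


@pytest.fixture(scope="session")
def small_scene_field(small_scene_pre):
    return compute_gradient(small_scene_pre)


@pytest.fixture(scope="session")
def tube_processed():
    """Smoothed noiseless width-16 gaussian tube with its gradient field."""
    img0, gt = make_tube(width=16, angle_deg=25)
    img = smooth(img0, 8)
    return img, gt, compute_gradient(img)
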