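"""Synthetic fundus scenes with known vessel ground truth.

Scenes emulate the structures a fundus photograph presents to a vessel
detector: a bright elliptical retina disc on a dark frame, smooth non-uniform
illumination, bright tubular vessel trees with Gaussian-like cross-sections,
drusen-like blob distractors, and additive grey-level noise.  Vessels are
rendered bright on a darker background (the normalised polarity used
throughout the pipeline).

Width convention
----------------
The configured width of a vessel is the distance between the two inflection
points of its cross-section profile.  For the Gaussian profile this means
``sigma = width / 2``: the ground-truth wall ring then coincides with the
locus of maximal grey-level gradient, which is exactly what the wall-pixel
detector localises and what a wall-pair distance estimates.  The rendered
profile decays smoothly beyond the nominal wall, as real vessels do.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import interpolate, ndimage

from .image import GreyImage

__all__ = ["SceneConfig", "SyntheticScene", "generate_scene"]

PROFILES = ("single_gaussian", "dual_mode", "single_sided")


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene; the seed fully determines it."""

    height: int = 605
    width: int = 700
    n_vessels: int = 15
    width_range: tuple[float, float] = (5.0, 50.0)
    profile: str = "single_gaussian"
    vessel_contrast: float = 60.0
    background_level: float = 90.0
    background_gradient_amplitude: float = 20.0
    n_drusen: int = 8
    drusen_radius_range: tuple[float, float] = (5.0, 20.0)
    drusen_contrast: float = 40.0
    noise_sigma: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("zero-area image")
        lo, hi = self.width_range
        if not (1.0 <= lo <= hi <= min(self.height, self.width) / 4):
            raise ValueError(
                f"width_range {self.width_range} outside [1, min(H,W)/4]"
            )
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.n_vessels < 0 or self.n_drusen < 0 or self.noise_sigma < 0:
            raise ValueError("counts and noise_sigma must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["width_range"] = list(self.width_range)
        d["drusen_radius_range"] = list(self.drusen_radius_range)
        return d


@dataclass
class SyntheticScene:
    """Rendered scene plus pixel-accurate ground truth."""

    image: GreyImage
    vessel_mask: np.ndarray
    wall_mask: np.ndarray
    centerline_mask: np.ndarray
    width_map: np.ndarray  # vessel width at centreline pixels, 0 elsewhere
    config: SceneConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def save(self, outdir: str | Path) -> None:
        from .image import save_image, save_mask

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_image(outdir / "image.png", self.image)
        save_mask(outdir / "vessel_mask.png", self.vessel_mask)
        save_mask(outdir / "wall_mask.png", self.wall_mask)
        save_mask(outdir / "centerline.png", self.centerline_mask)
        with open(outdir / "scene.json", "w") as fh:
            json.dump({"config": self.config.to_dict()}, fh, indent=2)


def _fov_ellipse(h: int, w: int) -> np.ndarray:
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.ogrid[:h, :w]
    return ((yy - cy) / (h / 2.0)) ** 2 + ((xx - cx) / (w / 2.0)) ** 2 <= 1.0


def _random_centerline(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Smooth random curve through the FOV ellipse, ~unit-step sampled.

    A cubic spline is fit through waypoints laid along a random chord of the
    ellipse with bounded perpendicular jitter, which caps the curvature and
    keeps the wall-pairing geometry (locally quasi-linear vessels) valid.
    """
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = 0.46 * h, 0.46 * w
    # two endpoints on the inset ellipse, forced at least a quarter-turn apart
    t0 = rng.uniform(0, 2 * np.pi)
    t1 = t0 + rng.uniform(0.5 * np.pi, 1.5 * np.pi)
    p0 = np.array([cy + ry * np.sin(t0), cx + rx * np.cos(t0)])
    p1 = np.array([cy + ry * np.sin(t1), cx + rx * np.cos(t1)])
    chord = p1 - p0
    length = float(np.hypot(*chord))
    normal = np.array([-chord[1], chord[0]]) / max(length, 1e-9)

    n_mid = 3
    ts = np.linspace(0, 1, n_mid + 2)
    jitter = np.zeros(n_mid + 2)
    jitter[1:-1] = rng.uniform(-0.12, 0.12, size=n_mid) * length
    pts = p0[None, :] + ts[:, None] * chord[None, :] + jitter[:, None] * normal[None, :]

    tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], s=0, k=3)
    n_samp = max(int(2 * length), 32)
    yy, xx = interpolate.splev(np.linspace(0, 1, n_samp), tck)
    return np.stack([yy, xx], axis=1)


def _sample_width(rng: np.random.Generator, width_range: tuple[float, float]) -> float:
    """Log-uniform widths: many narrow vessels, few wide trunks."""
    lo, hi = width_range
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _profile(dist: np.ndarray, width: float, kind: str) -> np.ndarray:
    """Cross-section profile as a function of unsigned distance to the CL."""
    half = width / 2.0
    if kind == "single_gaussian":
        sigma = half  # wall ring at the inflection point
        return np.exp(-(dist**2) / (2.0 * sigma**2))
    if kind == "dual_mode":
        sep, sig = width / 4.0, width / 8.0
        two = np.exp(-((dist - sep) ** 2) / (2.0 * sig**2)) + np.exp(
            -((dist + sep) ** 2) / (2.0 * sig**2)
        )
        return two / two.max() if two.max() > 0 else two
    if kind == "single_sided":
        slope = width / 8.0  # sigmoid wall transition centred on the wall
        return 1.0 / (1.0 + np.exp((dist - half) / slope))
    raise ValueError(kind)


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Render a scene and its vessel/wall/centreline ground truth.

    Deterministic: the same config (including seed) yields a bit-identical
    scene.  Vessels are combined by maximum so crossings do not double in
    brightness; masks follow the rendered geometry exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    fov = _fov_ellipse(h, w)

    vessel_layer = np.zeros((h, w), dtype=np.float64)
    vessel_mask = np.zeros((h, w), dtype=bool)
    wall_mask = np.zeros((h, w), dtype=bool)
    centerline_mask = np.zeros((h, w), dtype=bool)
    width_map = np.zeros((h, w), dtype=np.float64)

    for _ in range(config.n_vessels):
        pts = _random_centerline(rng, h, w)
        width = _sample_width(rng, config.width_range)

        raster = np.ones((h, w), dtype=bool)
        rr = np.clip(np.rint(pts[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.rint(pts[:, 1]).astype(int), 0, w - 1)
        raster[rr, cc] = False
        dist = ndimage.distance_transform_edt(raster)

        vessel_layer = np.maximum(
            vessel_layer, config.vessel_contrast * _profile(dist, width, config.profile)
        )
        tube = dist <= width / 2.0
        vessel_mask |= tube
        wall_mask |= np.abs(dist - width / 2.0) <= 0.5
        on_cl = np.zeros((h, w), dtype=bool)
        on_cl[rr, cc] = True
        centerline_mask |= on_cl
        width_map[on_cl] = np.maximum(width_map[on_cl], width)

    wall_mask &= fov
    vessel_mask &= fov
    centerline_mask &= fov
    width_map[~fov] = 0.0

    # background: constant + smooth illumination ramp
    phi = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[:h, :w]
    ramp = (np.cos(phi) * (xx / max(w - 1, 1)) + np.sin(phi) * (yy / max(h - 1, 1)))
    ramp = ramp - ramp.mean()
    span = ramp.max() - ramp.min()
    if span > 0:
        ramp = ramp / span
    background = config.background_level + config.background_gradient_amplitude * ramp

    # drusen-like bright blobs
    drusen_layer = np.zeros((h, w), dtype=np.float64)
    for _ in range(config.n_drusen):
        ang = rng.uniform(0, 2 * np.pi)
        rad_frac = np.sqrt(rng.uniform(0, 0.8))
        dy = (h / 2.0) * rad_frac * np.sin(ang)
        dx = (w / 2.0) * rad_frac * np.cos(ang)
        cy, cx = (h - 1) / 2.0 + dy, (w - 1) / 2.0 + dx
        lo, hi = config.drusen_radius_range
        radius = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        amp = config.drusen_contrast * rng.uniform(0.5, 1.0)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        drusen_layer += amp * np.exp(-d2 / (2.0 * (radius / 2.0) ** 2))

    image = background + drusen_layer + vessel_layer
    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, size=(h, w))
    image = np.where(fov, image, 0.0)
    image = np.clip(np.rint(image), 0, 255)

    grey = GreyImage(image, fov)
    return SyntheticScene(
        image=grey,
        vessel_mask=vessel_mask,
        wall_mask=wall_mask,
        centerline_mask=centerline_mask,
        width_map=width_map,
        config=config,
    )
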