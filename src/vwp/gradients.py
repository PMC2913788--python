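"""Gradient field, local orientation frame and homogeneity features.

Vessels are elongated, locally quasi-linear structures: grey levels vary
slowly along the vessel axis (the local ``u`` direction) and sharply across it
(the ``v`` direction, parallel or antiparallel to the grey-level gradient).
The wall-pixel stage therefore needs, per pixel: the gradient vector and its
magnitude, the unit vessel orientation (gradient rotated by 90 degrees), a
Gaussian gradient-strength score, the spatial scope over which the local
orientation stays homogeneous, and block variances of gradient, orientation
and curvature used as homogeneity filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import GreyImage

__all__ = [
    "GradientField",
    "compute_gradient",
    "gradient_strength",
    "orientation_scope",
    "local_homogeneity",
]


@dataclass
class GradientField:
    """Per-pixel gradient geometry of a smoothed grey image.

    ``grad[..., 0]`` is the row derivative, ``grad[..., 1]`` the column
    derivative.  ``unit_dir`` is the normalised gradient; ``orientation`` is
    ``unit_dir`` rotated by +90 degrees and is the local vessel axis estimate
    (orthogonal to the gradient by construction).  Where the magnitude is
    zero the direction is undefined and ``defined`` is False.
    """

    grad: np.ndarray
    mag: np.ndarray
    unit_dir: np.ndarray
    orientation: np.ndarray
    defined: np.ndarray
    fov_mask: np.ndarray
    global_mean_mag: float
    global_std: float
    strength: np.ndarray | None = None
    scope: np.ndarray | None = None
    local_std: np.ndarray | None = field(default=None)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mag.shape  # type: ignore[return-value]

    def angle(self) -> np.ndarray:
        """Orientation angle in radians (axial, i.e. defined modulo pi)."""
        return np.arctan2(self.orientation[..., 0], self.orientation[..., 1])


def compute_gradient(img: GreyImage) -> GradientField:
    """Central-difference gradient restricted to the FOV.

    Global statistics (mean gradient magnitude and its standard deviation)
    are taken over FOV pixels only, so the dark frame outside the retina
    ellipse never biases them.
    """
    gy, gx = np.gradient(img.pixels)
    fov = img.fov_mask
    grad = np.stack([gy, gx], axis=-1)
    grad[~fov] = 0.0
    mag = np.hypot(grad[..., 0], grad[..., 1])

    defined = mag > 0
    unit = np.zeros_like(grad)
    np.divide(grad, mag[..., None], out=unit, where=defined[..., None])
    # +90 degree rotation: (r, c) -> (-c, r)
    orientation = np.stack([-unit[..., 1], unit[..., 0]], axis=-1)

    vals = mag[fov]
    mean_mag = float(vals.mean()) if vals.size else 0.0
    std = float(np.sqrt(np.mean((vals - mean_mag) ** 2))) if vals.size else 0.0
    return GradientField(
        grad=grad,
        mag=mag,
        unit_dir=unit,
        orientation=orientation,
        defined=defined,
        fov_mask=fov.copy(),
        global_mean_mag=mean_mag,
        global_std=std,
    )


def gradient_strength(
    fld: GradientField,
    neighborhood: int = 9,
    deviation_form: bool = False,
) -> np.ndarray:
    """Gaussian gradient-strength map ``s = A exp(-||grad||^2 / (2 sigma^2))``.

    ``A`` is the maximum gradient magnitude over a square neighbourhood
    (side ``neighborhood``), making the score locally sensitive; ``sigma`` is
    the global standard deviation of the magnitude over the FOV.  With
    ``deviation_form=True`` the exponent uses the squared deviation of the
    magnitude from its global mean instead of the raw squared magnitude, so
    the score peaks at typical rather than at vanishing gradients.  The raw
    form is the default; because it is maximal at zero gradient, wall-pixel
    candidacy pairs it with the magnitude itself (see :mod:`vwp.wall`).

    The result is stored on ``fld.strength`` and returned.
    """
    A = ndimage.maximum_filter(fld.mag, size=neighborhood, mode="nearest")
    sigma = fld.global_std
    if sigma <= 0.0:
        warnings.warn("constant gradient field: strength degenerates to A", stacklevel=2)
        s = A.copy()
    else:
        if deviation_form:
            expo = -((fld.mag - fld.global_mean_mag) ** 2) / (2.0 * sigma**2)
        else:
            expo = -(fld.mag**2) / (2.0 * sigma**2)
        s = A * np.exp(expo)
    fld.strength = s
    return s


def _window_std(arr: np.ndarray, size: int) -> np.ndarray:
    m = ndimage.uniform_filter(arr, size=size, mode="nearest")
    m2 = ndimage.uniform_filter(arr**2, size=size, mode="nearest")
    return np.sqrt(np.maximum(m2 - m**2, 0.0))


def orientation_scope(
    fld: GradientField,
    max_radius: int = 10,
    thr: float = 0.5,
    angle_scale: float = np.deg2rad(20.0),
) -> np.ndarray:
    """Radius over which the local orientation stays homogeneous.

    A vessel pixel is surrounded by a region of quasi-constant orientation;
    the scope is how far that region extends.  For each radius ``r`` the
    circular standard deviation of the (axial) orientation over a
    ``(2r+1)``-sided window is scored with a Gaussian homogeneity measure
    ``exp(-sigma_circ^2 / (2 angle_scale^2))``; the scope is the largest
    ``r`` such that the score stays >= ``thr`` at every radius up to ``r``.
    Lowering ``thr`` can therefore never shrink the scope.  Windows are
    square; at these radii the difference from true disks is below the
    pixel-quantisation of the scope itself.
    """
    theta2 = 2.0 * fld.angle()
    c = np.where(fld.defined, np.cos(theta2), 0.0)
    s = np.where(fld.defined, np.sin(theta2), 0.0)
    d = fld.defined.astype(np.float64)
    scope = np.zeros(fld.shape, dtype=np.float64)
    alive = np.ones(fld.shape, dtype=bool)
    for r in range(1, max_radius + 1):
        size = 2 * r + 1
        cm = ndimage.uniform_filter(c, size=size, mode="nearest")
        sm = ndimage.uniform_filter(s, size=size, mode="nearest")
        dm = ndimage.uniform_filter(d, size=size, mode="nearest")
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.where(dm > 0, np.hypot(cm, sm) / dm, 0.0)
        R = np.clip(R, 1e-12, 1.0)
        sigma_circ = 0.5 * np.sqrt(-2.0 * np.log(R))
        score = np.exp(-(sigma_circ**2) / (2.0 * angle_scale**2))
        alive &= score >= thr
        scope[alive] = r
    scope[~fld.fov_mask] = 0.0
    fld.scope = scope
    return scope


def local_homogeneity(
    fld: GradientField, block: int = 8
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Block variance of gradient magnitude, orientation, and curvature.

    Returns ``(var_mag, var_orient, var_curv)``, each per pixel over a
    ``block`` x ``block`` sliding window.  Orientation is axial (defined
    modulo pi), so its spread is measured as the circular variance of the
    doubled angle, ``1 - |mean(exp(2i theta))|``.  Curvature is approximated
    by the magnitude of the directional derivative of the doubled-angle unit
    vector along the vessel axis, halved to undo the angle doubling.
    """
    var_mag = _window_std(fld.mag, block) ** 2

    theta2 = 2.0 * fld.angle()
    c, s = np.cos(theta2), np.sin(theta2)
    c[~fld.defined] = 0.0
    s[~fld.defined] = 0.0
    cm = ndimage.uniform_filter(c, size=block, mode="nearest")
    sm = ndimage.uniform_filter(s, size=block, mode="nearest")
    var_orient = 1.0 - np.hypot(cm, sm)

    # directional derivative of (cos 2theta, sin 2theta) along u^
    dcy, dcx = np.gradient(c)
    dsy, dsx = np.gradient(s)
    u = fld.orientation
    dc = u[..., 0] * dcy + u[..., 1] * dcx
    ds = u[..., 0] * dsy + u[..., 1] * dsx
    curvature = 0.5 * np.hypot(dc, ds)
    var_curv = _window_std(curvature, block) ** 2
    return var_mag, var_orient, var_curv
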