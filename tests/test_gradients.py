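"""Gradient field, strength, scope and homogeneity features."""

import numpy as np
import pytest

from vwp.gradients import (
    compute_gradient,
    gradient_strength,
    local_homogeneity,
    orientation_scope,
)
from vwp.image import GreyImage

from .conftest import make_tube


def test_constant_image_has_zero_magnitude_and_undefined_direction():
    fld = compute_gradient(GreyImage(np.full((32, 32), 50.0)))
    assert np.all(fld.mag == 0)
    assert not fld.defined.any()


def test_unit_ramp_gradient_and_orientation():
    img = GreyImage(np.tile(np.arange(64, dtype=float), (64, 1)))
    fld = compute_gradient(img)
    interior = np.s_[1:-1, 1:-1]
    assert np.allclose(fld.grad[interior][..., 1], 1.0)
    assert np.allclose(fld.grad[interior][..., 0], 0.0)
    # orientation is orthogonal to the gradient
    dots = np.einsum("...i,...i->...", fld.orientation, fld.unit_dir)
    assert np.abs(dots[fld.defined]).max() < 1e-6
    assert np.allclose(np.abs(fld.orientation[interior][..., 0]), 1.0)


def test_global_stats_match_double_loop_oracle():
    rng = np.random.default_rng(1)
    img = GreyImage(rng.uniform(0, 255, (32, 32)))
    fld = compute_gradient(img)
    gy, gx = np.gradient(img.pixels)
    mags = [np.hypot(gy[i, j], gx[i, j]) for i in range(32) for j in range(32)]
    assert fld.global_mean_mag == pytest.approx(np.mean(mags), abs=1e-12)
    assert fld.global_std == pytest.approx(
        np.sqrt(np.mean((np.array(mags) - np.mean(mags)) ** 2)), abs=1e-12
    )


def test_strength_closed_forms_and_oracle(small_scene_field):
    fld = small_scene_field
    s = gradient_strength(fld)
    A = np.where(fld.mag == 0, s, np.nan)
    # zero-gradient pixels score exactly A (exp(0) = 1)
    zeros = fld.mag == 0
    if zeros.any():
        from scipy import ndimage

        Amap = ndimage.maximum_filter(fld.mag, size=9, mode="nearest")
        assert np.allclose(s[zeros], Amap[zeros])
    # per-pixel scalar re-evaluation oracle
    from scipy import ndimage

    Amap = ndimage.maximum_filter(fld.mag, size=9, mode="nearest")
    oracle = Amap * np.exp(-(fld.mag**2) / (2 * fld.global_std**2))
    assert np.abs(s - oracle).max() < 1e-12


def test_strength_at_one_sigma_is_exp_minus_half():
    # mag = sigma, A = 1  ->  s = exp(-1/2)
    assert np.exp(-(1.0**2) / (2 * 1.0**2)) == pytest.approx(0.6065, abs=1e-4)


def test_strength_decreases_with_magnitude_at_fixed_A(small_scene_field):
    fld = small_scene_field
    s = gradient_strength(fld)
    from scipy import ndimage

    A = ndimage.maximum_filter(fld.mag, size=9, mode="nearest")
    sel = (A > 0) & fld.fov_mask
    # within pixels sharing (nearly) the same A, strength is decreasing in mag
    a0 = np.quantile(A[sel], 0.6)
    band = sel & (np.abs(A - a0) < 1e-9)
    if band.sum() > 10:
        mags, ss = fld.mag[band], s[band]
        order = np.argsort(mags)
        assert np.all(np.diff(ss[order]) <= 1e-12)


def test_deviation_form_peaks_at_mean_magnitude(small_scene_field):
    fld = small_scene_field
    s = gradient_strength(fld, deviation_form=True)
    from scipy import ndimage

    A = ndimage.maximum_filter(fld.mag, size=9, mode="nearest")
    near_mean = np.abs(fld.mag - fld.global_mean_mag) < 0.05
    if near_mean.any():
        assert np.all(s[near_mean] >= 0.95 * A[near_mean])


def test_constant_image_strength_warns():
    fld = compute_gradient(GreyImage(np.full((32, 32), 9.0)))
    with pytest.warns(UserWarning):
        gradient_strength(fld)


def test_scope_large_inside_tube_small_in_noise():
    img0, _ = make_tube(width=20, size=120)
    from vwp.preprocess import smooth

    fld = compute_gradient(smooth(img0, 8))
    scope = orientation_scope(fld, max_radius=10)
    interior = np.zeros((120, 120), bool)
    interior[50:70, 20:100] = True
    assert np.median(scope[interior]) >= 10  # >= tube half-width

    rng = np.random.default_rng(0)
    noise = GreyImage(np.clip(rng.normal(128, 20, (64, 64)), 0, 255))
    scope_n = orientation_scope(compute_gradient(noise), max_radius=10)
    assert np.median(scope_n) <= 2


def test_scope_monotone_in_threshold(small_scene_field):
    tight = orientation_scope(small_scene_field, max_radius=6, thr=0.8)
    loose = orientation_scope(small_scene_field, max_radius=6, thr=0.3)
    assert np.all(loose >= tight)
    vac = orientation_scope(small_scene_field, max_radius=6, thr=0.0)
    assert np.all(vac[small_scene_field.fov_mask] == 6)


def test_local_homogeneity_zero_on_uniform_ramp():
    img = GreyImage(np.tile(np.arange(64, dtype=float), (64, 1)))
    fld = compute_gradient(img)
    vm, vo, vc = local_homogeneity(fld)
    inner = np.s_[8:-8, 8:-8]
    assert np.abs(vm[inner]).max() < 1e-9
    assert np.abs(vo[inner]).max() < 1e-6
    assert np.abs(vc[inner]).max() < 1e-9


def test_checkerboard_orientation_variance_near_maximal():
    yy, xx = np.mgrid[:64, :64]
    img = GreyImage(((yy // 4 + xx // 4) % 2) * 255.0)
    fld = compute_gradient(img)
    _, vo, _ = local_homogeneity(fld)
    assert np.median(vo[8:-8, 8:-8]) > 0.5


def test_block_variance_matches_sliding_window_oracle():
    rng = np.random.default_rng(2)
    img = GreyImage(rng.uniform(0, 255, (40, 40)))
    fld = compute_gradient(img)
    vm, _, _ = local_homogeneity(fld, block=8)
    from numpy.lib.stride_tricks import sliding_window_view

    pad = np.pad(fld.mag, ((4, 3), (4, 3)), mode="edge")
    windows = sliding_window_view(pad, (8, 8)).reshape(40, 40, -1)
    oracle = windows.var(axis=-1)
    assert np.abs(vm - oracle).max() < 1e-9


def test_orientation_rotation_equivariance():
    a0, _ = make_tube(width=16, angle_deg=0, size=128)
    a90, _ = make_tube(width=16, angle_deg=90, size=128)
    from vwp.preprocess import smooth

    f0 = compute_gradient(smooth(a0, 8))
    f90 = compute_gradient(smooth(a90, 8))
    band0 = np.zeros((128, 128), bool)
    band0[50:78, 30:98] = True
    th0 = np.median((f0.angle() % np.pi)[band0 & f0.defined])
    th90 = np.median((f90.angle() % np.pi)[band0.T & f90.defined])
    diff = abs((th90 - th0) % np.pi)
    assert min(diff, np.pi - diff) == pytest.approx(np.pi / 2, abs=0.05)
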