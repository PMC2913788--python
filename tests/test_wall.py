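"""Wall-pixel candidacy, antiparallel pairing, inclusion and pruning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from vwp.gradients import compute_gradient
from vwp.image import GreyImage
from vwp.preprocess import smooth
from vwp.synthetic import SceneConfig, generate_scene
from vwp.wall import (
    InclusionStats,
    build_wall_map,
    candidate_wall_pixels,
    gaussian_inclusion,
    gaussian_similarity,
    pair_wall_pixels,
    prune_sparse,
)


def _double_edge(separation=20, size=80, slope=1.5):
    """Two antiparallel wall transitions (bright band) `separation` apart."""
    x0 = (size - separation) // 2
    xx = np.arange(size)[None, :].astype(float)
    prof = 1 / (1 + np.exp(-(xx - x0) / slope)) * 1 / (
        1 + np.exp((xx - (x0 + separation)) / slope)
    )
    return GreyImage(np.broadcast_to(90 + 60 * prof, (size, size)).copy())


# ---------------------------------------------------------------- candidates

def test_constant_image_has_no_candidates():
    fld = compute_gradient(GreyImage(np.full((64, 64), 120.0)))
    assert candidate_wall_pixels(fld, rim_margin=0).sum() == 0


def test_candidates_hug_the_true_walls():
    cfg = SceneConfig(height=200, width=200, n_vessels=1, width_range=(14, 14),
                      noise_sigma=0, n_drusen=0, background_gradient_amplitude=0,
                      seed=5)
    s = generate_scene(cfg)
    img = smooth(s.image, 8)
    fld = compute_gradient(img)
    cand = candidate_wall_pixels(fld)
    assert cand.any()
    # candidates stay within 1 px of the wall ring
    near_wall = ndimage.binary_dilation(s.wall_mask, iterations=1)
    assert (cand & ~near_wall).sum() <= 0.1 * cand.sum()
    # and the wall is densely covered: 90% of ring pixels have a candidate
    # within 1 px
    covered = ndimage.binary_dilation(cand, iterations=1)[s.wall_mask & ndimage.binary_erosion(s.image.fov_mask, iterations=12)]
    assert covered.mean() >= 0.9


def test_vacuous_percentile_keeps_all_crest_pixels(small_scene_field):
    strict = candidate_wall_pixels(small_scene_field, percentile_thr=0.95,
                                   local_dominance=0.0)
    vac = candidate_wall_pixels(small_scene_field, percentile_thr=0.0,
                                local_dominance=0.0)
    assert strict.sum() < vac.sum()
    assert not (strict & ~vac).any()  # strict ⊆ vacuous


# ------------------------------------------------------------------- pairing

def test_antiparallel_edges_pair_at_their_separation():
    img = smooth(_double_edge(separation=20), 8)
    fld = compute_gradient(img)
    cand = candidate_wall_pixels(fld, rim_margin=0)
    pairs = pair_wall_pixels(cand, fld)
    assert len(pairs) >= 40  # about one pair per interior row
    assert np.abs(pairs.distance - 20).max() <= 1.5
    assert pairs.ay.nunique() >= 40


def test_edges_beyond_width_range_do_not_pair():
    img = smooth(_double_edge(separation=60, size=120), 8)
    fld = compute_gradient(img)
    cand = candidate_wall_pixels(fld, rim_margin=0)
    pairs = pair_wall_pixels(cand, fld, width_range=(5, 50))
    assert len(pairs) == 0


def test_isolated_edge_has_no_partner():
    xx = np.arange(80)[None, :].astype(float)
    img = smooth(GreyImage(np.broadcast_to(
        90 + 60 / (1 + np.exp(-(xx - 40) / 1.5)), (80, 80)).copy()), 8)
    fld = compute_gradient(img)
    cand = candidate_wall_pixels(fld, rim_margin=0)
    assert cand.any()
    assert len(pair_wall_pixels(cand, fld)) == 0


def test_pairing_is_mutual(small_scene_pre, small_scene_field):
    cand = candidate_wall_pixels(small_scene_field)
    pairs = pair_wall_pixels(cand, small_scene_field)
    seen = {}
    for p in pairs.itertuples():
        a, b = (p.ay, p.ax), (p.by, p.bx)
        assert a not in seen and b not in seen  # each pixel used once
        seen[a] = b
        seen[b] = a
    for p in pairs.itertuples():
        assert seen[(p.ay, p.ax)] == (p.by, p.bx)


def test_pair_distances_within_configured_range(small_scene_field):
    cand = candidate_wall_pixels(small_scene_field)
    pairs = pair_wall_pixels(cand, small_scene_field, width_range=(5, 50))
    assert len(pairs) > 0
    assert pairs.distance.between(5, 50).all()
    assert pairs.quality.between(0, 1).all()


# ----------------------------------------------------------------- inclusion

def test_inclusion_probability_closed_forms():
    stats = InclusionStats(
        mu=np.array([10.0, 0.5, 100.0, 20.0]),
        sigma=np.array([2.0, 0.1, 10.0, 5.0]),
        circular=np.array([False, True, False, False]),
    )
    p, ok = gaussian_inclusion(np.array([10.0, 0.5, 100.0, 20.0]), stats)
    assert p == pytest.approx(1.0)
    assert ok
    # one feature at exactly two sigma: that factor is exp(-2), still accepted
    p, ok = gaussian_inclusion(np.array([14.0, 0.5, 100.0, 20.0]), stats)
    assert p == pytest.approx(np.exp(-2.0))
    assert ok
    # a three-sigma feature rejects regardless of the others
    p, ok = gaussian_inclusion(np.array([16.0, 0.5, 100.0, 20.0]), stats)
    assert not ok


def test_degenerate_sigma_rejects_unless_exact():
    stats = InclusionStats(
        mu=np.array([10.0]), sigma=np.array([0.0]), circular=np.array([False])
    )
    assert gaussian_inclusion(np.array([10.0]), stats) == (1.0, True)
    assert gaussian_inclusion(np.array([10.1]), stats) == (0.0, False)


def test_gaussian_similarity_scalar():
    assert gaussian_similarity(12.0, 10.0, 1.0) == pytest.approx(np.exp(-2.0))
    assert gaussian_similarity(10.0, 10.0, 0.0) == 1.0


# ------------------------------------------------------------------- pruning

def _blob(mask, y, x, n):
    """Lay down a 4-connected snake of n pixels starting at (y, x)."""
    for k in range(n):
        mask[y + k // 8, x + k % 8] = True


def test_component_size_pruning_worked_example():
    mask = np.zeros((100, 200), bool)
    for x0, n in zip((5, 55, 105, 155), (3, 8, 20, 50)):
        _blob(mask, 40, x0, n)
    out = prune_sparse(mask, min_size=10)
    assert out.sum() == 70  # only the 20- and 50-pixel components survive
    _, ncomp = ndimage.label(out, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool))
    assert ncomp == 2


def test_prune_empty_mask_is_empty():
    empty = np.zeros((32, 32), bool)
    assert not prune_sparse(empty).any()


def test_hough_mode_keeps_line_drops_singletons():
    rng = np.random.default_rng(0)
    mask = np.zeros((64, 64), bool)
    mask[12, 10:50] = True  # straight 40-px line
    ys = rng.integers(20, 60, 20)
    xs = rng.integers(0, 64, 20)
    mask[ys, xs] = True
    out = prune_sparse(mask, mode="hough")
    assert out[12, 10:50].sum() >= 35
    scattered = np.zeros_like(mask)
    scattered[ys, xs] = True
    scattered[12, 10:50] = False
    assert out[scattered].sum() <= 4


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 100), min_size=st.integers(1, 30))
def test_pruning_never_adds_pixels(seed, min_size):
    rng = np.random.default_rng(seed)
    mask = rng.random((48, 48)) < 0.08
    out = prune_sparse(mask, min_size=min_size)
    assert not (out & ~mask).any()


# ------------------------------------------------------------ full wall map

def test_wall_map_contract(small_scene, small_scene_pre, small_scene_field):
    wm = build_wall_map(small_scene_pre, small_scene_field)
    assert wm.n_pairs > 50
    # every paired pixel is in the mask
    on = wm.mask[wm.pairs.ay, wm.pairs.ax] & wm.mask[wm.pairs.by, wm.pairs.bx]
    assert on.all()
    assert wm.pairs.distance.between(5, 50).all()
    # inclusion probabilities live on the mask
    assert np.isnan(wm.inclusion_prob[~wm.mask]).all()


def test_width_recovery_on_noiseless_scene():
    cfg = SceneConfig(height=256, width=256, n_vessels=3, width_range=(8, 20),
                      noise_sigma=0, n_drusen=0, profile="single_sided", seed=21)
    s = generate_scene(cfg)
    from .conftest import preprocess_small

    img = preprocess_small(s.image)
    fld = compute_gradient(img)
    wm = build_wall_map(img, fld)
    from scipy.spatial import cKDTree

    mid = wm.midpoints()
    cl = np.argwhere(s.centerline_mask)
    d, i = cKDTree(cl).query(mid)
    near = d <= 3
    est = np.sqrt(np.maximum(wm.pairs.distance.to_numpy()[near] ** 2 - 16.0, 1.0))
    gtw = s.width_map[cl[i[near], 0], cl[i[near], 1]]
    err = np.abs(est - gtw)
    assert (err <= 2).mean() >= 0.8
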