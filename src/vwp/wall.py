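"""Vessel Wall Pixel (VWP) map construction.

The VWP mask is the coarse stage of the detector: a small set of pixels that
very likely sit on vessel walls, later used to restrict where the expensive
matched-filter convolutions run.  It is built in four steps:

1. candidate selection — block-adaptive gradient thresholding (per-block
   histogram percentile) plus 1D non-maximum suppression along the gradient,
   which thins each wall transition to its crest line;
2. antiparallel pairing — each candidate marches uphill along its gradient
   across the (bright) vessel and accepts the first candidate whose gradient
   is antiparallel and whose orientation agrees, at a distance inside the
   admissible vessel-width range; the pair distance estimates the width;
3. Gaussian inclusion — each paired pixel's features (gradient magnitude,
   gradient orientation, grey level, contrast) are compared with the local
   statistics of neighbouring accepted wall pixels through Gaussian
   similarity kernels, with a two-sigma acceptance gate per feature;
4. sparse pruning — 4-connected components that recruit fewer than
   ``min_size`` pixels are sent back to the background class (alternatively a
   windowed, angle-limited Hough transform keeps only line-supported pixels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .gradients import GradientField
from .image import GreyImage

__all__ = [
    "InclusionStats",
    "WallPixelMap",
    "candidate_wall_pixels",
    "pair_wall_pixels",
    "gaussian_similarity",
    "gaussian_inclusion",
    "inclusion_filter",
    "prune_sparse",
    "build_wall_map",
]

PAIR_COLUMNS = ["ay", "ax", "by", "bx", "distance", "angle", "quality"]

FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class InclusionStats:
    """Local per-feature mean/std over accepted wall-pixel neighbours."""

    mu: np.ndarray  # shape (n_features,)
    sigma: np.ndarray
    circular: np.ndarray  # bool per feature: axial-angle feature
    window_radius: int = 12
    n_neighbors: int = 0


@dataclass
class WallPixelMap:
    """Binary VWP mask with pairing and per-pixel feature information."""

    mask: np.ndarray
    pairs: pd.DataFrame
    inclusion_prob: np.ndarray
    features: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def midpoints(self) -> np.ndarray:
        """Rounded pair midpoints (centreline seeds), shape (n, 2)."""
        if self.pairs.empty:
            return np.empty((0, 2), dtype=int)
        my = np.rint((self.pairs.ay.to_numpy() + self.pairs.by.to_numpy()) / 2.0)
        mx = np.rint((self.pairs.ax.to_numpy() + self.pairs.bx.to_numpy()) / 2.0)
        return np.stack([my, mx], axis=1).astype(int)


# ---------------------------------------------------------------------------
# 1. candidate selection
# ---------------------------------------------------------------------------

def _block_threshold(mag: np.ndarray, fov: np.ndarray, block: int, q: float) -> np.ndarray:
    """Per-block ``q``-quantile of gradient magnitude, expanded to pixels."""
    h, w = mag.shape
    nb_r, nb_c = -(-h // block), -(-w // block)
    padded = np.full((nb_r * block, nb_c * block), np.nan)
    padded[:h, :w] = np.where(fov, mag, np.nan)
    blocks = padded.reshape(nb_r, block, nb_c, block).transpose(0, 2, 1, 3)
    blocks = blocks.reshape(nb_r, nb_c, block * block)
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-NaN blocks outside the FOV
            thr = np.nanquantile(blocks, q, axis=2)
    thr = np.nan_to_num(thr, nan=np.inf)
    return np.kron(thr, np.ones((block, block)))[:h, :w]


def candidate_wall_pixels(
    fld: GradientField,
    percentile_thr: float = 0.90,
    block: int = 32,
    rim_margin: int = 10,
    local_dominance: float = 0.85,
    dominance_window: int = 17,
) -> np.ndarray:
    """Block-adaptive gradient threshold + non-maximum suppression.

    A pixel is a candidate iff it is a local maximum of the gradient
    magnitude along the gradient direction (bilinear 1D NMS — the crest of a
    grey-level transition) and its magnitude clears either threshold:

    * the per-block histogram quantile ``percentile_thr`` (32x32 blocks),
      the size budget that keeps the final search region near ~2% of the
      field of view; or
    * ``local_dominance`` times the locally sensitive reference A (the
      maximum magnitude over a ``dominance_window`` neighbourhood).  Wide
      vessels have gentle slopes, so in a block shared with a strong edge
      their walls would never clear the block histogram; local dominance
      admits any crest that is the strongest structure in its own
      neighbourhood.

    ``rim_margin`` erodes the FOV before candidacy: the step between retina
    and frame produces the strongest gradients in the image and would
    otherwise dominate every rim block's histogram.
    """
    mag = fld.mag
    fov = fld.fov_mask
    if rim_margin > 0:
        fov = ndimage.binary_erosion(fov, iterations=rim_margin)
    if percentile_thr <= 0.0:
        thr = np.full(mag.shape, -np.inf)  # vacuous budget: NMS alone decides
    else:
        thr = _block_threshold(mag, fov, block, percentile_thr)
    if local_dominance is not None and 0 < local_dominance <= 1:
        A = ndimage.maximum_filter(mag, size=dominance_window, mode="nearest")
        thr = np.minimum(thr, np.maximum(local_dominance * A, 1e-12))

    yy, xx = np.mgrid[: mag.shape[0], : mag.shape[1]].astype(np.float64)
    uy, ux = fld.unit_dir[..., 0], fld.unit_dir[..., 1]
    fwd = ndimage.map_coordinates(mag, [yy + uy, xx + ux], order=1, mode="nearest")
    bwd = ndimage.map_coordinates(mag, [yy - uy, xx - ux], order=1, mode="nearest")
    nms = (mag >= fwd) & (mag >= bwd)

    return fov & fld.defined & nms & (mag > thr)


# ---------------------------------------------------------------------------
# 2. antiparallel pairing
# ---------------------------------------------------------------------------

def _axial_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Absolute difference between axial (mod-pi) angles, in radians."""
    d = np.abs(a - b) % np.pi
    return np.minimum(d, np.pi - d)


def pair_wall_pixels(
    candidates: np.ndarray,
    fld: GradientField,
    width_range: tuple[float, float] = (5.0, 50.0),
    cos_tol: float = float(np.cos(np.deg2rad(160.0))),
    angle_tol: float = np.deg2rad(20.0),
    step: float = 0.5,
    dark_vessels: bool = False,
    max_rounds: int = 3,
    mag_ratio: float = 0.5,
) -> pd.DataFrame:
    """Pair each wall candidate with its antiparallel partner across the vessel.

    From candidate ``a`` the search marches along the gradient direction
    (uphill into the bright vessel; set ``dark_vessels`` to march downhill)
    in sub-pixel steps and accepts the first candidate ``b`` satisfying

    * antiparallel gradients: <unit_dir(a), unit_dir(b)> <= ``cos_tol``;
    * consistent vessel axis: axial orientation difference <= ``angle_tol``;
    * Euclidean distance inside ``width_range``;
    * comparable crest strength: min(|grad a|, |grad b|) >= ``mag_ratio``
      times max(|grad a|, |grad b|) — the two walls of one vessel have
      similar gradient magnitude, whereas a spurious noise crest on the flat
      top of a wide vessel is much weaker than the wall that reached it.

    Proposals are made mutual nearest-first: sorted by distance, a pair is
    kept only while both endpoints are still unpaired, so ``(a, b)`` in the
    result always implies partner(b) = a.  Candidates whose chosen partner
    was claimed by a closer pair re-march in a further round against the
    still-unpaired candidates (``max_rounds`` rounds in total) — on a dense
    crest line the first choice of several neighbouring candidates is often
    the same pixel, and the runner-up partner is equally valid.
    """
    coords = np.argwhere(candidates)
    if coords.size == 0:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    h, w = candidates.shape
    n = len(coords)

    dirs = fld.unit_dir[coords[:, 0], coords[:, 1]]
    if dark_vessels:
        dirs = -dirs
    theta = np.arctan2(
        fld.orientation[coords[:, 0], coords[:, 1], 0],
        fld.orientation[coords[:, 0], coords[:, 1], 1],
    )

    def build_maps(avail: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx_map = np.full((h, w), -1, dtype=np.int64)
        sel = np.flatnonzero(avail)
        idx_map[coords[sel, 0], coords[sel, 1]] = sel
        # crest curves are one pixel thin and step diagonally, so a marching
        # ray can round past them; a one-pixel halo around each candidate
        # catches these near misses (the true coordinates are still used)
        halo_map = idx_map.copy()
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == 0 and dx == 0:
                    continue
                shifted = np.full((h, w), -1, dtype=np.int64)
                ys = slice(max(dy, 0), h + min(dy, 0))
                xs = slice(max(dx, 0), w + min(dx, 0))
                yd = slice(max(-dy, 0), h + min(-dy, 0))
                xd = slice(max(-dx, 0), w + min(-dx, 0))
                shifted[yd, xd] = idx_map[ys, xs]
                halo_map = np.where(halo_map >= 0, halo_map, shifted)
        return idx_map, halo_map

    def march(active: np.ndarray, idx_map: np.ndarray, halo_map: np.ndarray):
        partner = np.full(n, -1, dtype=np.int64)
        dist = np.full(n, np.inf)
        open_idx = active.copy()
        for d in np.arange(max(step, 1.0), width_range[1] + step / 2, step):
            if open_idx.size == 0:
                break
            pos = coords[open_idx] + d * dirs[open_idx]
            ry = np.clip(np.rint(pos[:, 0]).astype(int), 0, h - 1)
            rx = np.clip(np.rint(pos[:, 1]).astype(int), 0, w - 1)
            hit = idx_map[ry, rx]
            hit = np.where(hit >= 0, hit, halo_map[ry, rx])
            ok = (hit >= 0) & (hit != open_idx)
            if ok.any():
                a = open_idx[ok]
                b = hit[ok]
                dvec = coords[b] - coords[a]
                euclid = np.hypot(dvec[:, 0], dvec[:, 1])
                anti = np.einsum("ij,ij->i", dirs[a], fld.unit_dir[coords[b, 0], coords[b, 1]])
                if dark_vessels:
                    anti = -anti
                align = _axial_diff(theta[a], theta[b])
                mag_a = fld.mag[coords[a, 0], coords[a, 1]]
                mag_b = fld.mag[coords[b, 0], coords[b, 1]]
                similar = np.minimum(mag_a, mag_b) >= mag_ratio * np.maximum(mag_a, mag_b)
                good = (
                    (anti <= cos_tol)
                    & (align <= angle_tol)
                    & (euclid >= width_range[0])
                    & (euclid <= width_range[1])
                    & similar
                )
                partner[a[good]] = b[good]
                dist[a[good]] = euclid[good]
                resolved = np.zeros(n, dtype=bool)
                resolved[a[good]] = True
                open_idx = open_idx[~resolved[open_idx]]
        return partner, dist

    used = np.zeros(n, dtype=bool)
    rows = []
    for _ in range(max_rounds):
        avail = ~used
        if avail.sum() < 2:
            break
        idx_map, halo_map = build_maps(avail)
        partner, dist = march(np.flatnonzero(avail), idx_map, halo_map)
        prop = np.flatnonzero(partner >= 0)
        if prop.size == 0:
            break
        order = prop[np.argsort(dist[prop], kind="stable")]
        new_pairs = 0
        for a in order:
            b = partner[a]
            if used[a] or used[b]:
                continue
            used[a] = used[b] = True
            new_pairs += 1
            anti = float(dirs[a] @ fld.unit_dir[coords[b, 0], coords[b, 1]])
            if dark_vessels:
                anti = -anti
            align = float(_axial_diff(theta[a], theta[b]))
            q_anti = (
                np.clip((-anti + cos_tol) / (1.0 + cos_tol), 0.0, 1.0)
                if cos_tol > -1
                else 1.0
            )
            q_align = np.clip(1.0 - align / angle_tol, 0.0, 1.0)
            pair_angle = float(
                np.arctan2(coords[b, 0] - coords[a, 0], coords[b, 1] - coords[a, 1])
            )
            rows.append(
                (
                    int(coords[a, 0]),
                    int(coords[a, 1]),
                    int(coords[b, 0]),
                    int(coords[b, 1]),
                    float(dist[a]),
                    pair_angle,
                    0.5 * (q_anti + q_align),
                )
            )
        if new_pairs == 0:
            break
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


# ---------------------------------------------------------------------------
# 3. Gaussian-similarity inclusion
# ---------------------------------------------------------------------------

def gaussian_similarity(value: float, mu: float, sigma: float) -> float:
    """exp(-(value - mu)^2 / (2 sigma^2)); 1.0 when sigma == 0 and value == mu."""
    dev = value - mu
    if sigma == 0.0:
        return 1.0 if dev == 0.0 else 0.0
    return float(np.exp(-(dev**2) / (2.0 * sigma**2)))


def gaussian_inclusion(
    values: np.ndarray, stats: InclusionStats, n_sigmas: float = 2.0
) -> tuple[float, bool]:
    """Combined inclusion probability and the per-feature two-sigma gate.

    The combined score is the product of the per-feature Gaussian
    similarities (an independence reading of the per-feature kernels); the
    pixel is accepted only if *every* feature deviation is within
    ``n_sigmas`` local standard deviations.  A zero-sigma feature with a
    nonzero deviation rejects the pixel (degenerate statistics).
    """
    values = np.asarray(values, dtype=np.float64)
    p = 1.0
    accept = True
    for v, mu, sig, circ in zip(values, stats.mu, stats.sigma, stats.circular):
        dev = float(_axial_diff(np.array(v), np.array(mu))) if circ else abs(v - mu)
        if sig == 0.0:
            if dev != 0.0:
                return 0.0, False
            continue
        p *= float(np.exp(-(dev**2) / (2.0 * sig**2)))
        accept &= dev <= n_sigmas * sig
    return p, bool(accept)


def _local_sums(indicator: np.ndarray, values: np.ndarray, size: int) -> np.ndarray:
    return ndimage.uniform_filter(np.where(indicator, values, 0.0), size=size, mode="constant") * size**2


def inclusion_filter(
    mask: np.ndarray,
    feature_maps: dict[str, np.ndarray],
    window_radius: int = 12,
    n_min: int = 5,
    n_sigmas: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Gaussian-inclusion gate over a paired-pixel mask.

    ``feature_maps`` must contain ``grad_mag``, ``orientation`` (axial
    radians), ``gl`` and ``contrast``.  Local statistics are computed over
    the accepted neighbours inside a ``(2 window_radius + 1)`` window; pixels
    with fewer than ``n_min`` neighbours are deferred (kept, probability
    NaN).  Returns ``(accepted_mask, prob_map, deferred_mask)``.
    """
    size = 2 * window_radius + 1
    cnt = _local_sums(mask, np.ones_like(mask, dtype=np.float64), size)
    cnt_other = np.maximum(cnt - mask, 0.0)  # exclude the pixel itself

    prob = np.full(mask.shape, np.nan)
    within = np.ones(mask.shape, dtype=bool)
    for name in ("grad_mag", "gl", "contrast"):
        v = feature_maps[name]
        s1 = _local_sums(mask, v, size) - np.where(mask, v, 0.0)
        s2 = _local_sums(mask, v**2, size) - np.where(mask, v**2, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = s1 / cnt_other
            var = np.maximum(s2 / cnt_other - mu**2, 0.0)
        sig = np.sqrt(var)
        dev = np.abs(v - mu)
        with np.errstate(invalid="ignore", divide="ignore"):
            term = np.exp(-(dev**2) / (2.0 * var))
        ok_sig = sig > 0
        within &= np.where(ok_sig, dev <= n_sigmas * sig, dev == 0.0)
        term = np.where(ok_sig, term, np.where(dev == 0.0, 1.0, 0.0))
        prob = np.where(np.isnan(prob), term, prob * term)

    # orientation: circular statistics on the doubled angle
    theta2 = 2.0 * feature_maps["orientation"]
    c, s = np.cos(theta2), np.sin(theta2)
    cm = (_local_sums(mask, c, size) - np.where(mask, c, 0.0))
    sm = (_local_sums(mask, s, size) - np.where(mask, s, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.hypot(cm, sm) / cnt_other
        mean2 = np.arctan2(sm, cm)
    R = np.clip(R, 1e-12, 1.0)
    sig_circ = 0.5 * np.sqrt(np.maximum(-2.0 * np.log(R), 0.0))
    dev_circ = 0.5 * np.abs(np.angle(np.exp(1j * (theta2 - mean2))))
    ok_sig = sig_circ > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        term = np.exp(-(dev_circ**2) / (2.0 * sig_circ**2))
    within &= np.where(ok_sig, dev_circ <= n_sigmas * sig_circ, dev_circ == 0.0)
    term = np.where(ok_sig, term, np.where(dev_circ == 0.0, 1.0, 0.0))
    prob = prob * term

    deferred = mask & (cnt_other < n_min)
    accepted = mask & (deferred | within)
    prob = np.where(mask & ~deferred, prob, np.nan)
    return accepted, prob, deferred


# ---------------------------------------------------------------------------
# 4. sparse-pixel pruning
# ---------------------------------------------------------------------------

def prune_sparse(
    mask: np.ndarray,
    mode: str = "region_growing",
    min_size: int = 10,
    max_steps: int = 10,
    support: np.ndarray | None = None,
    min_votes: int = 15,
    window: int = 64,
    angle_halfwidth: float = np.deg2rad(15.0),
) -> np.ndarray:
    """Remove sporadic pixels; never adds any (output is a subset of input).

    ``region_growing``: regions are grown from the mask by at most
    ``max_steps`` 4-connected dilation steps (inside ``support`` when given);
    regions that merge during growth count as one, and a region that
    recruited fewer than ``min_size`` mask pixels is set back to the
    background class.  Growth serves only to measure cluster membership —
    nearby fragments of one wall run pool into one region — so the output
    never gains a pixel.

    ``hough``: per ``window`` x ``window`` tile, a line Hough transform
    restricted to the tile's dominant orientation +/- ``angle_halfwidth``
    keeps only pixels lying within one pixel of an accumulator peak with at
    least ``min_votes`` votes.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    if mode == "region_growing":
        grow_mask = None
        if support is not None:
            grow_mask = np.asarray(support, dtype=bool) | mask
        work = ndimage.binary_dilation(
            mask, structure=FOUR_CONN, iterations=max_steps, mask=grow_mask
        )
        labels, n = ndimage.label(work, structure=FOUR_CONN)
        if n == 0:
            return np.zeros_like(mask)
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(n + 1))
        keep = sizes >= min_size
        return mask & keep[labels]
    if mode == "hough":
        return _hough_prune(mask, window, min_votes, angle_halfwidth)
    raise ValueError(f"unknown prune mode {mode!r}")


def _hough_prune(
    mask: np.ndarray, window: int, min_votes: int, angle_halfwidth: float
) -> np.ndarray:
    from skimage.transform import hough_line, hough_line_peaks

    out = np.zeros_like(mask)
    h, w = mask.shape
    for r0 in range(0, h, window):
        for c0 in range(0, w, window):
            tile = mask[r0 : r0 + window, c0 : c0 + window]
            pts = np.argwhere(tile)
            if len(pts) < min_votes:
                continue
            # dominant axis from directions between nearby pixel pairs —
            # robust to scattered singletons, which form few close pairs
            from scipy.spatial import cKDTree

            close = list(cKDTree(pts).query_pairs(2.5))
            if close:
                pairs_arr = np.asarray(close)
                diffs = pts[pairs_arr[:, 1]] - pts[pairs_arr[:, 0]]
                ang2 = 2.0 * np.arctan2(diffs[:, 0], diffs[:, 1])
                axis_angle = 0.5 * np.arctan2(np.sin(ang2).sum(), np.cos(ang2).sum())
            else:
                centred = pts - pts.mean(axis=0)
                cov = centred.T @ centred
                _evals, evecs = np.linalg.eigh(cov)
                axis = evecs[:, np.argmax(_evals)]
                axis_angle = np.arctan2(axis[0], axis[1])
            normal = axis_angle + np.pi / 2  # hough theta is the line normal
            thetas = np.linspace(
                normal - angle_halfwidth, normal + angle_halfwidth, 31
            )
            acc, angles, dists = hough_line(tile, theta=thetas)
            peaks = hough_line_peaks(acc, angles, dists, threshold=min_votes)
            keep = np.zeros(tile.shape, dtype=bool)
            for votes, ang, rho in zip(*peaks):
                # pixels within 1 px of the line rho = x cos + y sin
                yy, xx = pts[:, 0], pts[:, 1]
                d = np.abs(xx * np.cos(ang) + yy * np.sin(ang) - rho)
                sel = pts[d <= 1.0]
                keep[sel[:, 0], sel[:, 1]] = True
            out[r0 : r0 + window, c0 : c0 + window] = keep
    return mask & out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _texture_map(img: GreyImage) -> np.ndarray:
    """Mean absolute grey-level difference to the 8-neighbourhood."""
    gl = img.pixels
    acc = np.zeros_like(gl)
    cnt = 0
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            acc += np.abs(gl - np.roll(np.roll(gl, dy, axis=0), dx, axis=1))
            cnt += 1
    return acc / cnt


def _contrast_map(img: GreyImage, block: int = 8) -> np.ndarray:
    """Local grey-level range (max - min) over a block x block window."""
    mx = ndimage.maximum_filter(img.pixels, size=block, mode="nearest")
    mn = ndimage.minimum_filter(img.pixels, size=block, mode="nearest")
    return mx - mn


def build_wall_map(
    img: GreyImage,
    fld: GradientField,
    percentile_thr: float = 0.90,
    block: int = 32,
    rim_margin: int = 10,
    local_dominance: float = 0.85,
    dominance_window: int = 17,
    width_range: tuple[float, float] = (5.0, 50.0),
    cos_tol: float = float(np.cos(np.deg2rad(160.0))),
    angle_tol: float = np.deg2rad(20.0),
    inclusion_radius: int = 12,
    min_size: int = 10,
    prune_mode: str = "region_growing",
    max_steps: int = 10,
    dark_vessels: bool = False,
    compute_scope: bool = False,
) -> WallPixelMap:
    """Run candidate selection, pairing, inclusion and pruning end to end.

    The returned mask contains only pixels that were paired, passed the
    Gaussian-inclusion gate and survived pruning; the pair table is filtered
    down to pairs whose two endpoints both remain in the mask.
    """
    from .gradients import gradient_strength, orientation_scope

    cand = candidate_wall_pixels(
        fld, percentile_thr=percentile_thr, block=block, rim_margin=rim_margin,
        local_dominance=local_dominance, dominance_window=dominance_window,
    )
    pairs = pair_wall_pixels(
        cand, fld, width_range=width_range, cos_tol=cos_tol,
        angle_tol=angle_tol, dark_vessels=dark_vessels,
    )

    paired = np.zeros(img.shape, dtype=bool)
    if not pairs.empty:
        paired[pairs.ay, pairs.ax] = True
        paired[pairs.by, pairs.bx] = True

    features = {
        "grad_mag": fld.mag,
        "orientation": fld.angle() % np.pi,
        "gl": img.pixels,
        "contrast": _contrast_map(img),
    }
    accepted, prob, _deferred = inclusion_filter(
        paired, features, window_radius=inclusion_radius
    )
    pruned = prune_sparse(
        accepted, mode=prune_mode, min_size=min_size, max_steps=max_steps
    )

    if not pairs.empty:
        keep = pruned[pairs.ay, pairs.ax] & pruned[pairs.by, pairs.bx]
        pairs = pairs[keep].reset_index(drop=True)
    mask = np.zeros(img.shape, dtype=bool)
    if not pairs.empty:
        mask[pairs.ay, pairs.ax] = True
        mask[pairs.by, pairs.bx] = True

    if fld.strength is None:
        gradient_strength(fld)
    feature_vec = {
        "strength": fld.strength,
        "scope": orientation_scope(fld) if compute_scope and fld.scope is None else fld.scope,
        "texture": _texture_map(img),
        "orientation": features["orientation"],
    }
    return WallPixelMap(
        mask=mask,
        pairs=pairs,
        inclusion_prob=np.where(mask, prob, np.nan),
        features=feature_vec,
    )
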