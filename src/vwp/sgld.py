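"""Spatial Grey Level Difference (co-occurrence) statistics.

The SGLD matrix for a displacement vector ``D = (d1, d2)`` tabulates the
joint probability that grey levels ``k1`` and ``k2`` occur at pixel pairs
``p`` and ``p + D``.  Scalar features of this matrix summarise local texture;
scanned over displacement magnitudes taken across the local vessel axis, the
concentration of probability mass near the matrix diagonal reveals the
dominant vessel widths: a pixel on one vessel flank re-encounters the same
grey level on the opposite flank when the displacement equals the width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .image import GreyImage

N_LEVELS = 256

__all__ = [
    "SGLDMatrix",
    "WidthCandidate",
    "compute_sgld",
    "sgld_features",
    "diagonal_concentration",
    "estimate_dominant_widths",
]


@dataclass
class SGLDMatrix:
    """256x256 joint grey-level probability matrix for one displacement."""

    P: np.ndarray
    displacement: tuple[int, int]
    n_pairs: int


@dataclass
class WidthCandidate:
    """A dominant-width estimate from the SGLD displacement scan."""

    width_raw: float
    width_snapped: int
    score: float
    confident: bool


def compute_sgld(
    img: GreyImage,
    displacement: tuple[int, int],
    region: np.ndarray | None = None,
    levels: int = N_LEVELS,
) -> SGLDMatrix:
    """Pair-counting SGLD matrix for one displacement vector.

    A pair contributes iff both endpoints lie inside the FOV (and the first
    endpoint inside ``region`` when given).  ``levels`` optionally requantises
    the 256 grey levels down (e.g. to 64) to trade grey resolution for pair
    statistics; the matrix is always 256-level indexed unless requantised.
    """
    d1, d2 = int(displacement[0]), int(displacement[1])
    h, w = img.shape
    if abs(d1) >= h or abs(d2) >= w:
        raise ValueError(f"displacement {displacement} exceeds image extent {img.shape}")

    gl = img.to_uint8()
    if levels != N_LEVELS:
        gl = (gl.astype(np.int64) * levels // N_LEVELS).astype(np.int64)
    else:
        gl = gl.astype(np.int64)

    valid = img.fov_mask.copy()
    if region is not None:
        valid &= np.asarray(region, dtype=bool)

    # crop so that p and p + D are both in-frame
    r0, r1 = max(0, -d1), min(h, h - d1)
    c0, c1 = max(0, -d2), min(w, w - d2)
    a = gl[r0:r1, c0:c1]
    b = gl[r0 + d1 : r1 + d1, c0 + d2 : c1 + d2]
    ok = valid[r0:r1, c0:c1] & img.fov_mask[r0 + d1 : r1 + d1, c0 + d2 : c1 + d2]

    idx = a[ok] * levels + b[ok]
    counts = np.bincount(idx, minlength=levels * levels).reshape(levels, levels)
    n = int(counts.sum())
    P = counts / n if n else counts.astype(np.float64)
    return SGLDMatrix(P=P.astype(np.float64), displacement=(d1, d2), n_pairs=n)


def sgld_features(m: SGLDMatrix) -> dict[str, float]:
    """Scalar texture features of an SGLD matrix.

    ``energy`` is the sum of squared probabilities, ``entropy`` the Shannon
    entropy in nats (0 log 0 = 0), ``mean``/``variance`` the average of the
    two marginal moments, ``correlation`` the grey-level correlation between
    the pair endpoints, and ``mean_gl_difference`` the expected absolute
    grey-level difference E|k1 - k2| (the grey-level-difference reading of
    the "mean observed distance" descriptor).
    """
    P = m.P
    n = P.shape[0]
    k = np.arange(n, dtype=np.float64)
    p1 = P.sum(axis=1)
    p2 = P.sum(axis=0)
    mu1, mu2 = float(p1 @ k), float(p2 @ k)
    var1 = float(p1 @ (k - mu1) ** 2)
    var2 = float(p2 @ (k - mu2) ** 2)
    cov = float(k @ P @ k) - mu1 * mu2
    denom = np.sqrt(var1 * var2)
    correlation = cov / denom if denom > 0 else 0.0

    nz = P[P > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    diff = np.abs(k[:, None] - k[None, :])
    return {
        "mean": 0.5 * (mu1 + mu2),
        "energy": float((P**2).sum()),
        "correlation": correlation,
        "variance": 0.5 * (var1 + var2),
        "entropy": entropy,
        "mean_gl_difference": float((P * diff).sum()),
    }


def diagonal_concentration(m: SGLDMatrix, delta: int = 16) -> float:
    """Probability mass within ``delta`` grey levels of the matrix diagonal.

    High values mean the displaced pixel usually shows nearly the same grey
    level as the origin pixel ("same tissue re-encountered").
    """
    n = m.P.shape[0]
    k = np.arange(n)
    band = np.abs(k[:, None] - k[None, :]) <= delta
    return float(m.P[band].sum())


def _dominant_normal(field, region: np.ndarray) -> float:
    """Angle of the dominant gradient direction (normal to the vessels)."""
    theta2 = 2.0 * np.arctan2(field.unit_dir[..., 0], field.unit_dir[..., 1])
    w = field.mag * region
    c = float((w * np.cos(theta2)).sum())
    s = float((w * np.sin(theta2)).sum())
    return 0.5 * np.arctan2(s, c)


def estimate_dominant_widths(
    img: GreyImage,
    region: np.ndarray,
    field=None,
    d_magnitudes: tuple[int, int] = (2, 30),
    angle: float | None = None,
    candidate_set: tuple[int, ...] = (16, 32, 64),
    delta: int = 16,
    prominence: float = 0.05,
    min_score: float = 0.15,
    min_margin: float = 0.1,
    top_k: int = 3,
) -> list[WidthCandidate]:
    """Scan displacement magnitudes across the vessels for dominant widths.

    ``region`` should mark high-gradient (flank) pixels: those are the pixels
    whose grey level recurs exactly one vessel-width away on the opposite
    flank, so the diagonal concentration of the SGLD matrix, as a function of
    displacement magnitude along the vessel normal, peaks at the dominant
    widths.  Interior peaks of that score curve (prominence-filtered, above
    ``min_score`` and standing at least ``min_margin`` above the curve's
    median — textureless noise produces a flat curve whose jitter peaks
    carry no such margin) are snapped to the nearest member of
    ``candidate_set``;
    a candidate more than 25% away from its snap target carries
    ``confident=False``.  An empty list means no width dominates (e.g. pure
    noise).
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        return []
    if angle is None:
        if field is None:
            raise ValueError("need either an explicit angle or a gradient field")
        angle = _dominant_normal(field, region)
    direction = np.array([np.sin(angle), np.cos(angle)])  # (row, col)

    mags = np.arange(d_magnitudes[0], d_magnitudes[1] + 1)
    scores = np.empty(mags.shape, dtype=np.float64)
    for i, mnt in enumerate(mags):
        d = np.rint(mnt * direction).astype(int)
        if d[0] == 0 and d[1] == 0:
            d = np.array([0, mnt])
        m = compute_sgld(img, (int(d[0]), int(d[1])), region=region)
        scores[i] = diagonal_concentration(m, delta=delta)

    peaks, _ = find_peaks(scores, prominence=prominence)
    floor = max(min_score, float(np.median(scores)) + min_margin)
    out: list[WidthCandidate] = []
    order = np.argsort(scores[peaks])[::-1]
    for j in order[:top_k]:
        p = peaks[j]
        score = float(scores[p])
        if score < floor:
            continue
        raw = float(mags[p])
        snapped = int(min(candidate_set, key=lambda c: abs(c - raw)))
        confident = abs(snapped - raw) <= 0.25 * raw
        out.append(WidthCandidate(raw, snapped, score, confident))
    return out
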