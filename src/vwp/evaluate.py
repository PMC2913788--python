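"""Pixel-wise detection statistics and ROC analysis.

Sensitivity SE = TP/(TP+FN) and specificity SP = TN/(FP+TN) are counted
over FOV pixels only.  ROC curves sweep the detector's two decisive
parameters — the local pairing-area radius r_L and the relative response
threshold th_MFR — and are summarised by the reliability D, the area
between the achieved curve SE = f(SP) and the chance diagonal SE = 1 - SP:
0 for a chance detector, 0.5 for a perfect one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import VesselMap, guided_detect
from .image import GreyImage
from .wall import WallPixelMap

__all__ = [
    "ROCCurve",
    "confusion",
    "se_sp",
    "roc_sweep",
    "reliability",
    "site_accounting",
    "plot_roc",
]


@dataclass
class ROCCurve:
    points: pd.DataFrame  # columns sp, se, r_l, th_mfr

    def sorted_points(self) -> pd.DataFrame:
        return self.points.sort_values("sp", kind="stable").reset_index(drop=True)


def confusion(
    pred: np.ndarray | VesselMap,
    gt: np.ndarray,
    fov: np.ndarray,
    tolerant: bool = False,
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) over FOV pixels.

    With ``tolerant`` the ground truth is dilated by one pixel before FP
    counting, absorbing the +-1 px localisation ambiguity of expert-drawn
    reference masks; off by default.
    """
    if isinstance(pred, VesselMap):
        pred = pred.vp_mask
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    fov = np.asarray(fov, dtype=bool)
    if pred.shape != gt.shape or pred.shape != fov.shape:
        raise ValueError("shape mismatch")
    if not fov.any():
        raise ValueError("empty FOV")
    gt_fp = gt
    if tolerant:
        from scipy import ndimage

        gt_fp = ndimage.binary_dilation(gt)
    tp = int((pred & gt & fov).sum())
    fn = int((~pred & gt & fov).sum())
    fp = int((pred & ~gt_fp & fov).sum())
    tn = int(fov.sum()) - tp - fn - fp
    return tp, fp, tn, fn


def se_sp(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float]:
    """Sensitivity and specificity; NaN when a denominator vanishes."""
    se = tp / (tp + fn) if (tp + fn) else float("nan")
    sp = tn / (fp + tn) if (fp + tn) else float("nan")
    return se, sp


def roc_sweep(
    img: GreyImage,
    wall: WallPixelMap,
    bank,
    gt: np.ndarray,
    grid: list[tuple[float, float]],
    tolerant: bool = False,
    detect_fn=None,
    **detect_kwargs,
) -> ROCCurve:
    """One (SP, SE) point per (r_L, th_MFR) parameter pair.

    The matched-filter responses depend on neither parameter, so they are
    computed once and re-thresholded across the grid.  Points whose SE or
    SP is undefined (degenerate ground truth) are flagged and excluded.
    ``detect_fn`` defaults to guided detection; pass
    :func:`vwp.detect.full_scan_detect` (wall is then ignored) to sweep the
    full-scan baseline.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    mfr = None
    rows = []
    for r_l, th in grid:
        if detect_fn is None:
            vm, mfr = guided_detect(
                img, wall, bank, th_mfr=th, r_l=int(r_l), mfr=mfr, **detect_kwargs
            )
        else:
            vm, mfr = detect_fn(img, bank, th_mfr=th, r_l=int(r_l), mfr=mfr, **detect_kwargs)
        se, sp = se_sp(*confusion(vm, gt, img.fov_mask, tolerant=tolerant))
        if np.isnan(se) or np.isnan(sp):
            continue
        rows.append((sp, se, r_l, th))
    return ROCCurve(points=pd.DataFrame(rows, columns=["sp", "se", "r_l", "th_mfr"]))


def reliability(roc: ROCCurve | pd.DataFrame | list) -> float:
    """Area between the achieved SE = f(SP) curve and the chance diagonal.

    The curve is extended to the conventional endpoints (SP=0, SE=1) and
    (SP=1, SE=0), deduplicated per SP by the best SE, sorted, and
    trapezoid-integrated; the chance-triangle area (1/2) is subtracted, so
    a perfect detector scores 0.5 and the diagonal SE = 1 - SP scores 0.
    Invariant to the ordering of the input points.
    """
    if isinstance(roc, ROCCurve):
        pts = roc.points[["sp", "se"]].to_numpy(dtype=float)
    elif isinstance(roc, pd.DataFrame):
        pts = roc[["sp", "se"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(roc, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        raise ValueError("need at least two ROC points")
    pts = np.vstack([pts, [[0.0, 1.0], [1.0, 0.0]]])
    df = pd.DataFrame(pts, columns=["sp", "se"]).groupby("sp", as_index=False).max()
    sp = df.sp.to_numpy()
    se = df.se.to_numpy()
    auc = float(np.trapezoid(se, sp))
    return auc - 0.5


def plot_roc(curves: dict[str, "ROCCurve"], path) -> None:
    """Write an SE-vs-SP plot of one or more labelled ROC curves to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, curve in curves.items():
        pts = curve.sorted_points()
        ax.plot(pts.sp, pts.se, "o-", label=f"{label} (D={reliability(curve):.3f})")
    ax.plot([0, 1], [1, 0], "k:", lw=1, label="chance")
    ax.set_xlabel("specificity SP")
    ax.set_ylabel("sensitivity SE")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def site_accounting(guided, full, fov: np.ndarray) -> dict:
    """Guided-vs-full convolution-site report.

    ``guided``/``full`` may be MFR fields or raw site counts; ``full`` may
    be None, in which case the full-scan count is the FOV pixel count (a
    full scan evaluates every FOV pixel by construction).
    """
    fov = np.asarray(fov, dtype=bool)
    g = guided if isinstance(guided, int) else guided.sites_evaluated
    if full is None:
        f = int(fov.sum())
    else:
        f = full if isinstance(full, int) else full.sites_evaluated
    return {
        "full_sites": int(f),
        "guided_sites": int(g),
        "ratio": g / f if f else 0.0,
        "mask_fraction": g / int(fov.sum()) if fov.any() else 0.0,
    }
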