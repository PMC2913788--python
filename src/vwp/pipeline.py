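"""End-to-end pipeline: preprocess -> {gradients, SGLD} -> wall map -> MF -> detect.

Mirrors the two-branch flow of the method: the enhanced image feeds both the
gradient-feature branch and the displacement/texture branch; their outputs
meet in the wall-pixel map, which tunes and guides the matched-filter bank;
evaluation runs when ground truth is available.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .detect import full_scan_detect, guided_detect
from .evaluate import confusion, se_sp, site_accounting
from .filters import make_bank
from .gradients import compute_gradient, gradient_strength
from .image import GreyImage, save_image, save_mask
from .preprocess import correct_illumination, fov_ellipse_mask, smooth
from .sgld import estimate_dominant_widths
from .wall import build_wall_map

log = logging.getLogger("vwp")

__all__ = ["run_pipeline", "preprocess_image", "candidate_bank_widths"]


def preprocess_image(img: GreyImage, cfg: PipelineConfig) -> GreyImage:
    out = fov_ellipse_mask(img) if img.fov_mask.all() else img
    out = smooth(out, cfg.preprocess.kernel_size)
    out = correct_illumination(out, background_sigma=cfg.preprocess.background_sigma)
    log.info("preprocess: shape=%s kernel=%d", out.shape, cfg.preprocess.kernel_size)
    return out


def candidate_bank_widths(img: GreyImage, region: np.ndarray, fld, cfg: PipelineConfig) -> list[float]:
    """Dominant widths from the SGLD scan, falling back to the configured set."""
    cands = estimate_dominant_widths(
        img, region, field=fld,
        d_magnitudes=cfg.sgld.d_range,
        candidate_set=cfg.sgld.candidate_widths,
        delta=cfg.sgld.delta,
    )
    widths = sorted({c.width_snapped for c in cands})
    if not widths:
        widths = sorted(cfg.sgld.candidate_widths)
    log.info("sgld: candidate widths %s", widths)
    return [float(w) for w in widths]


def run_pipeline(
    image: str | Path | GreyImage,
    config: PipelineConfig | None = None,
    gt: np.ndarray | None = None,
    outdir: str | Path | None = None,
    full_scan: bool = False,
) -> dict:
    """Run the whole detector; returns the report dict (and writes artifacts).

    The report carries the evaluated-site accounting, the wall-mask
    fraction of the FOV, and — when ground truth is given — SE/SP.
    """
    cfg = config or PipelineConfig()
    if isinstance(image, (str, Path)):
        from .image import load_image

        img0 = load_image(image, channel=cfg.preprocess.channel)
    else:
        img0 = image

    img = preprocess_image(img0, cfg)
    fld = compute_gradient(img)
    gradient_strength(fld, neighborhood=cfg.gradient.neighborhood,
                      deviation_form=cfg.gradient.deviation_form)

    wall = build_wall_map(
        img, fld,
        percentile_thr=cfg.wall.percentile_thr,
        block=cfg.wall.block,
        rim_margin=cfg.wall.rim_margin,
        local_dominance=cfg.wall.local_dominance,
        dominance_window=cfg.wall.dominance_window,
        width_range=cfg.wall.width_range,
        cos_tol=cfg.wall.cos_tol,
        angle_tol=cfg.wall.angle_tol,
        inclusion_radius=cfg.wall.inclusion_radius,
        min_size=cfg.wall.min_size,
        prune_mode=cfg.wall.prune_mode,
        max_steps=cfg.wall.max_steps,
        dark_vessels=cfg.wall.dark_vessels,
    )
    fov_n = int(img.fov_mask.sum())
    log.info("wall: %d mask px (%.3f%% of FOV), %d pairs",
             wall.mask.sum(), 100 * wall.mask.sum() / fov_n, wall.n_pairs)

    widths = candidate_bank_widths(img, wall.mask | _seed_region(wall), fld, cfg)
    bank = make_bank(
        widths, n_angles=cfg.mf.n_angles, n_scales=cfg.mf.n_scales,
        elongation=cfg.mf.elongation, mode=cfg.mf.mode, sided=cfg.mf.sided,
        as_printed=cfg.mf.as_printed,
    )

    if full_scan:
        vm, mfr = full_scan_detect(img, bank, th_mfr=cfg.detect.th_mfr, r_l=cfg.detect.r_l)
    else:
        vm, mfr = guided_detect(
            img, wall, bank,
            th_mfr=cfg.detect.th_mfr, r_l=cfg.detect.r_l,
            max_bad_fraction=cfg.detect.max_bad_fraction,
            site_mode=cfg.detect.site_mode, gap_max=cfg.detect.gap_max,
            grow_steps=cfg.detect.grow_steps,
            smoothing_sigma=cfg.preprocess.kernel_size / 4.0,
        )
    log.info("detect(%s): %d sites, %d vessel px", vm.provenance,
             mfr.sites_evaluated, vm.vp_mask.sum())

    report = {
        "provenance": vm.provenance,
        "config": cfg.to_dict(),
        "bank_widths": widths,
        "wall_mask_px": int(wall.mask.sum()),
        "wall_mask_fraction": wall.mask.sum() / fov_n,
        "n_pairs": int(wall.n_pairs),
        "vp_px": int(vm.vp_mask.sum()),
        "unresolved_regions": int(len(vm.unresolved)),
        **site_accounting(mfr, None if not full_scan else mfr, img.fov_mask),
    }
    if gt is not None:
        tp, fp, tn, fn = confusion(vm, gt, img.fov_mask, tolerant=cfg.eval.tolerant)
        se, sp = se_sp(tp, fp, tn, fn)
        report.update({"tp": tp, "fp": fp, "tn": tn, "fn": fn, "se": se, "sp": sp})

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_image(outdir / "preprocessed.png", img)
        save_mask(outdir / "wall_mask.png", wall.mask)
        save_mask(outdir / "vp_mask.png", vm.vp_mask)
        save_mask(outdir / "centerline.png", vm.centerline)
        wall.pairs.to_csv(outdir / "pairs.csv", index=False)
        ys, xs = np.nonzero(vm.width_map)
        import pandas as pd

        pd.DataFrame({"y": ys, "x": xs, "width": vm.width_map[ys, xs]}).to_csv(
            outdir / "width_map.csv", index=False
        )
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report


def _seed_region(wall) -> np.ndarray:
    from scipy import ndimage

    return ndimage.binary_dilation(wall.mask, iterations=2)
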