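# Methods

This note records what the package computes, the modelling assumptions
behind it, the defaults that matter, and where the approach is known to be
fragile. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`.

## Problem and approach

Pixel-wise vessel segmentation in fundus photographs is usually done by
correlating the image with banks of oriented, vessel-shaped kernels at every
pixel, every angle and every scale (maximum-intensity-projection style).
That cost is dominated by pixels that carry no vessel evidence at all. The
package splits detection in two: a coarse stage finds **vessel wall pixels**
(VWPs) — gradient crest pixels that can be *paired* with an antiparallel
partner across the vessel — and a fine stage runs the matched-filter bank
only at the sites that coarse stage licenses. Pairing is the load-bearing
idea: isolated strong edges are abundant in retinal images, but two crests
facing each other at a plausible vessel width, with consistent local
orientation and comparable strength, almost always bound a vessel.

## Synthetic scenes and the width convention

The generator (`vwp.synthetic`) renders: an elliptical FOV inscribed in the
frame; `n_vessels` smooth cubic-spline centrelines with bounded curvature
(waypoints along a random chord of the FOV with perpendicular jitter ≤ 12 %
of the chord); per-vessel widths log-uniform in `width_range` (many narrow,
few wide — the realistic mix); a constant background (90 GL) plus a linear
illumination ramp (default amplitude 20 GL); bright drusen-like Gaussian
blobs (default 8, radii 5–20 px, contrast ≤ 40 GL); additive Gaussian noise
(default σ = 5 GL); vessels bright on the darker background (the normalised
polarity the detector assumes; a `dark_vessels` flag flips the pairing
direction for raw green-channel data).

**Width convention.** A vessel's configured width is the distance between
the two inflection points of its cross-section. For the `single_gaussian`
profile this forces `σ_profile = width/2`, so that (a) the ground-truth wall
ring is the locus of maximal gradient and (b) a wall-pair distance estimates
the configured width directly. The `single_sided` profile is a plateau with
sigmoid walls of slope `width/8` centred on the nominal wall; `dual_mode`
sums two offset Gaussians (peaks at ±width/4).

Defaults (605×700, 15 vessels, widths 5–50 px) give a dense, demanding
scene: the ground-truth wall ring alone covers ~5 % of the FOV, more than
twice the budget the wall mask is allowed, so the mask must be selective by
construction.

What the generator does **not** emulate: vessel taper and branching
topology, central light reflex, micro-aneurysms/haemorrhages, optic disc and
fovea, camera vignetting beyond a linear ramp, and sensor noise correlation.
Passing tests therefore demonstrate the geometry/texture machinery, not
robustness to every retinal confounder.

## Preprocessing

Gaussian smoothing specified by its truncation window (8×8 … 32×32) with
`σ = window/4`; illumination correction subtracts a wide normalised-Gaussian
background estimate (default σ = 50 px ≥ 4× the widest vessel), re-centres
on the FOV mean and clips beyond ±3 global standard deviations. All
statistics anywhere in the pipeline are FOV-restricted. Candidate selection
additionally ignores a 10-px rim inside the FOV ellipse, where the
retina/frame step otherwise dominates every local gradient histogram.

## Wall-pixel mask

1. **Candidates.** 1-D non-maximum suppression along the gradient direction
   (bilinear sampling at ±1 px) intersected with an adaptive threshold: the
   per-32×32-block 90th-percentile of gradient magnitude, **or** local
   dominance — magnitude ≥ 0.85 × the maximum over a 17-px window. The
   percentile is the mask's size budget; local dominance exists because wide
   vessels have gentle slopes (peak slope ∝ contrast/σ) and would otherwise
   lose every block histogram they share with a strong narrow vessel.
2. **Pairing.** From each candidate, march uphill along the gradient in
   0.5-px steps (a 1-px halo catches rounding misses on diagonal crests) and
   accept the first candidate with antiparallel gradient (within 20°),
   consistent axial orientation (within 20°), distance in 5–50 px, and
   comparable crest strength (magnitude ratio ≥ 0.5 — this last condition
   removes spurious partners from noise crests on wide-vessel tops, which
   otherwise bias widths low). Pairs are made mutual nearest-first; losers
   re-march against the still-unpaired set for up to 3 rounds, because on a
   dense crest line several neighbours often choose the same first partner.
3. **Inclusion.** Per-pixel Gaussian similarity of {gradient magnitude,
   orientation (axial, circular statistics), grey level, 8×8 contrast}
   against the statistics of paired neighbours within 12 px; the combined
   score is the product (independence reading) and acceptance requires every
   deviation ≤ 2σ. At 2σ a single factor equals `exp(−2) ≈ 0.135` (a
   published account rounds this to 1/(2e) ≈ 0.184; we use the exact value).
   Pixels with fewer than 5 neighbours are retained but flagged.
4. **Pruning.** Regions grow from the mask by ≤ 10 4-connected dilation
   steps; a region that recruits fewer than `min_size = 10` mask pixels goes
   back to background. A windowed Hough alternative (64×64 tiles, dominant
   axis ±15°, ≥ 15 votes, ±1 px) is available but off by default.

With these defaults the fundus-scale mask lands at 1.5–1.9 % of the FOV
across seeds, inside the ~2 % design budget, carrying 2–3 k wall pairs.

## Matched filters

The kernel in the vessel frame is an amplitude-modulated Gaussian:
`K ∝ (u²−a_u²)(v²−a_v²) exp(−(u²/2σ_u² + v²/2σ_v²))` on a disk of radius
`D`, zero outside, then mean-subtracted over the support (flat background ⇒
exactly zero response) and scaled to unit L2 norm divided by √(2a_u+1): a
unit-norm elongated template on a straight ridge responds ∝ √length, and the
division makes the scales of one bank comparable. The published form of
this kernel centres the Gaussian at scale- or offset-dependent points; both
literal variants are preserved behind `as_printed` / `support_as_printed`
flags, but the default centres envelope and support on the evaluated site —
the offsets' role is to place the zero crossings (at `|u| = a_u`,
`|v| = a_v`), not to translate the kernel.

Bank defaults per width `w`: `σ_v = w/4`, `σ_u = 2σ_v`, `a_v = w/2`,
`a_u = σ_u`, `D = max(a_u, a_v) + 2σ_v`; 12 angles in [0, 2π), 4 scales
geometric over the SGLD-candidate widths. Dual-mode kernels superpose two
mirrored copies offset by the width; single-sided kernels keep the v ≥ 0
lobe. Note the bank's internal matching scale: the kernel labelled `w` is
maximal on a Gaussian ridge of σ ≈ w/8, so argmax-scale is an ordinal, not
metric, width readout — metric widths come from pair distances.

`convolve_at` evaluates the bank only at caller-given sites (patch
extraction + one matrix product per kernel-size group), bit-identical to a
dense correlation with zero boundary at shared sites; the full scan is the
same engine applied at every FOV pixel.

## Guided detection

Default sites are the wall-pair midpoints (centreline seeds). A seed is
accepted when its maximal response exceeds `th_MFR · μ_MFR` (μ over the
evaluated sites; default `th_MFR = 0.5`) and its grey level lies in
`[½μ_L, 2.5μ_L]`, where μ_L is a local mean over a region whose radius
follows the local grey-level std, floored at 3 px and capped at
min(25, r_L) so the region never degenerates. Accepted pairs promote their
rasterised cross-section (dropped when the segment's dark-pixel fraction
exceeds 0.25, or when the majority of the segment sits on the dark side of
the local background — such pairs bridge background; their pixels may be
reassigned to a neighbouring accepted segment within 2σ of its grey-level
statistics). Midpoints become the centreline; gaps ≤ 5 px are bridged with
linearly interpolated widths; quadrilaterals between adjacent pairs fill the
interior; finally an 8-iteration 4-connected region growing (admission:
grey level ≥ local background mean + 0.5 local std, which keeps background
noise below the percolation threshold) recovers interior pixels the pairing
missed. Widths are reported as `sqrt(d² − (2σ_smooth)²)`, removing the
crest-separation widening caused by the known preprocessing blur. Seeds
that fail any gate are returned as `unresolved` regions rather than handled
interactively.

The full-scan baseline applies the identical gates at every FOV pixel with
the global response mean, and skeletonises its mask for a centreline.

## Evaluation

SE/SP are counted over FOV pixels; ROC sweeps re-threshold one set of
responses over a `(r_L, th_MFR)` grid (responses depend on neither
parameter). The reliability `D` extends the curve to (SP=0, SE=1) and
(SP=1, SE=0), deduplicates per SP by best SE, trapezoid-integrates and
subtracts the chance triangle (½): 0 for the diagonal, 0.5 for a perfect
detector.

## Problem sizes used in the checks

Fundus-scale claims (mask fraction, site counts) use the default 605×700
scene. Width recovery uses twenty 300×300 five-vessel scenes with widths
5–50 and the sigmoid-wall profile — the profile for which wall-to-wall
width is geometrically well defined. ROC comparisons use five 256×256
four-vessel scenes (widths 6–20, noise σ = 3), where guided reliability
averages within 0.05 of (and often above) the full scan's.

## Known limitations

* **Pure-Gaussian width bias.** With `σ_profile = width/2`, the gradient
  crests of wide curved vessels shift inward under centreline curvature and
  illumination correction (≈ −4 px at width 40 even noiseless and
  isolated); pair distances then under-read the nominal width. This is a
  property of that cross-section model, not of the estimator; the effect is
  negligible for plateau-like (sigmoid-wall) profiles.
* Guided sensitivity is bounded by pairing coverage: stretches where one
  wall is occluded (crossings, overlapping tubes, drusen contact) yield no
  seeds and are recovered only as far as region growing reaches.
* The SGLD width scan needs crest-sharp regions (it is fed the candidate
  mask); on smooth flanks the diagonal-concentration peak smears and the
  scan falls back to the configured candidate set {16, 32, 64}.
* Scale selection by bank argmax is octave-accurate only; metric widths
  come from pairs.
* The per-case FFT-domain filtering hook mentioned alongside smoothing in
  the original pipeline description is not implemented.
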