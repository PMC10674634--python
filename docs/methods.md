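# Methods

This note documents the models, numerical choices and limitations behind
`kelpyield`, in the spirit of a methods appendix: what the code assumes,
which knobs matter, and what passing the test suite does and does not show.

## The flat-sheet yield model

Cultivated sugar kelp hangs from a suspended rope line and grows downward;
currents and gravity keep the bundle close to a vertical plane. The package
therefore models the crop as a **flat, fronto-parallel sheet** at a single
range `Z` from the camera. Yield is the sheet's surface area:

    yield_m2 = N_px * (Z / f_h) * (Z / f_v)

with `N_px` the segmented pixel count and `f_h`, `f_v` the focal lengths in
pixels. Consequences of the model:

* One range per frame suffices; we use the median of valid disparities in a
  central crop (600 × 400 px by default — the image center is least
  affected by lens distortion, and the median discards open-water and
  particle pixels without an outlier model). Per-pixel depth weighting is a
  possible extension, deliberately not implemented: it would re-introduce
  sensitivity to exactly the noisy disparities the median was chosen to
  suppress.
* The median is taken in the **disparity domain** and then triangulated,
  not the other way around: disparity noise is approximately symmetric,
  whereas `1/d` skews depth noise. A depth-domain median would differ only
  through that skew; the disparity-domain choice is documented and easy to
  switch in calling code.
* Area in m² is a *proxy* for biomass. Converting to kilograms needs a
  harvest-calibrated density and is out of scope, as is mosaicking
  overlapping frames into a whole-line total.

The camera model is an in-air pinhole with purely horizontal disparity
(`Z = b·f/d`). The reference rig keeps both optical axes orthogonal to the
housing and water interfaces, so refraction is ignored by construction; no
lens distortion or rectification stage is modeled. Pixel coordinates are
0-based, origin top-left; pixel `(i, j)` covers `[i, i+1) × [j, j+1)` with
its center at `(i+0.5, j+0.5)` — the same centers rule is used by the
rasterizer, the renderer and the truth bookkeeping, so they agree exactly.

A framing note: with a 65° vertical field of view, a centered object of
extent `E` first fits the frame at `E / (2·tan(FOV/2))`; for a 4 m plant
that is ≈ 3.14 m. `min_viewing_distance` implements this standard formula.

## Semi-global matching

The disparity stage is the classic three-step pipeline:

1. **Cost**: sum of absolute differences over a square block (default 16 px,
   matching the field configuration; the block of size `b` centered at `x`
   spans `[x-(b-1)//2, x+b//2]`, clipped at borders). Candidates reading
   outside the right image get a sentinel cost (4000 per block pixel) that
   strictly dominates any legitimate SAD, so they are never selected when
   an in-bounds candidate exists.
2. **Aggregation**: for each of `n_paths` scan directions (default 8),
   the 1-D recurrence
   `L_r(p,d) = C(p,d) + min(L_r(p-r,d), L_r(p-r,d±1)+P1, min_k L_r(p-r,k)+P2) − min_k L_r(p-r,k)`,
   summed over directions.
3. **Selection**: per-pixel argmin (ties break to the lowest disparity),
   three-point subpixel refinement, and validity tests.

Numerical/parameter choices that matter:

* **Penalties.** `P1 = 2·b²`, `P2 = 8·b²` by default. This is deliberately
  gentler than the widely used `8/32` scaling: at the 1–4 m working range
  the true disparities are small (5–20 px) and fractional, and strong
  penalties flatten the aggregated cost curvature around the minimum,
  locking the subpixel estimate onto integers. Measured on synthetic
  scenes, the median-disparity bias drops from ≈ 0.4 px to ≤ 0.1 px with
  the gentler scaling.
* **Subpixel method.** Default is the *equiangular* (symmetric-V) fit,
  `(c₋ − c₊) / (2·(max(c₋,c₊) − c₀))`, which is unbiased when the cost is
  piecewise linear in disparity — as SAD is. The parabola vertex fit is
  available as `subpixel_method="parabola"`. Offsets are clipped to ±0.5.
* **Validity.** Three independent tests, all carried in an explicit flag
  (`d = 0` stays a legal value; no sentinel disparities):
  * sentinel threshold — no in-bounds candidate at all;
  * uniqueness — the best cost must undercut the runner-up (excluding
    immediate neighbors) by a configurable ratio (default 10 %);
  * **data support** — the winner's *raw* (pre-aggregation) cost must
    undercut the median raw cost across fully-in-bounds candidates by a
    margin (default 2 gray levels per block pixel). This test exists
    because path aggregation happily extends a surface's disparity across
    featureless open water; the streaked pixels look confident in the
    aggregated volume but have no image evidence, and without this test
    they bias the scene median whenever the crop is mostly water.
  An approximate left-right consistency check (re-reading the cost volume
  from the right view) is available but off by default.
* **Search range.** The generic default is 0–48 px; runs on the synthetic
  camera use 0–24 px, which covers the 1.5–3.5 m band with margin
  (d = b·f/Z ∈ [7.7, 17.9] px).

## Synthetic scenes

The generator emulates what the monitoring rig sees, with exact ground
truth; its defaults are the nominal study conditions:

| parameter | default | meaning |
| --- | --- | --- |
| camera | 480×360 px, f = 282.5 px, b = 95 mm | 65° vertical FOV at desk-scale resolution |
| sheet depth | uniform 1.5–3.5 m | working band of the rig |
| visible sheet area | 0.5–6 m² | fill fraction of the frame at depth |
| attenuation β | uniform 0–0.3 /m | turbidity haze |
| airlight | 170 (8-bit) | green-blue veiling intensity |
| sensor noise σ | uniform 0–5 gray levels | additive Gaussian, clipped |
| texture | band-limited noise, σ = 30, clipped ±2σ | vertical ribbon streaks |

Haze follows `I = J·exp(−βZ) + A·(1 − exp(−βZ))`; open water (no depth) is
pure airlight plus noise and carries no valid disparity, which exercises
invalid-pixel handling downstream. Sheet texture is sampled in *world*
coordinates, so the two stereo views see the identical pattern at
sub-pixel-consistent positions and a sheet at depth `Z` carries the exact
disparity `b·f/Z`. Sheets are fronto-parallel constant-depth planes;
slanted or billowing sheets are a documented extension. Visible truth area
is computed analytically (projection clipped to the frame, occlusions by
nearer sheets subtracted in the image plane), so end-to-end recovery is
checked against an exact number, not a rasterized approximation. All
randomness flows from one scene seed; per-stage seeds are spawned from it.

What the generator does **not** emulate — and hence what passing tests do
not show about field data: real blade shapes and drape, motion blur and
surface-wave lighting flicker, fouling and rigging distractors, wavelength-
dependent attenuation, or the true texture statistics of kelp. The
classical segmenter exploits the renderer's clean color separation
(red-dominant blades vs blue-green water) and should be read as a
desk-scale stand-in for a trained segmentation model, which plugs in
through the external hook.

## Segmentation and IoU

The classical segmenter thresholds a per-pixel discriminant with Otsu's
method, then applies square-footprint opening+closing (radius 2) and
discards components below 64 px. The default discriminant is `R − B`
(blades are brown, the veiling light blue-green; attenuation shrinks the
gap but never flips its sign), with dark-polarity luminance as an
alternative. A minimum-contrast guard (12 gray levels between class means)
keeps pure open-water frames empty instead of hallucinating structure.

IoU conventions: `iou(∅, ∅) = 1` (perfect agreement on "nothing here"),
`iou(∅, A≠∅) = 0`. Polygons rasterize under the even-odd centers rule;
an axis-aligned W×H rectangle yields exactly W·H pixels. Only the nearest
line's seaweed is foreground; the generator marks sheets beyond a
configurable depth as negative class, mirroring the field labeling policy.

## Error budget and repeatability

`propagate_error(iou, r) = (1 − IoU) + 2r`, linear first-order addition.
Linear (not quadrature) combination is the deliberate choice: the two
error sources are neither independent nor zero-mean in practice, and
linear addition is the conservative bound (quadrature would report ≈ 13 %
at the reference operating point instead of 18.8 %). The segmentation term
uses `1 − IoU` as the relative pixel-count error proxy; the range term is
doubled because area scales as `Z²`.

`repeatability_stats` reports mean, sample standard deviation (ddof = 1),
half-range and a Freedman–Diaconis histogram of any per-frame scalar
series; std and half-range are both reported because "±x %" spread figures
are ambiguous between the two.

## Problem sizes and determinism

Default test and acceptance runs use the 480 × 360 synthetic camera with a
0–24 px search range: 20-scene end-to-end sweeps, 100-frame stationary
series, and exhaustive oracle comparisons on ≤ 16 × 16 pairs with ≤ 8
disparities — sizes chosen so the whole suite runs in minutes on one CPU
while still spanning the full working range. The SGM implementation is
compared pixel-exactly against a loop-based reference on integer-valued
inputs (all intermediate costs are integers in float64, so vectorized and
naive summation agree bit-for-bit). Pipeline runs are deterministic given
config and seed; `yields.csv` is written with fixed float formatting and
reruns are byte-identical.

## Known limitations

* Fronto-parallel single-range assumption: a sheet slanted in depth is
  systematically mis-measured (the flat-sheet model trades this bias for
  robustness).
* The classical segmenter is tuned to the renderer's reflectance model and
  will not transfer to field imagery; it exists to make the pipeline
  testable end to end.
* No de-hazing: at optical depths β·Z ≳ 1.5 contrast compression degrades
  both matching and segmentation.
* The approximate left-right check reuses the left cost volume rather than
  rematching from the right image.
* Whole-farm totals, frame mosaicking/overlap correction, and kg-biomass
  conversion are out of scope.
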