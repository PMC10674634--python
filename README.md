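# kelpyield

Stereo-vision yield estimation for vertically farmed seaweed.

Sugar kelp (*Saccharina latissima*) is grown on rope lines suspended between
buoys; the blades hang downward in a dense, nearly planar bundle up to
several meters long. `kelpyield` estimates the **surface area in m²** of
that hanging sheet from underwater frame sets — one RGB image (for
segmentation) plus a rectified grayscale stereo pair (for range) — giving
farmers a per-frame yield proxy without divers or harvest sampling.

The package is aimed at people building or evaluating underwater
crop-monitoring pipelines: it contains the full processing chain, a
ground-truthed synthetic scene generator so every stage is testable without
field data, and a repeatability/error-budget layer.

## Method

For each frame set:

1. **Segmentation** — a binary seaweed mask from the RGB image, via a
   deterministic classical segmenter (channel-difference threshold +
   morphology), rasterized polygon annotations, or any external model
   plugged in through a file-based hook.
2. **Disparity** — semi-global block matching (SAD block costs, 8-path
   dynamic-programming aggregation with penalties P1/P2, winner-takes-all
   with subpixel refinement, uniqueness and data-support validity tests) on
   the rectified pair.
3. **Range** — the 2-D median of valid disparities inside a central crop,
   triangulated through the pinhole relation

   $$Z = \frac{b\,f}{d}$$

   with baseline $b$ (95 mm for the reference rig), focal length $f$
   (pixels) and disparity $d$ (pixels).
4. **Yield** — the flat-sheet, fronto-parallel conversion

   $$\text{yield} = N_\text{px} \cdot \frac{Z}{f_h}\cdot\frac{Z}{f_v}
   \;[\mathrm{m^2}],$$

   where $N_\text{px}$ is the segmented pixel count.

The first-order error budget combines segmentation quality (IoU) and
relative range precision $r$ linearly, the factor two reflecting the
quadratic range dependence of metric area:

$$\varepsilon = (1 - \mathrm{IoU}) + 2r .$$

At the published operating point (IoU = 0.9, r = 4.4 %) this gives
$\varepsilon = 0.188 \approx 18\%$.

## Worked example

```python
from kelpyield import (
    random_scene, render_stereo_set, compute_disparity, median_scene_distance,
    classical_segment, estimate_yield, propagate_error, SgmParams,
)

scene = random_scene(3)                   # one sheet in the 1.5-3.5 m band
frame = render_stereo_set(scene)
cam = scene.camera

disp = compute_disparity(frame.left_gray, frame.right_gray,
                         SgmParams(disparity_range=(0, 24)))
rng = median_scene_distance(disp, cam, cam.image_size)
mask = classical_segment(frame.rgb_image)
est = estimate_yield(mask, rng.depth_m, cam,
                     rel_error=propagate_error(0.9, 0.044))

print(f"true range   {scene.sheets[0].depth:.3f} m")
print(f"est. range   {rng.depth_m:.3f} m  (median of {rng.median_disparity:.2f} px)")
print(f"true area    {frame.truth_area_m2:.3f} m2")
print(f"est. yield   {est.yield_m2:.3f} m2  ({est.seaweed_px} px)")
```

Output:

```
true range   1.671 m
est. range   1.673 m  (median of 16.04 px)
true area    2.113 m2
est. yield   2.121 m2  (60502 px)
```

The range lands within 2 mm of truth and the yield within 0.4 % — a
noise-free-ish draw; across the nominal study conditions (haze
β ≤ 0.3 /m, sensor noise σ ≤ 5) the median absolute yield error stays
below 5 %.

The same chain is scriptable from the shell:

```sh
kelpyield simulate --out data/ --n-frames 5 --seed 0
kelpyield run --manifest data/manifest.json --out results/
kelpyield repeatability --series results/yields.csv
```

`run` writes `yields.csv` (frame_id, seaweed_px, range_m, yield_m2,
rel_error, flags) and a `report.json` with the full configuration echo;
reruns with the same config and seed are byte-identical.

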