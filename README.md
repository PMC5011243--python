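# lungseg

Accurate lung-field segmentation in single 2D thoracic CT slices by the
integration of multiple simple strategies — for developers of computer-aided
lung-disease diagnosis (CAD) pipelines, where a missed juxtapleural nodule at
the segmentation step is unrecoverable downstream.

No single simple method segments lungs reliably: plain thresholding drops
dense pathology, region growing leaks and roughens edges, and a raw random
walk is exquisitely sensitive to its seeds.  `lungseg` chains six simple
stages so that each covers the others' failure modes:

1. **Guided-filter denoising** — edge-preserving smoothing; the output is a
   local linear transform of the guide, `q_i = a_k I_i + b_k` with
   `a_k = cov(I, p) / (var(I) + ε)` per window (window 15, ε = 0.008 on
   normalized intensities).
2. **Otsu binarization** — threshold `T = argmin_k [ω₀σ₀² + ω₁σ₁²](k)` over
   a 256-bin histogram, keeping the low-density (air/lung) class.
3. **Thorax extraction** — region growing from the four image corners
   removes background air; detached artifacts (scanner bed) are discarded
   and the solid body cross-section retained.
4. **Seeded random walk** — thorax pixels form a graph with edge weights
   `w_ij = exp(−β (g_i − g_j)²)`, β = 90; lung seeds are placed
   automatically at pixels nearest −500 HU, background seeds on the thorax
   boundary and the densest interior pixels; per-label probabilities solve
   the Dirichlet problem `L_u x_u = −B x_m` on the graph Laplacian.
5. **Rolling-ball hole filling** — closes vessel holes in the lung mask.
6. **Curvature-based contour correction** — horizontal scan lines sample
   each lung border; points whose discrete curvature jumps past an adaptive
   (0.9-quantile) threshold are removed and bridged, restoring
   juxtapleural nodules and mediastinal indentations that density-based
   stages exclude.

Evaluation metrics (over-/undersegmentation rate, mean absolute border
distance in mm, overlap ratio, PSNR) and a deterministic synthetic thorax
phantom with pixel-exact ground truth make every stage testable without
clinical data.  See `docs/methods.md` for the full model description.

## Worked example

```python
from lungseg import PhantomSpec, evaluate, generate, segment_lung

ct, truth, _ = generate(PhantomSpec(noise_sd=20.0, seed=42))  # 512x512 slice
result = segment_lung(ct)
report = evaluate(result.mask, truth)
print(result.status, result.mask.area_px())
print(f"over {report.over_pct:.3f}%  under {report.under_pct:.3f}%  "
      f"ABD {report.abd_mm:.3f} mm  overlap {report.overlap_pct:.4f}%")
```

prints

```
ok 52254
over 0.523%  under 0.000%  ABD 0.174 mm  overlap 99.8962%
```

i.e. the final mask contains 52 254 pixels, wrongly includes 0.523% of the
reference lung area, misses none of it, its border lies 0.17 mm from the
reference border on average, and 99.90% of all pixels are classified
correctly.  The `examples/` directory has one narrative script per
capability (phantom anatomy, denoising, thresholding + thorax, random walk,
nodule-recovering refinement, full-battery evaluation).

Clinical slices enter through `read_ct_slice` (single-frame DICOM, HU
recovered from the rescale tags) or as 16-bit rasters with an explicit
`(slope, intercept)` mapping.  A thin CLI wraps the library:

```bash
lungseg phantom --suite --seed 0 --out ph/
lungseg segment ph/clean.png --slope 1 --intercept -1024 --out seg/
lungseg metrics seg/clean_mask.png ph/clean_truth.png --spacing 0.692
lungseg batch ph/clean.png ph/noisy.png --truth ph/clean_truth.png \
    --truth ph/noisy_truth.png --slope 1 --intercept -1024 --out batch_out/
```

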