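# Methods

`lungseg` segments the lung parenchyma in a single 2D axial thoracic CT
slice by chaining six deliberately simple strategies, each robust where the
others are fragile, and evaluates the result with the standard
segmentation measures.  This note records the model behind each stage, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic phantom does and does not establish.

## Pipeline model

**1. Intensity normalization and guided-filter denoising.**  HU values are
clipped to the thoracic window `[-1000, 400]` HU and mapped linearly onto
`[0, 1]`.  Denoising uses the guided filter: within each square window
`w_k` the output is a local linear transform of the guidance image `I`,
`q_i = a_k I_i + b_k`, with coefficients minimizing the ridge-regularized
reconstruction error

    a_k = (mean(I p) - mean(I) mean(p)) / (var(I) + eps),
    b_k = mean(p) - a_k mean(I),

and the final output averaging the coefficients of all windows covering a
pixel.  CT slices are self-guided (`I = p`): homogeneous parenchyma
(variance << eps) is box-averaged, while the high-contrast lung wall
(variance >> eps) passes through with `a ~ 1`.  Defaults: window 15 px,
`eps = 0.008` in squared normalized intensity — `eps` is only meaningful on
the normalized scale, which is why normalization precedes filtering.  Box
means use an integral image over a reflectively padded array (O(N) per
image, no window-size dependence); reflective padding avoids the edge
darkening of zero padding.  Two exact special cases are preserved by
construction: a globally constant image is returned unchanged (fixed
point), and `eps = 0` with self-guidance is the identity on images whose
windows are all nonconstant.  An RGB path (each channel self-guided) is
kept as an API generalization only.

**2. Otsu binarization.**  The denoised slice is histogrammed into L = 256
equal-width bins; the threshold T minimizes the intra-class variance
`w0 s0^2 + w1 s1^2` over all candidate splits (equivalently maximizes the
between-class variance; both argmin sets coincide since the two terms sum
to the total variance).  Ties break toward the smallest bin, empty classes
contribute zero, and a constant image degenerates to level 1 with a
warning.  Polarity: the mask is true for the *low-density* class (air,
lung, airway), because the next stages grow the air background and segment
the low-density lungs.

**3. Thorax extraction.**  External air touches the image corners, so
flood-filling the low-density mask from the four 1-px corner patches
(4-connected by default) recovers the background.  Everything that is not
background is labeled; components that do not overlap the central box
(half of each image dimension) are discarded — this is the rule that drops
the scanner bed, which is detached from the body by an air gap — and the
surviving body outline is hole-filled, so the thorax mask is the solid
body cross-section.  Enclosed holes can never belong to the
corner-connected background, hence thorax and background are provably
disjoint.

**4. Seeded random walk.**  Thorax pixels form a 4-connected graph with
Gaussian edge affinities `w_ij = exp(-beta (g_i - g_j)^2)` on normalized
intensities; `beta = 90` by default and is the stage's main dial (larger
beta hardens density edges; Dice against the intensity-defined region is
non-decreasing in beta on the phantom).  For each label the probability
that a walker reaches that label's seeds first is the harmonic function
solving `L_u x_u = -B x_m` with the combinatorial Laplacian partitioned by
seeded/unseeded nodes; the sparse SPD system is solved by sparse LU, with
probabilities clipped/renormalized only against accumulated floating-point
error.  Connected components holding no seed are assigned background with
a warning.  A pixel becomes lung when its lung probability strictly
exceeds every other label's; exact ties go to background (conservative).

Seeds are automatic, from tissue-density priors: the 3 thorax pixels
closest to the target lung density (default -500 HU, the physical density
of aerated parenchyma), mutually >= 20 px apart, ties toward the smaller
(row, col); each is expanded by its 8 lowest-HU thorax neighbors within a
5 px radius.  Background seeds are the thorax boundary ring plus the 3
highest-HU interior pixels (chest wall/bone).  If no thorax pixel is
within 300 HU of the target, the slice is declared lungless — a status,
not an error.  In the pipeline, seed selection runs on the denoised slice
mapped back to HU, consistent with every other stage operating on the
smoothed image; this also shrinks the noise on seed candidates by the
window averaging.  Known limitation: under heavy noise the greedy pick
with a 20 px separation can land all three initial seeds in one lung;
the seed count, separation and target are all configurable.

**5. Hole filling.**  Morphological closing with a disk (radius 3 px)
followed by filling of enclosed cavities; the result is unioned with the
input, so the stage is superset-monotone and channels to the border wider
than twice the ball radius stay open.

**6. Scan-line curvature correction.**  Each lung component is scanned
every 3 rows; per scanned row the leftmost/rightmost crossings ("first"/
"last") sample the lateral and medial borders, interior crossings
("middle") are dropped.  Each border chain is smoothed by three 1-2-1
weighted-averaging passes, and the discrete curvature

    k_i = [(x_{i-1}-x_i)(y_{i-1}-2y_i+y_{i+1}) - (y_{i-1}-y_i)(x_{i-1}-2x_i+x_{i+1})]
          / ((x_{i-1}-x_i)^2 + (y_{i-1}-y_i)^2)^{3/2}

(x = column, y = row; coincident points return an +inf sentinel) is
evaluated along the smoothed chain.  The adaptive threshold is the 0.9
quantile of the chain's initial absolute curvature-difference
distribution.  Screening is iterated (<= 10 rounds): removing the rim of a
defect exposes its interior — locally smooth for the circular notch a
nodule carves — to large curvature differences against the surviving
neighbors, so repeated rounds peel the whole defect away.  Two guards make
this stable and safe: a candidate is only removable when the chord through
its retained neighbors lies *outward* of it (indentations are bridged,
the naturally high-curvature lung apices are untouched), and the corrected
border never retreats inward of the original chain.  The smoothed chain
serves only curvature estimation; the bridge interpolates through the
actual surviving border points.  The region between corrected chains is
re-filled row-wise with outward (floor/ceil) rounding and unioned with the
input component, so refinement never deletes lung pixels; components
under 100 px are discarded as debris, and components crossed by fewer than
3 scan lines are left unchanged with a warning.  This stage is what
restores juxtapleural nodules and mediastinal indentations that every
density-driven stage excludes.

## Evaluation measures

For automatic mask `A` and reference `M`: oversegmentation rate
`|A \ M| / |M|`, undersegmentation rate `|M \ A| / |M|`, overlap ratio
`(TP + TN) / all pixels` (pixel accuracy — it counts true negatives and is
deliberately *not* Dice or Jaccard, both of which are provided as extras),
and the average absolute border distance: the mean over `A`-border pixels
of the Euclidean distance in mm to the nearest `M`-border pixel, computed
with a distance transform using the pixel spacing.  Border pixels are mask
pixels with at least one false 4-neighbor; the measure is one-directional
(A -> M) with a symmetric variant behind a flag.  PSNR
`10 log10(peak^2 / MSE)` compares denoising quality; identical images give
+inf.  Batch aggregation reports per-slice values; any pooled mean is
labeled as such.

## The phantom

The synthetic generator emulates a 512x512 axial chest slice at 0.692 mm
isotropic spacing: air background (-1000 HU), elliptical soft-tissue body
(+40), two lung ellipses (-500), a circular mediastinal airway (-1000,
excluded from the lung truth), a vertebral body (+400), a detached
scanner-bed bar (+100), optional nodules (dense disks counted as lung in
the truth), and additive Gaussian noise in HU applied last; everything is
deterministic for a given seed.  The fixed battery covers six scenarios:
clean, noisy (sd 20 HU), juxtapleural nodule (radius 8 px, +20 HU,
centered 7 px inside the medial border so it abuts the pleura with a small
external cap), mediastinal indentation (a +40 HU bump indenting the medial
border), an exaggerated bed artifact, and a lungless slice.

What passing on the phantom shows: the mechanics of every stage — the
histogram split, corner growing, the Dirichlet solve, notch bridging — on
inputs with exactly the structures each stage exists to handle.  What it
does not show: performance on clinical data.  The phantom has no vascular
or bronchial texture, no partial-volume blur at interfaces, no beam
hardening and perfect left-right symmetry; its razor-sharp edges make the
random walk nearly exact, so clinical error rates will be larger than the
sub-percent figures measured here.  One visible consequence: whole-image
PSNR on the piecewise-constant phantom slightly *decreases* under any
smoother (edges dominate the MSE) even though the in-tissue residual drops
about 8-fold; the per-region residuals in `examples/02` are the meaningful
readout.

## Numerical and design choices

- Histograms use 256 bins over the normalized range; bin centers serve as
  class values, so the Otsu scan is exact for the stored histogram.
- The Dirichlet solve factorizes the unseeded Laplacian block once and
  reuses it across labels; with two labels the background field is
  `1 - lung`, guaranteeing exact row sums.
- The sparse solver is exercised against a dense direct solve (grids up to
  20x20, max abs diff < 1e-6) and a Monte-Carlo absorbing-walk estimate
  (1e5 walks, +-0.02) in the test suite; the guided filter against an
  explicit per-window brute-force oracle (< 1e-8); the border distance
  against an O(n^2) all-pairs computation (< 1e-9).
- Degenerate inputs are contracts, not crashes: constant image at the
  Otsu stage (level 1 + warning), lungless slice (no-lung status), empty
  masks where a measure is undefined (validation error; ABD reported as
  NaN in batch rows), seedless graph components (background + warning).
- Inference contains no randomness; two runs on identical input and
  configuration produce bit-identical masks.
- Problem sizes in the test suite: per-stage tests run on 128-192 px
  phantoms and 16-40 px oracle grids; the end-to-end battery runs at the
  full 512x512 study size, chosen so the whole suite completes in about a
  minute on one CPU.

## Reproducing the numbers

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates the 512x512 battery, runs the full pipeline on every scenario,
and writes the per-scenario rates, overlap, border distances, nodule
coverage, PSNR figures and the determinism check as JSON.  All quantities
are recomputed at run time; none are stored.
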