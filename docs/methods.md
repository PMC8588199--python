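# Methods

This note records the models, parameter choices and numerical decisions
behind `ttcseg`, and what the synthetic-phantom experiments do and do not
demonstrate.

## Synthetic phantoms

The package targets camera photographs of TTC-stained rat brain slices. Since
such animal datasets are rarely distributable, all quantitative testing runs
on synthetic phantoms with exact ground truth.

**Compound phantoms** (default 450 × 600 px, eight slices in a 2 × 4 grid)
emulate the features that make extraction hard: reddish elliptical slices
(healthy tissue around RGB (200, 60, 70) with per-slice jitter), pale infarct
patches (around (235, 225, 215), covering a configurable area fraction,
default 0.25), a neutral gray background (around (90, 95, 105)) with a random
linear illumination gradient (default ±12.5 8-bit units), white specular
reflection disks half inside slices and half on the background (default six,
radius 6 px), a scale-bar and a text-like label block touching the inferior
image border, Gaussian boundary blur (σ = 1.2 px) and additive Gaussian pixel
noise (σ = 3). Truth masks are the crisp pre-blur ellipses. The 450 × 600
canvas is half the linear scale of a typical smartphone photograph
(900 × 1600); it is the package's chosen phantom scale and keeps the
end-to-end experiment suite fast while preserving the slice-to-superpixel
size ratio that the saliency stage depends on.

**Slice phantoms** (320 × 480 px) provide the hemisphere stage with a
two-lobed slice: the union of two ellipses (default semi-axes 120 × 105 px)
whose centers are offset horizontally by 0.9 × the column semi-axis. This
leaves a superior groove and an inferior concavity of depth ≈ 0.107 × the row
semi-axis (≈ 13 px), which is what the endpoint detector needs. A dark
midline band (±1.5 px around a sinusoidal bow of configurable amplitude) is
drawn between the lobes, and the whole geometry is rotated analytically by
the tilt angle, so the truth masks partition the slice *exactly* into
left ∪ right ∪ one-pixel midline chain even under tilt. Midline truth is
rasterized from dense samples and reduced to a minimal 8-connected chain.

Determinism is a hard contract: identical (spec, seed) produce byte-identical
images and truth, and every random draw happens in a fixed order regardless
of which features are enabled.

What the phantoms do **not** model: realistic tissue texture, the
double-contour effect of slice thickness (a real slice photographs as two
offset cross-sections, and the bottom one can dominate for the olfactory
bulb), touching slices, and reflections merging with slice borders. Passing
the phantom suite therefore shows the pipeline recovers its own generative
model's structure under noise, blur, tilt and clutter — not performance on
real animal data.

## Saliency features and classification

Colors are compared in a 6-D space concatenating channel-normalized RGB and
range-normalized CIELab means ((L/100, (a+128)/255, (b+128)/255)); a single
Euclidean norm serves as the color distance. Superpixel positions are
normalized to [0, 1]²; histograms quantize RGB to 4 levels per channel
(B = 64 bins) and are normalized to unit sum with ε = 1e−12 guarding the
χ² denominators.

The proximity and color-affinity Gaussian weights use σ_p = 0.25 (normalized
image coordinates) and σ_c = 0.2 (normalized color units); both weight sets
are normalized to unit sum per reference superpixel. For the spatial color
distribution, μ_i is the affinity-weighted mean *position* — the weighted
mean that the feature's variance interpretation requires. Each feature is
min–max scaled to [0, 1] per image before classification, making the
classifier transferable across image sizes and illumination levels.

SLIC is delegated to scikit-image with adaptive (SLIC0) compactness, 30
iterations and σ = 1 pre-smoothing; with K = 65 requested this yields ≈ 60
connected superpixels with reliable adherence to blurred slice borders
(every phantom slice contains a superpixel ≥ 90 % inside it).

The saliency scorer is a 200-tree random forest (fixed seed; the score is the
foreground vote fraction). It is trained on superpixels from 20 synthetic
compound phantoms, labeled foreground when ≥ 80 % of their pixels lie inside
a truth slice and background when ≤ 20 %; mixed superpixels are dropped.
Trimap thresholds default to T_f = 0.7, T_b = 0.3.

## Graph-cut refinement

The trimap-to-mask step is implemented in-package: per-side Gaussian mixture
color models (5 full-covariance components, ≤ 20 000 subsampled pixels per
side, fixed seed) give unary terms −log p clipped at 50; the pairwise term is
the standard contrast-sensitive Potts weight γ·exp(−β‖z_i−z_j‖²) with γ = 50
and β = 1/(2⟨‖Δz‖²⟩) on a 4-connected grid. The binary labeling is a min
s-t cut, solved with scipy's integer maximum-flow on the subgraph of
non-hard-background pixels (capacities scaled ×10 and rounded); the
source-side partition is recovered by BFS on the residual graph.

Iteration follows the automatic-saliency-segmentation recipe: up to 5 inner
iterations of (refit GMMs, re-cut) and up to 4 outer passes that re-derive
the trimap from the current mask — pixels deeper than 10 px inside become
hard foreground, a 10-px dilation band stays unknown, the rest becomes hard
background — with early exit at a mask fixed point. On the first pass the
trimap's foreground and unknown classes are both treated as probable
foreground (high recall), and only the background class is hard.

One detail matters for stability: GMM samples exclude a 4-px ring around the
current mask boundary. Blurred transition pixels belong to neither color
population; if they enter the background model, each pass claims a deeper
ring of tissue and the mask erodes steadily (observed: per-slice Dice
drifting from ≈ 0.94 to ≈ 0.83 over the schedule). With the ring excluded
the schedule converges at Dice ≈ 0.998 on phantoms.

Degenerate contracts: a trimap with no background returns the full-frame
mask; one with no foreground or unknown returns an empty mask with a warning.

## Snakes

Both deformable models share a semi-implicit core: the pentadiagonal
internal-energy matrix A (tension α, rigidity β; cyclic for closed contours,
natural boundary conditions for open curves) is handled implicitly,
(I + 2τA) v⁺ = v + τF(v), which is unconditionally stable in the internal
term. α = β = 1.4 and γ = 1 throughout.

*Closed boundary snake* (200 snaxels, τ = 1, tol 0.1 px, ≤ 300 iterations,
uniform arc-length resampling every 10 iterations): the external energy is
−γ|∇(G_σ ∗ Î)|² with σ = 2 px on the red-dominance transform Î/255
(T_s = 50). The force field −∇E_ext is normalized to unit peak magnitude —
the customary conditioning that makes snaxel steps O(1 px) regardless of
image scale — and every step is backtracked (halved up to 8 times) whenever
it would increase the total discrete energy, so the energy trace is
non-increasing by construction and evolution stops at a local minimum. A
refinement whose result overlaps its initialization at Dice < 0.8 is
rejected in favor of the pre-snake component, keeping the stage strictly a
boundary polish.

*Open midline snake* (60 snaxels, τ = 1, tol 0.1 px, ≤ 200 iterations): the
external force is the GVF field itself. The endpoint rows are pinned to the
superior/inferior boundary rows found by the endpoint detector, so endpoints
slide laterally only; all snaxels are clamped inside the strip.

## GVF solver

The GVF Euler equations are iterated explicitly from the initialization
(u, v) = ∇S_g, where S_g is the σ = 1 Gaussian-smoothed, max-normalized
Sobel magnitude of the CLAHE-enhanced strip. The smoothing is deliberate: the
dark midline band has two parallel edge walls, and σ = 1 merges them into a
single ridge so the GVF attracts the curve to the *center* of the band rather
than one wall. The default time step 1/(4μ_g + max|∇S_g|²) sits safely inside
the explicit-Euler stability bound 1/(4μ_g) (requesting a larger step
raises); 80 iterations suffice for the capture range the strip needs, and the
solver's fixed point satisfies the discretized Euler equations to < 1e−3
sup-norm residual when run to convergence.

## Medial strip, endpoints, splitting

The slice is deskewed by its mask's principal axis (second-moment
orientation, reduced to (−45°, 45°] so either a wide or a tall slice ends up
axis-aligned); the rotation is recorded and inverted exactly as a coordinate
map when results are transported back. The strip has width w = 36 px centered
on the mass-center column (shrunk with a warning for narrower masks); CLAHE
uses clip limit 0.01 with scikit-image's default tiling.

The verbal groove/concave prescriptions are operationalized on the deskewed
mask's boundary profiles within the strip: the groove is the column with the
*largest* top-boundary row (deepest superior notch); the concave point is the
column with the *smallest* bottom-boundary row within ±w/2 columns of the
groove's vertical, ties resolved toward it. Masks with < 3 px of superior
relief (no notch) fall back to the mass-center column's top/bottom boundary
pixels, flagged in the result.

The evolved curve is extended along its end tangents, rasterized with
Bresenham segments, thinned morphologically, and reduced to the minimal
8-connected chain between its extreme endpoints (BFS shortest path, which
also discards spurs). Removing the chain from the mask must leave ≥ 2
four-connected components (else the split fails loudly); components are
assigned left/right by centroid column relative to the interpolated path
column at their centroid row. The partition left ∪ right ∪ (chain ∩ mask) is
exact by construction.

## Metrics

All eight metrics are computed from a single confusion count. Sensibility is
implemented exactly as defined with denominator TP + FN — unusual for a
specificity-like measure (it can go negative when FP exceeds the gold area)
but kept as the method's over-segmentation score, and documented in the
docstring. Conformity is undefined at TP = 0 and the error ratio at
N_g = 0; both surface as NaN, never as 0. Stack aggregation is offered both
volumetric (metrics of summed counts — the convention behind "volumetric
Dice") and slice-averaged; the two differ on unbalanced stacks and tests pin
that difference.

## Problem sizes in the test and acceptance runs

The test suite trains one 20-phantom classifier per session, runs the full
extraction pipeline on 20 seeded compound phantoms and the hemisphere
pipeline on 20 seeded slice phantoms (|tilt| ≤ 10°, |bow| ≤ 4 px);
`scripts/acceptance.py` uses 20 training phantoms, 10 compound phantoms (80
slices) and 20 slice phantoms. These sizes give stable means (per-slice Dice
s.d. ≈ 0.1 pp) at a few minutes of single-core runtime.

## Known limitations

- The clutter filter assumes scale-bar/label objects touch the image border
  or are small (< 1 % of the image); free-floating large clutter would
  survive into the slice list.
- The hemisphere stage assumes a visible (if faint) dark midline band and a
  superior groove; a slice with neither falls back to a vertical mass-center
  split.
- Phantom realism limits (see above) mean reported scores bound the
  pipeline's self-consistency, not its accuracy on animal data.
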