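# ttcseg

Automatic **brain extraction** and **cerebral hemisphere segmentation** for
camera-based photographs of TTC-stained rat brains.

In rodent stroke research (e.g. the MCAO ischemia model), brains are cut into
coronal slices and stained with 2,3,5-triphenyltetrazolium chloride (TTC):
viable tissue turns red, infarcted tissue stays pale. The slices are
photographed together with a scale bar and a subject label, on a cluttered
background, with specular reflections from tissue moisture. Quantitative
analysis then needs two tedious manual steps that this package automates:

1. **Brain extraction** — find every slice in the compound photograph and crop
   it (with its mask) into a fixed-size 480 × 320 image;
2. **Hemisphere segmentation** — split each slice along its interhemispheric
   midline into left and right halves.

Because such animal image datasets are rarely shareable, the package ships a
first-class **synthetic phantom generator** that emulates the relevant image
properties (reddish elliptical slices, white infarct patches, blurred borders,
reflections, illumination gradient, clutter objects, a two-lobed slice with a
curved/tilted dark midline) together with pixel-exact ground truth, so every
stage is quantitatively testable.

## Method

**Extraction** (five phases). The photograph is oversegmented into K = 65 SLIC
superpixels z_i. Four saliency features are computed per superpixel from its
6-D color vector c_i (normalized RGB ⊕ CIELab means), normalized centroid p_i
and quantized-color histogram h_i:

- global color saliency  GCS(z_i) = Σ_{j≠i} Δ(c_i, c_j),
- local color saliency  LCS(z_i) = Σ_{j≠i} α(p_i, p_j) Δ(c_i, c_j) with
  Gaussian proximity weights α (σ_p = 0.25, normalized to unit sum),
- color histogram contrast  CHC(z_i) = Σ_j χ²(h_i, h_j),
- spatial color distribution  SCD(z_i) = Σ_j β(c_i, c_j) ‖p_j − μ_i‖², the
  color-affinity-weighted spatial variance (σ_c = 0.2); concentrated colors
  (low SCD) are salient.

A random forest maps the features to a foreground score; two thresholds
(T_f = 0.7, T_b = 0.3) produce a **trimap** (foreground / background /
unknown), which seeds an iterative GrabCut-style segmentation: per-side
5-component Gaussian mixture color models, a contrast-sensitive smoothness
term, a min s-t cut, and adaptive re-derivation of the trimap from the mask
(eroded core → foreground, dilated band → unknown) until a fixed point.
Interior holes left by reflections are filled morphologically, and each
component boundary is polished by a closed parametric snake minimizing

    E = ∫ α|v_s|² + β|v_ss|² + E_ext(v) ds,   E_ext = −γ |∇(G_σ ∗ Î)|²,

where Î is a red-dominance transform (2R−G−B when |R−B| ≤ T_s, else 2R−G+B)
that boosts tissue against blurred borders. Defaults: α = β = 1.4, γ = 1.

**Hemisphere split** (three phases). The slice mask is deskewed by its
principal axis; a vertical medial strip of width w = 36 px around the
mass-center column is cut out, its red channel contrast-enhanced (CLAHE) and
Sobel-filtered. The superior *groove* point (deepest notch between the lobes)
and inferior *concave* point define a straight initial midline. A **gradient
vector flow** field v = (u, v) solving

    μ_g ∇²u − (u − S_gx)(S_gx² + S_gy²) = 0   (and likewise for v)

with μ_g = 0.2 extends the edge forces across the strip; an open snake with
pinned endpoint rows is advected onto the dark midline band, thinned to a
one-pixel chain, and used to partition the mask exactly into
left ∪ right ∪ midline.

**Evaluation metrics.** Conformity κ_c = (1 − (FP+FN)/TP)·100, Jaccard κ_J,
Dice κ_D, sensitivity η_st, sensibility η_sb = (1 − FP/(TP+FN))·100, pixel
count difference ΔN, distinction ΔF = FP+FN and error ratio ε_F = ΔF/N_g·100,
with both volumetric (summed-count) and slice-averaged stack aggregation.

## Worked example

```python
import numpy as np
from ttcseg import (PhantomSpec, make_slice_phantom, split_slice, evaluate_masks)

spec = PhantomSpec(n_slices=1, seed=42, midline_tilt_deg=6.0, midline_curvature_amp=3.0)
image, truth = make_slice_phantom(spec)
result = split_slice(image, truth.slice_masks[0])

left = evaluate_masks(result.midline.left_mask, truth.left_masks[0])
right = evaluate_masks(result.midline.right_mask, truth.right_masks[0])
print(f"left  hemisphere: dice={left.dice:.2f}%  conformity={left.conformity:.2f}%")
print(f"right hemisphere: dice={right.dice:.2f}%  sensitivity={right.sensitivity:.2f}%")
print(f"midline: {len(result.midline.path)} px chain, "
      f"rows {result.midline.path[0,0]}..{result.midline.path[-1,0]}")
```

prints

```
left  hemisphere: dice=99.76%  conformity=99.51%
right hemisphere: dice=99.75%  sensitivity=99.83%
midline: 215 px chain, rows 52..266
```

i.e. on a slice phantom tilted by 6° with a 3-px midline bow, both recovered
hemispheres overlap the ground truth at ≈ 99.8 % Dice and the midline is a
one-pixel 8-connected chain spanning the slice from the superior groove to
the inferior concavity.

The same flows are available from the shell:

```sh
ttcseg phantom --kind compound --seed 1 --out phantom/
ttcseg train --n-images 20 --seed 7 --out model.joblib
ttcseg extract phantom/phantom.png --model model.joblib --out slices/
ttcseg hemispheres slices/phantom_slice0.png --mask slices/phantom_slice0_mask.png --out hemi/
ttcseg evaluate hemi/phantom_slice0_left.png phantom/slice0_left.png
```

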