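"""Synthetic TTC-stained phantom images with exact ground truth.

Real camera photographs of TTC-stained rat brains contain several reddish
slices on a cluttered gray background (a scale bar, a subject label, specular
reflections from tissue moisture), and each slice carries pale infarct patches
plus a faint dark midline between the hemispheres.  This module generates
images that emulate those properties with pixel-exact truth masks, so every
pipeline stage can be tested quantitatively without an animal dataset.

Two phantom kinds are produced:

* compound phantoms — a grid of elliptical slices plus clutter, for the brain
  extraction pipeline;
* slice phantoms — a single two-lobed slice (union of two ellipses, leaving a
  superior groove and an inferior concavity) with a dark, possibly curved and
  tilted midline band, for the hemisphere-splitting pipeline.

Geometry is evaluated analytically per pixel in a rotated frame, so truth
masks, midline paths and the left/right partition stay exact under tilt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as cc_label

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_compound_phantom",
    "make_slice_phantom",
    "make_training_set",
    "HEALTHY_RGB",
    "INFARCT_RGB",
    "BACKGROUND_RGB",
]

# Color model: cardinal-red healthy tissue, near-white infarct, neutral gray
# background, dark red-brown interhemispheric fissure.
HEALTHY_RGB = np.array([200.0, 60.0, 70.0])
INFARCT_RGB = np.array([235.0, 225.0, 215.0])
BACKGROUND_RGB = np.array([90.0, 95.0, 105.0])
MIDLINE_RGB = np.array([130.0, 35.0, 45.0])
REFLECTION_RGB = np.array([250.0, 250.0, 253.0])
SCALEBAR_RGB = np.array([240.0, 240.0, 240.0])
LABEL_RGB = np.array([225.0, 220.0, 205.0])

_CLUTTER_BAND = 40  # bottom rows reserved for scale bar / label objects


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a phantom image; identical (spec, seed) give identical bytes."""

    image_size: tuple[int, int] = (450, 600)
    n_slices: int = 8
    slice_axes: tuple[float, float] | None = None  # (row, col) ellipse semi-axes
    infarct_fraction: float = 0.25
    reflection_count: int = 6
    reflection_radius_px: int = 6
    boundary_blur_sigma: float = 1.2
    background_gradient_amp: float = 25.0
    midline_curvature_amp: float = 2.0
    midline_tilt_deg: float = 5.0
    noise_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValueError("image_size must be positive")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if not 0.0 <= self.infarct_fraction <= 1.0:
            raise ValueError("infarct_fraction must lie in [0, 1]")
        if self.reflection_count < 0 or self.reflection_radius_px <= 0:
            raise ValueError("reflection parameters must be non-negative/positive")
        for name in ("boundary_blur_sigma", "background_gradient_amp", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.slice_axes is not None:
            ar, ac = self.slice_axes
            if ar <= 0 or ac <= 0:
                raise ValueError("slice_axes must be positive")


@dataclass
class PhantomTruth:
    """Ground truth registered to a phantom image."""

    slice_masks: list[np.ndarray] = field(default_factory=list)
    midline_paths: list[np.ndarray] = field(default_factory=list)  # (n, 2) (row, col)
    left_masks: list[np.ndarray] = field(default_factory=list)
    right_masks: list[np.ndarray] = field(default_factory=list)
    clutter_mask: np.ndarray | None = None

    @property
    def slice_union(self) -> np.ndarray:
        out = np.zeros_like(self.slice_masks[0], dtype=bool)
        for m in self.slice_masks:
            out |= m
        return out


def _background(shape: tuple[int, int], amp: float, rng: np.random.Generator) -> np.ndarray:
    """Base background with a smooth linear illumination gradient."""
    h, w = shape
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = BACKGROUND_RGB
    if amp > 0:
        theta = rng.uniform(0.0, 2.0 * math.pi)
        rr, cc = np.mgrid[0:h, 0:w]
        plane = (rr / h) * math.sin(theta) + (cc / w) * math.cos(theta)
        plane = (plane - plane.mean()) * amp
        img += plane[:, :, None]
    else:
        rng.uniform(0.0, 2.0 * math.pi)  # keep draw order seed-stable
    return img


def _finalize(img: np.ndarray, blur: float, noise: float, rng: np.random.Generator) -> np.ndarray:
    if blur > 0:
        img = ndi.gaussian_filter(img, sigma=(blur, blur, 0.0))
    if noise > 0:
        img = img + rng.normal(0.0, noise, img.shape)
    else:
        rng.normal(0.0, 1.0, img.shape)  # keep draw order seed-stable
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def make_compound_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render a compound phantom: a grid of stained slices plus clutter.

    Returns the 8-bit RGB image and a :class:`PhantomTruth` whose
    ``slice_masks`` follow row-major grid order and whose ``clutter_mask``
    covers the scale-bar and label objects.
    """
    h, w = spec.image_size
    axes = spec.slice_axes if spec.slice_axes is not None else (55.0, 45.0)
    rng = np.random.default_rng(spec.seed)

    # grid layout above the clutter band
    usable_h = h - _CLUTTER_BAND
    n_cols = max(1, math.ceil(math.sqrt(spec.n_slices * w / max(usable_h, 1))))
    n_rows = math.ceil(spec.n_slices / n_cols)
    cell_h, cell_w = usable_h / n_rows, w / n_cols
    jitter = 6.0
    if axes[0] + jitter + 4 > cell_h / 2 or axes[1] + jitter + 4 > cell_w / 2:
        raise ValueError(
            "slice layout overflow: ellipses of semi-axes "
            f"{axes} do not fit {n_rows}x{n_cols} cells of {cell_h:.0f}x{cell_w:.0f}px"
        )

    img = _background((h, w), spec.background_gradient_amp, rng)
    truth = PhantomTruth(clutter_mask=np.zeros((h, w), dtype=bool))

    slice_pix: list[tuple[np.ndarray, np.ndarray]] = []
    for k in range(spec.n_slices):
        gr, gc = divmod(k, n_cols)
        cy = (gr + 0.5) * cell_h + rng.uniform(-jitter, jitter)
        cx = (gc + 0.5) * cell_w + rng.uniform(-jitter, jitter)
        ar = axes[0] * rng.uniform(0.92, 1.08)
        ac = axes[1] * rng.uniform(0.92, 1.08)
        mask = _ellipse_mask((h, w), (cy, cx), (ar, ac))
        color = HEALTHY_RGB + rng.uniform(-12, 12, 3)
        img[mask] = color
        if spec.infarct_fraction > 0:
            s = math.sqrt(spec.infarct_fraction)
            off = rng.uniform(-0.25, 0.25, 2) * np.array([ar, ac])
            patch = _ellipse_mask((h, w), (cy + off[0], cx + off[1]), (0.9 * s * ar, 0.9 * s * ac))
            patch &= mask
            img[patch] = INFARCT_RGB + rng.uniform(-5, 5, 3)
        truth.slice_masks.append(mask)
        slice_pix.append(((cy, cx), (ar, ac)))

    for a, b in zip(truth.slice_masks, truth.slice_masks[1:]):
        if np.any(a & b):
            raise ValueError("slice layout overflow: generated slices overlap")

    # clutter: scale bar and label blocks touching the inferior image border
    bar = np.zeros((h, w), dtype=bool)
    bar[h - 8 : h, 30 : 30 + min(210, w // 2)] = True
    img[bar] = SCALEBAR_RGB
    lab = np.zeros((h, w), dtype=bool)
    lab[h - 34 : h, w - 52 : w - 8] = True
    img[lab] = LABEL_RGB
    for i in range(3):  # dark text-like strips on the label
        img[h - 28 + 8 * i : h - 25 + 8 * i, w - 46 : w - 14] = 60.0
    truth.clutter_mask = bar | lab

    # specular reflections: half inside slices, half on the background
    for i in range(spec.reflection_count):
        rad = spec.reflection_radius_px
        if i % 2 == 0 and spec.n_slices > 0:
            (cy, cx), (ar, ac) = slice_pix[int(rng.integers(spec.n_slices))]
            ang = rng.uniform(0, 2 * math.pi)
            rho = rng.uniform(0, 0.6)
            py, px = cy + rho * ar * math.sin(ang), cx + rho * ac * math.cos(ang)
        else:
            for _ in range(100):
                py = rng.uniform(rad + 2, usable_h - rad - 2)
                px = rng.uniform(rad + 2, w - rad - 2)
                clear = all(
                    ((py - cy) / (ar + rad + 4)) ** 2 + ((px - cx) / (ac + rad + 4)) ** 2 > 1.0
                    for (cy, cx), (ar, ac) in slice_pix
                )
                if clear:
                    break
        disk = _ellipse_mask((h, w), (py, px), (rad, rad))
        img[disk] = REFLECTION_RGB

    img = _finalize(img, spec.boundary_blur_sigma, spec.noise_sigma, rng)
    return img, truth


def _minimal_chain(points: np.ndarray) -> np.ndarray:
    """Drop chain pixels whose predecessor and successor are already 8-adjacent."""
    pts = [tuple(p) for p in points]
    changed = True
    while changed:
        changed = False
        out = [pts[0]]
        i = 1
        while i < len(pts) - 1:
            prev, nxt = out[-1], pts[i + 1]
            if max(abs(prev[0] - nxt[0]), abs(prev[1] - nxt[1])) <= 1:
                changed = True  # pts[i] redundant
                i += 1
            else:
                out.append(pts[i])
                i += 1
        if len(pts) > 1:
            out.append(pts[-1])
        pts = out
    return np.array(pts, dtype=int)


def _rasterize_curve(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Round a densely sampled curve to a deduplicated 8-connected pixel chain."""
    pr = np.round(rows).astype(int)
    pc = np.round(cols).astype(int)
    pts = [(pr[0], pc[0])]
    for r, c in zip(pr[1:], pc[1:]):
        if (r, c) != pts[-1]:
            pts.append((r, c))
    return _minimal_chain(np.array(pts, dtype=int))


def make_slice_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render a single two-lobed slice with a dark midline band.

    The slice is the union of two ellipses whose centers are offset
    horizontally by 0.9x the column semi-axis, which leaves a superior groove
    notch and an inferior concavity.  The midline bows laterally by
    ``midline_curvature_amp`` pixels and the whole geometry is rotated by
    ``midline_tilt_deg``.  Truth masks partition the slice exactly into
    left + right + one-pixel midline path.
    """
    if spec.n_slices != 1:
        raise ValueError("slice phantoms require n_slices=1")
    h, w = spec.image_size if spec.image_size != (450, 600) else (320, 480)
    b, a = spec.slice_axes if spec.slice_axes is not None else (120.0, 105.0)
    if 2.9 * a + 8 > w or 2.0 * b + 8 > h:
        raise ValueError("slice layout overflow: two-lobed slice does not fit the frame")
    rng = np.random.default_rng(spec.seed)
    theta = math.radians(spec.midline_tilt_deg)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    # frame coordinates: image offset rotated by -theta
    rr, cc = np.mgrid[0:h, 0:w]
    dr = (rr - cy) * math.cos(theta) + (cc - cx) * math.sin(theta)
    dc = -(rr - cy) * math.sin(theta) + (cc - cx) * math.cos(theta)

    off = 0.45 * a
    inside = ((dr / b) ** 2 + ((dc + off) / a) ** 2 <= 1.0) | (
        (dr / b) ** 2 + ((dc - off) / a) ** 2 <= 1.0
    )

    r_top = -b * math.sqrt(1.0 - (off / a) ** 2)  # groove floor row (frame)
    r_bot = -r_top
    span = r_bot - r_top

    def midcol(fr):
        t = np.clip((fr - r_top) / span, 0.0, 1.0)
        return spec.midline_curvature_amp * np.sin(math.pi * t)

    img = _background((h, w), spec.background_gradient_amp, rng)
    color_l = HEALTHY_RGB + rng.uniform(-10, 10, 3)
    color_r = HEALTHY_RGB + rng.uniform(-10, 10, 3)
    img[inside & (dc <= 0)] = color_l
    img[inside & (dc > 0)] = color_r

    m_of_dr = midcol(dr)
    if spec.infarct_fraction > 0:
        s = math.sqrt(spec.infarct_fraction)
        patch = ((dr / (0.8 * s * b)) ** 2 + ((dc - 0.5 * a) / (0.8 * s * a)) ** 2) <= 1.0
        patch &= inside & (dc - m_of_dr > 3.0)
        img[patch] = INFARCT_RGB + rng.uniform(-5, 5, 3)

    band = inside & (np.abs(dc - m_of_dr) <= 1.5)
    img[band] = MIDLINE_RGB

    # reflections inside the lobes, kept away from the medial strip
    for _ in range(spec.reflection_count):
        rad = spec.reflection_radius_px
        for _try in range(100):
            fr = rng.uniform(-0.7 * b, 0.7 * b)
            fc = rng.uniform(-0.9 * a, 0.9 * a) + np.sign(rng.uniform(-1, 1)) * 0.45 * a
            if abs(fc) < 40:
                continue
            py = cy + fr * math.cos(theta) - fc * math.sin(theta)
            px = cx + fr * math.sin(theta) + fc * math.cos(theta)
            disk = _ellipse_mask((h, w), (py, px), (rad, rad))
            if np.all(inside[disk]):
                img[disk] = REFLECTION_RGB
                break

    # truth midline path: dense samples in the frame mapped to image pixels
    fr = np.arange(r_top - 6.0, r_bot + 6.0, 0.25)
    fc = midcol(fr)
    prow = cy + fr * math.cos(theta) - fc * math.sin(theta)
    pcol = cx + fr * math.sin(theta) + fc * math.cos(theta)
    chain = _rasterize_curve(prow, pcol)
    keep = inside[chain[:, 0], chain[:, 1]]
    chain = chain[keep]

    path_img = np.zeros((h, w), dtype=bool)
    path_img[chain[:, 0], chain[:, 1]] = True
    rest = inside & ~path_img
    labels = cc_label(rest, connectivity=1)
    left = np.zeros((h, w), dtype=bool)
    right = np.zeros((h, w), dtype=bool)
    signed = dc - m_of_dr
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        if signed[comp].mean() <= 0:
            left |= comp
        else:
            right |= comp

    truth = PhantomTruth(
        slice_masks=[inside],
        midline_paths=[chain],
        left_masks=[left],
        right_masks=[right],
        clutter_mask=np.zeros((h, w), dtype=bool),
    )
    img = _finalize(img, spec.boundary_blur_sigma, spec.noise_sigma, rng)
    return img, truth


def superpixel_labels_from_truth(
    segments: np.ndarray, fg_truth: np.ndarray, lo: float = 0.2, hi: float = 0.8
) -> tuple[np.ndarray, np.ndarray]:
    """Label superpixels by truth purity: fg if >= hi inside, bg if <= lo.

    Returns (keep_ids, labels) where labels is a boolean fg indicator for the
    kept superpixel ids; mixed superpixels (purity in (lo, hi)) are dropped.
    """
    ids = np.arange(int(segments.max()) + 1)
    area = np.bincount(segments.ravel(), minlength=ids.size).astype(float)
    inside = np.bincount(segments.ravel(), weights=fg_truth.ravel().astype(float), minlength=ids.size)
    frac = inside / np.maximum(area, 1.0)
    keep = (frac >= hi) | (frac <= lo)
    return ids[keep], (frac >= hi)[keep]


def make_training_set(
    n_images: int,
    seed: int,
    base_spec: PhantomSpec | None = None,
    n_segments: int = 65,
    n_bins: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Build a superpixel feature/label training set from compound phantoms.

    For each phantom, superpixels at least 80% inside a truth slice mask are
    labeled foreground, those at most 20% inside are background, and mixed
    ones are dropped.  Features are the four saliency features, min-max scaled
    per image.
    """
    from .saliency import compute_features, oversegment, superpixel_stats

    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    spec0 = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for _ in range(n_images):
        spec = replace(spec0, seed=int(rng.integers(0, 2**31 - 1)))
        img, truth = make_compound_phantom(spec)
        part = oversegment(img, n_segments)
        stats = superpixel_stats(img, part, n_bins=n_bins)
        feats = compute_features(stats, scale=True)
        keep, y = superpixel_labels_from_truth(part.labels, truth.slice_union)
        if not np.any(~y):
            raise ValueError("degenerate phantom: no background superpixels")
        rows.append(feats[keep])
        labels.append(y)
    X = np.vstack(rows)
    y = np.concatenate(labels)
    return X, y
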