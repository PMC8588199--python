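"""End-to-end pipelines: compound image -> slices, slice -> hemispheres."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi

from .config import PipelineConfig
from .midline import (
    MedialSubimage,
    MidlineResult,
    detect_endpoints,
    evolve_midline,
    gvf_field,
    initial_midline,
    medial_subimage,
    split_hemispheres,
)
from .phantoms import PhantomSpec, make_training_set
from .refine import BrainSlice, extract_slices, fill_holes, refine_boundaries
from .saliency import compute_features, oversegment, superpixel_stats
from .snakes import Contour
from .trimap import SaliencyModel, Trimap, predict_trimap, saliency_cut, train_model

__all__ = [
    "ExtractionResult",
    "HemisphereResult",
    "train_synthetic_model",
    "extract_brains",
    "split_slice",
]


@dataclass
class ExtractionResult:
    slices: list[BrainSlice]
    mask: np.ndarray  # final refined brain mask over the compound image
    cut_mask: np.ndarray  # mask straight out of the graph-cut stage
    trimap: Trimap
    labels: np.ndarray  # superpixel label map


@dataclass
class HemisphereResult:
    midline: MidlineResult
    subimage: MedialSubimage
    curve: Contour  # evolved midline, subimage coordinates
    fallback: bool


def train_synthetic_model(
    n_images: int = 20,
    seed: int = 7,
    config: PipelineConfig | None = None,
    base_spec: PhantomSpec | None = None,
) -> SaliencyModel:
    """Train the saliency classifier on synthetic compound phantoms."""
    cfg = config or PipelineConfig()
    X, y = make_training_set(
        n_images, seed, base_spec=base_spec, n_segments=cfg.n_superpixels, n_bins=cfg.n_bins
    )
    return train_model(X, y, n_trees=cfg.n_trees, seed=cfg.seed)


def extract_brains(
    image: np.ndarray,
    model: SaliencyModel,
    config: PipelineConfig | None = None,
) -> ExtractionResult:
    """Run the five-phase brain extraction pipeline on a compound image."""
    cfg = config or PipelineConfig()
    part = oversegment(image, cfg.n_superpixels)
    stats = superpixel_stats(image, part, n_bins=cfg.n_bins)
    feats = compute_features(stats, sigma_p=cfg.sigma_p, sigma_c=cfg.sigma_c, scale=True)
    trimap = predict_trimap(model, feats, tf=cfg.tf, tb=cfg.tb)
    cut = saliency_cut(
        image,
        part,
        trimap,
        max_outer=cfg.max_outer,
        max_inner=cfg.max_inner,
        band_px=cfg.band_px,
        seed=cfg.seed,
    )
    filled = fill_holes(cut)
    refined = refine_boundaries(
        image,
        filled,
        ts=cfg.ts,
        gamma=cfg.gamma,
        sigma=cfg.energy_sigma,
        alpha=cfg.alpha,
        beta=cfg.beta,
        n_snaxels=cfg.n_snaxels,
        max_iters=cfg.snake_iters,
        a_min=cfg.a_min,
    )
    slices = extract_slices(image, refined, a_min=cfg.a_min)
    return ExtractionResult(
        slices=slices, mask=refined, cut_mask=cut, trimap=trimap, labels=part.labels
    )


def split_slice(
    image: np.ndarray,
    mask: np.ndarray,
    config: PipelineConfig | None = None,
) -> HemisphereResult:
    """Run the three-phase hemisphere segmentation on one extracted slice."""
    cfg = config or PipelineConfig()
    sub = medial_subimage(image, mask, w=cfg.strip_width)
    groove, concave, fallback = detect_endpoints(sub)
    init = initial_midline(groove, concave, n_points=cfg.midline_snaxels)
    # sigma=1 smoothing merges the two walls of the dark midline band into a
    # single ridge of the edge map, so the GVF attracts the curve to its center
    sg = ndi.gaussian_filter(sub.edges, 1.0)
    field = gvf_field(sg, mu=cfg.mu_g, n_iters=cfg.gvf_iters)
    curve = evolve_midline(
        init, field, alpha=cfg.alpha, beta=cfg.beta, max_iters=cfg.midline_iters
    )
    result = split_hemispheres(image, mask, curve, sub)
    result = replace(result, fallback=fallback)
    return HemisphereResult(midline=result, subimage=sub, curve=curve, fallback=fallback)
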