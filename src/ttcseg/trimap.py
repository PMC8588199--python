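"""Saliency classification and iterative graph-cut foreground extraction.

A random-forest classifier maps the four per-superpixel saliency features to
a foreground score in [0, 1]; two thresholds (Tf, Tb) turn the scores into a
trimap (foreground / background / unknown).  The trimap then seeds an
iterative GrabCut-style segmentation: 5-component Gaussian-mixture color
models for each side define unary terms, a contrast-sensitive Potts term
couples neighboring pixels, and the binary labeling is solved as a min s-t
cut.  After each converged cut the trimap is re-derived from the mask
(eroded core -> hard foreground, dilated band -> unknown) and the process
repeats until the mask is stable — the "iterative refining and adaptive
fitting" strategy of automatic saliency segmentation.

The min-cut is computed with scipy's maximum-flow solver on a 4-connected
pixel grid restricted to non-hard-background pixels; the source-side
partition is recovered by BFS on the residual graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import joblib
import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from sklearn.ensemble import RandomForestClassifier
from sklearn.mixture import GaussianMixture

from .saliency import SuperpixelPartition

__all__ = [
    "BG",
    "UNKNOWN",
    "FG",
    "Trimap",
    "SaliencyModel",
    "train_model",
    "predict_trimap",
    "saliency_cut",
]

BG, UNKNOWN, FG = 0, 1, 2

DEFAULT_TF = 0.7
DEFAULT_TB = 0.3

_CAP_SCALE = 10.0  # float->int capacity scaling for the integer max-flow solver
_D_MAX = 50.0  # clip for -log GMM likelihoods
_HARD = 10_000  # capacity of hard terminal links (pre-scaling units)


@dataclass(frozen=True)
class Trimap:
    """Per-superpixel saliency scores and the induced three-class map."""

    scores: np.ndarray  # (K,) in [0, 1]
    classes: np.ndarray  # (K,) values in {BG, UNKNOWN, FG}
    tf: float
    tb: float

    def pixel_classes(self, labels: np.ndarray) -> np.ndarray:
        """Expand superpixel classes to a dense pixel map."""
        return self.classes[labels]


class SaliencyModel:
    """Random-forest saliency scorer over the four superpixel features.

    The score of a superpixel is the fraction of trees voting foreground,
    which is deterministic for a fixed fitted model.
    """

    def __init__(self, n_trees: int = 200, seed: int = 0):
        self.n_trees = n_trees
        self.seed = seed
        self._forest = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1
        )

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "SaliencyModel":
        features = np.asarray(features, dtype=float)
        labels = np.asarray(labels).astype(bool)
        if not np.all(np.isfinite(features)):
            raise ValueError("features must be finite")
        if labels.all() or not labels.any():
            raise ValueError("training labels must contain both classes")
        self._forest.fit(features, labels.astype(int))
        return self

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        """Foreground vote fraction in [0, 1] per row of ``features``."""
        proba = self._forest.predict_proba(np.asarray(features, dtype=float))
        fg_col = list(self._forest.classes_).index(1)
        return proba[:, fg_col]

    def save(self, path) -> None:
        joblib.dump({"format": "ttcseg-saliency-model-v1", "model": self}, path)

    @staticmethod
    def load(path) -> "SaliencyModel":
        blob = joblib.load(path)
        if not (isinstance(blob, dict) and blob.get("format") == "ttcseg-saliency-model-v1"):
            raise ValueError(f"{path} is not a ttcseg saliency model file")
        return blob["model"]


def train_model(
    features: np.ndarray, labels: np.ndarray, n_trees: int = 200, seed: int = 0
) -> SaliencyModel:
    """Fit the saliency classifier on labeled superpixel features."""
    return SaliencyModel(n_trees=n_trees, seed=seed).fit(features, labels)


def predict_trimap(
    model: SaliencyModel,
    features: np.ndarray,
    tf: float = DEFAULT_TF,
    tb: float = DEFAULT_TB,
) -> Trimap:
    """Score superpixels and threshold into {fg, unknown, bg}.

    score > tf -> foreground, score < tb -> background, otherwise unknown.
    """
    if not 0.0 <= tb <= tf <= 1.0:
        raise ValueError("thresholds must satisfy 0 <= Tb <= Tf <= 1")
    scores = model.predict_scores(features)
    classes = np.full(scores.shape, UNKNOWN, dtype=np.int8)
    classes[scores > tf] = FG
    classes[scores < tb] = BG
    return Trimap(scores=scores, classes=classes, tf=tf, tb=tb)


def _pairwise_beta(img: np.ndarray) -> float:
    dh = ((img[:, 1:] - img[:, :-1]) ** 2).sum(axis=-1)
    dv = ((img[1:, :] - img[:-1, :]) ** 2).sum(axis=-1)
    mean = (dh.sum() + dv.sum()) / (dh.size + dv.size)
    return 1.0 / max(2.0 * mean, 1e-8)


def _fit_gmm(pixels: np.ndarray, seed: int) -> GaussianMixture:
    n_comp = min(5, max(1, len(pixels) // 10))
    gmm = GaussianMixture(
        n_components=n_comp,
        covariance_type="full",
        reg_covar=1e-4,
        random_state=seed,
        max_iter=100,
    )
    gmm.fit(pixels)
    return gmm


def _binary_cut(
    img: np.ndarray,
    active: np.ndarray,
    src_cap: np.ndarray,
    snk_cap: np.ndarray,
    gamma: float,
    beta: float,
) -> np.ndarray:
    """Min-cut labeling of active pixels; returns the foreground mask."""
    h, w = active.shape
    n_active = int(active.sum())
    node_id = np.full((h, w), -1, dtype=np.int64)
    node_id[active] = np.arange(n_active)
    src, snk = n_active, n_active + 1

    rows_l, cols_l, caps_l = [], [], []

    def add_links(a_idx, b_idx, cap):
        rows_l.extend([a_idx, b_idx])
        cols_l.extend([b_idx, a_idx])
        caps_l.extend([cap, cap])

    for axis in (0, 1):
        sl_a = (slice(0, -1), slice(None)) if axis == 0 else (slice(None), slice(0, -1))
        sl_b = (slice(1, None), slice(None)) if axis == 0 else (slice(None), slice(1, None))
        a_act, b_act = active[sl_a], active[sl_b]
        d2 = ((img[sl_a] - img[sl_b]) ** 2).sum(axis=-1)
        wgt = gamma * np.exp(-beta * d2)
        both = a_act & b_act
        add_links(node_id[sl_a][both], node_id[sl_b][both], wgt[both])
        # neighbor fixed to background: fold the smoothness cost into the sink link
        a_only = a_act & ~b_act
        snk_cap[node_id[sl_a][a_only]] += wgt[a_only]
        b_only = b_act & ~a_act
        snk_cap[node_id[sl_b][b_only]] += wgt[b_only]

    node_idx = np.arange(n_active)
    rows_l.append(np.full(n_active, src))
    cols_l.append(node_idx)
    caps_l.append(src_cap)
    rows_l.append(node_idx)
    cols_l.append(np.full(n_active, snk))
    caps_l.append(snk_cap)

    rows = np.concatenate([np.atleast_1d(np.asarray(r)) for r in rows_l])
    cols = np.concatenate([np.atleast_1d(np.asarray(c)) for c in cols_l])
    caps = np.concatenate([np.atleast_1d(np.asarray(c)) for c in caps_l])
    icaps = np.maximum(np.round(caps * _CAP_SCALE), 0).astype(np.int32)

    graph = csr_matrix((icaps, (rows, cols)), shape=(n_active + 2, n_active + 2))
    result = maximum_flow(graph, src, snk)
    residual = graph - result.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    reach = breadth_first_order(residual, src, directed=True, return_predecessors=False)
    fg_nodes = np.zeros(n_active + 2, dtype=bool)
    fg_nodes[reach] = True
    mask = np.zeros((h, w), dtype=bool)
    mask[active] = fg_nodes[:n_active]
    return mask


def saliency_cut(
    image: np.ndarray,
    part: SuperpixelPartition,
    trimap: Trimap,
    max_outer: int = 4,
    max_inner: int = 5,
    gamma: float = 50.0,
    band_px: int = 10,
    seed: int = 0,
    max_gmm_pixels: int = 20000,
    sample_margin: int = 4,
) -> np.ndarray:
    """Refine a trimap into a pixel-level binary brain mask.

    Each inner iteration refits the per-side color GMMs and re-solves the
    min-cut; each outer pass re-derives the trimap from the current mask
    (erosion -> hard foreground core, dilation band -> unknown) and repeats.
    Stops early whenever the mask reaches a fixed point.

    GMM samples exclude a ``sample_margin``-px ring around the current mask
    boundary: blurred transition pixels there belong to neither color
    population, and letting them enter the background model makes the mask
    erode run-away (each pass the model claims a deeper ring of tissue).
    """
    pix_cls = trimap.pixel_classes(part.labels)
    if not np.any(pix_cls != BG):
        warnings.warn("empty trimap initialization: returning an empty mask")
        return np.zeros(part.labels.shape, dtype=bool)
    if not np.any(pix_cls == BG):
        return np.ones(part.labels.shape, dtype=bool)

    img = image.astype(np.float64) / 255.0
    beta = _pairwise_beta(img)
    rng = np.random.default_rng(seed)

    # first pass: trimap bg is hard background, fg and unknown are probable fg
    hard_bg = pix_cls == BG
    hard_fg = np.zeros_like(hard_bg)
    mask = ~hard_bg
    prev_outer = None

    for _outer in range(max_outer):
        for _inner in range(max_inner):
            if sample_margin > 0:
                ring = ndi.binary_dilation(mask, iterations=sample_margin) & ~ndi.binary_erosion(
                    mask, iterations=sample_margin
                )
            else:
                ring = np.zeros_like(mask)
            fg_px = img[mask & ~hard_bg & ~ring]
            bg_px = img[(~mask | hard_bg) & ~ring]
            if len(fg_px) < 10 or len(bg_px) < 10:
                break
            sub = lambda px: px[
                rng.choice(len(px), size=min(len(px), max_gmm_pixels), replace=False)
            ]
            gmm_fg = _fit_gmm(sub(fg_px), seed)
            gmm_bg = _fit_gmm(sub(bg_px), seed)

            active = ~hard_bg
            flat = img[active]
            d_fg = np.clip(-gmm_fg.score_samples(flat), 0.0, _D_MAX)
            d_bg = np.clip(-gmm_bg.score_samples(flat), 0.0, _D_MAX)
            src_cap = d_bg.copy()  # cost of assigning background
            snk_cap = d_fg.copy()
            if hard_fg.any():
                src_cap[hard_fg[active]] = _HARD
            new_mask = _binary_cut(img, active, src_cap, snk_cap, gamma, beta)
            if np.array_equal(new_mask, mask):
                mask = new_mask
                break
            mask = new_mask
        if not mask.any():
            warnings.warn("saliency cut collapsed to an empty mask")
            break
        if prev_outer is not None and np.array_equal(mask, prev_outer):
            break
        prev_outer = mask.copy()
        # adaptive re-initialization from the current segmentation
        inside = ndi.distance_transform_edt(mask)
        outside = ndi.distance_transform_edt(~mask)
        hard_fg = inside > band_px
        band = (outside <= band_px) & ~hard_fg
        hard_bg = ~(hard_fg | band)
        if not hard_fg.any():  # mask thinner than the band: keep mask itself as core
            hard_fg = mask.copy()
            hard_bg = outside > band_px

    mask[hard_bg] = False
    return mask
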