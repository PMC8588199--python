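"""Hemisphere segmentation: medial strip, GVF midline evolution, splitting.

The interhemispheric midline of an extracted slice is found in three steps:

1. medial subimage — the slice mask is deskewed by its principal axis so the
   midline is near-vertical, and a vertical strip of width ``w`` (default 36)
   centered on the mass-center column is cut out; its red channel is
   contrast-enhanced with clip-limited adaptive histogram equalization and a
   Sobel edge map is computed;
2. initial midline — the superior groove point (deepest notch of the top
   boundary between the lobes) and the inferior concave point (deepest
   indentation of the bottom boundary near the groove's vertical) are joined
   by a straight line;
3. final midline — a gradient vector flow (GVF) field diffuses the edge
   gradients of the enhanced strip, and an open active contour initialized
   at the straight line is advected onto the dark midline band, its
   endpoints sliding along the superior/inferior boundary rows; the evolved
   curve is rasterized, thinned to one pixel and used to partition the
   slice mask into the two hemispheres.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as draw_line
from skimage.exposure import equalize_adapthist
from skimage.filters import sobel
from skimage.measure import label as cc_label
from skimage.morphology import thin as morph_thin

from .snakes import Contour, evolve_open_curve

__all__ = [
    "DEFAULT_W",
    "DEFAULT_MU_G",
    "MedialSubimage",
    "GvfField",
    "MidlineResult",
    "medial_subimage",
    "detect_endpoints",
    "initial_midline",
    "gvf_field",
    "gvf_residual",
    "evolve_midline",
    "split_hemispheres",
]

DEFAULT_W = 36  # medial strip width in px
DEFAULT_MU_G = 0.2  # GVF regularization weight


def _rot_matrix(deg: float) -> np.ndarray:
    t = math.radians(deg)
    return np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])


@dataclass
class MedialSubimage:
    """Medial strip of a deskewed slice with derived maps.

    ``angle_deg``/``center`` record the deskew so that subimage coordinates
    map back to original slice coordinates exactly (as a real-valued affine
    map): p_slice = R(angle) @ (p_deskew - center) + center.
    """

    red: np.ndarray  # Sr: red-channel strip, float in [0, 1]
    enhanced: np.ndarray  # Sc: CLAHE-enhanced strip
    edges: np.ndarray  # Se: normalized Sobel magnitude of Sc
    width: int
    row_range: tuple[int, int]  # strip rows in deskewed coords
    col_range: tuple[int, int]
    angle_deg: float
    center: tuple[float, float]
    deskewed_mask: np.ndarray  # full deskewed slice mask

    def to_deskewed(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, float) + [self.row_range[0], self.col_range[0]]

    def to_slice(self, pts: np.ndarray) -> np.ndarray:
        """Map subimage (row, col) points to original slice coordinates."""
        p = self.to_deskewed(pts) - self.center
        return p @ _rot_matrix(self.angle_deg).T + self.center

    def from_slice(self, pts: np.ndarray) -> np.ndarray:
        p = np.asarray(pts, float) - self.center
        p = p @ _rot_matrix(-self.angle_deg).T + self.center
        return p - [self.row_range[0], self.col_range[0]]


@dataclass
class GvfField:
    """Gradient-vector-flow field over a subimage; u is the column (x)
    component and v the row (y) component."""

    u: np.ndarray
    v: np.ndarray
    mu: float
    edge_map: np.ndarray


@dataclass
class MidlineResult:
    """One-pixel midline chain and the induced hemisphere partition."""

    path: np.ndarray  # (n, 2) ordered (row, col), superior to inferior
    left_mask: np.ndarray
    right_mask: np.ndarray
    fallback: bool = False


def _principal_angle(mask: np.ndarray) -> float:
    """Angle (deg) rotating the deskewed frame back to the slice frame.

    Chosen in (-45, 45] so the mask's principal axis becomes horizontal (wide
    slices) or vertical (tall slices) after deskewing by the inverse.
    """
    rr, cc = np.nonzero(mask)
    r = rr - rr.mean()
    c = cc - cc.mean()
    mu20 = (c**2).mean()
    mu02 = (r**2).mean()
    mu11 = (r * c).mean()
    phi = 0.5 * math.degrees(math.atan2(2 * mu11, mu20 - mu02))  # major axis vs col axis
    while phi <= -45.0:
        phi += 90.0
    while phi > 45.0:
        phi -= 90.0
    return -phi  # R(-phi) resampling in _rotate_about_center levels the axis


def _rotate_about_center(
    arr: np.ndarray, deg: float, center: tuple[float, float], order: int
) -> np.ndarray:
    """Resample ``arr`` in the deskewed frame: output(p) = input(R(deg)(p-c)+c)."""
    mat = _rot_matrix(deg)
    offset = np.asarray(center) - mat @ np.asarray(center)
    if arr.ndim == 3:
        out = np.stack(
            [
                ndi.affine_transform(arr[..., d].astype(float), mat, offset=offset, order=order)
                for d in range(arr.shape[2])
            ],
            axis=-1,
        )
        return out
    return ndi.affine_transform(arr.astype(float), mat, offset=offset, order=order)


def medial_subimage(
    image: np.ndarray, mask: np.ndarray, w: int = DEFAULT_W
) -> MedialSubimage:
    """Deskew the slice and cut the medial strip around the mass-center column."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty slice mask")
    angle = _principal_angle(mask)
    h, wd = mask.shape
    center = ((h - 1) / 2.0, (wd - 1) / 2.0)
    desk_mask = _rotate_about_center(mask, angle, center, order=0) > 0.5
    desk_img = _rotate_about_center(image, angle, center, order=1)

    rows, cols = np.nonzero(desk_mask)
    com_c = cols.mean()
    r0, r1 = max(int(rows.min()) - 2, 0), min(int(rows.max()) + 3, h)
    mask_w = int(cols.max()) - int(cols.min()) + 1
    if mask_w < w:
        warnings.warn(f"mask narrower ({mask_w}px) than requested strip width {w}px")
        w = mask_w
    c0 = int(round(com_c - w / 2.0))
    c0 = max(0, min(c0, wd - w))
    c1 = c0 + w

    red = desk_img[r0:r1, c0:c1, 0] / 255.0
    enhanced = equalize_adapthist(np.clip(red, 0.0, 1.0), clip_limit=0.01)
    edges = sobel(enhanced)
    if edges.max() > 0:
        edges = edges / edges.max()
    return MedialSubimage(
        red=red,
        enhanced=enhanced,
        edges=edges,
        width=w,
        row_range=(r0, r1),
        col_range=(c0, c1),
        angle_deg=angle,
        center=center,
        deskewed_mask=desk_mask,
    )


def detect_endpoints(sub: MedialSubimage) -> tuple[np.ndarray, np.ndarray, bool]:
    """Locate the superior groove and inferior concave points (subimage coords).

    The groove is the deepest notch of the superior boundary inside the strip
    (largest top-boundary row); the concave point is the deepest upward
    indentation of the inferior boundary within +-w/2 columns of the groove's
    vertical line, ties resolved toward that line.  A mask without a notch
    (boundary-profile relief < 3 px) falls back to the mass-center column's
    top/bottom boundary pixels, flagged by the returned boolean.
    """
    m = sub.deskewed_mask
    c0, c1 = sub.col_range
    cols = np.arange(c0, c1)
    has = m[:, c0:c1].any(axis=0)
    if not has.any():
        raise ValueError("medial strip contains no mask pixels")
    cols = cols[has]
    top = np.array([np.nonzero(m[:, c])[0][0] for c in cols])
    bot = np.array([np.nonzero(m[:, c])[0][-1] for c in cols])

    fallback = top.max() - top.min() < 3
    if fallback:
        com_c = int(round(np.nonzero(m)[1].mean()))
        col_sel = cols[np.argmin(np.abs(cols - com_c))]
        rows_here = np.nonzero(m[:, col_sel])[0]
        groove = np.array([rows_here[0], col_sel], dtype=float)
        concave = np.array([rows_here[-1], col_sel], dtype=float)
    else:
        gi = int(np.argmax(top))
        groove = np.array([top[gi], cols[gi]], dtype=float)
        near = np.abs(cols - cols[gi]) <= sub.width / 2.0
        bn, cn = bot[near], cols[near]
        best = bn.min()
        ties = np.nonzero(bn == best)[0]
        ci = ties[np.argmin(np.abs(cn[ties] - cols[gi]))]
        concave = np.array([bn[ci], cn[ci]], dtype=float)
    offset = np.array([sub.row_range[0], sub.col_range[0]], dtype=float)
    return groove - offset, concave - offset, bool(fallback)


def initial_midline(groove: np.ndarray, concave: np.ndarray, n_points: int = 60) -> Contour:
    """Straight open contour from the groove to the concave point."""
    groove = np.asarray(groove, float)
    concave = np.asarray(concave, float)
    if np.allclose(groove, concave):
        raise ValueError("groove and concave points coincide")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    t = np.linspace(0.0, 1.0, n_points)[:, None]
    return Contour((1 - t) * groove[None, :] + t * concave[None, :], closed=False)


def gvf_field(
    edge_map: np.ndarray,
    mu: float = DEFAULT_MU_G,
    n_iters: int = 80,
    dt: float | None = None,
) -> GvfField:
    """Diffuse the edge-map gradients into a gradient vector flow field.

    Gradient-descent iteration of the GVF Euler equations
    mu * lap(u) - (u - Sg_x) * (Sg_x^2 + Sg_y^2) = 0 (and likewise for v),
    initialized at grad(Sg).  The default time step
    1 / (4*mu + max |grad Sg|^2) is safely inside the explicit-Euler
    stability bound dt <= 1/(4*mu); requesting a larger step raises.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    sg = np.asarray(edge_map, dtype=float)
    gy, gx = np.gradient(sg)  # gy: d/drow, gx: d/dcol
    mag = gx**2 + gy**2
    limit = 1.0 / (4.0 * mu)
    if dt is None:
        dt = 1.0 / (4.0 * mu + max(float(mag.max()), 1e-12))
    elif dt > limit + 1e-12:
        raise ValueError(f"unstable time step {dt} > {limit}")
    u = gx.copy()
    v = gy.copy()
    for _ in range(n_iters):
        u += dt * (mu * ndi.laplace(u) - (u - gx) * mag)
        v += dt * (mu * ndi.laplace(v) - (v - gy) * mag)
    return GvfField(u=u, v=v, mu=mu, edge_map=sg)


def gvf_residual(field: GvfField) -> float:
    """Sup-norm residual of the discretized GVF Euler equations."""
    gy, gx = np.gradient(field.edge_map)
    mag = gx**2 + gy**2
    ru = field.mu * ndi.laplace(field.u) - (field.u - gx) * mag
    rv = field.mu * ndi.laplace(field.v) - (field.v - gy) * mag
    return max(float(np.abs(ru).max()), float(np.abs(rv).max()))


def evolve_midline(
    init: Contour,
    field: GvfField,
    alpha: float = 1.4,
    beta: float = 1.4,
    max_iters: int = 200,
    tol: float = 0.1,
) -> Contour:
    """Advect the open midline contour in the GVF field.

    Endpoint rows stay pinned to the superior/inferior boundary rows of the
    initialization, so the endpoints slide laterally only; snaxels are
    clamped inside the subimage.
    """
    pin = (float(init.points[0, 0]), float(init.points[-1, 0]))
    return evolve_open_curve(
        init,
        force_u=field.u,
        force_v=field.v,
        alpha=alpha,
        beta=beta,
        max_iters=max_iters,
        tol=tol,
        pin_rows=pin,
    )


_OFFS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _chain_from_skeleton(skel: np.ndarray) -> np.ndarray:
    """Ordered minimal 8-connected chain between the two extreme endpoints."""
    pix = set(map(tuple, np.argwhere(skel)))
    if not pix:
        raise ValueError("empty midline skeleton")
    deg = {p: sum(((p[0] + dr, p[1] + dc) in pix) for dr, dc in _OFFS) for p in pix}
    ends = [p for p, d in deg.items() if d <= 1]
    if len(ends) < 2:
        ends = [min(pix), max(pix)]
    start = min(ends)  # smallest row: superior end
    goal = max(ends, key=lambda p: p[0])
    prev: dict = {start: None}
    queue = deque([start])
    while queue:
        p = queue.popleft()
        if p == goal:
            break
        for dr, dc in _OFFS:
            q = (p[0] + dr, p[1] + dc)
            if q in pix and q not in prev:
                prev[q] = p
                queue.append(q)
    if goal not in prev:
        raise ValueError("midline skeleton is disconnected")
    path = []
    p = goal
    while p is not None:
        path.append(p)
        p = prev[p]
    return np.array(path[::-1], dtype=int)


def split_hemispheres(
    image: np.ndarray,
    mask: np.ndarray,
    curve: Contour,
    sub: MedialSubimage,
) -> MidlineResult:
    """Partition the slice mask into hemispheres along the evolved midline.

    The curve is mapped back through the deskew into slice coordinates,
    extended along its end tangents to fully transect the mask, rasterized,
    thinned to a one-pixel chain, and removed from the mask; the two
    remaining components are assigned left/right by centroid column relative
    to the path.
    """
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    pts = sub.to_slice(curve.points)

    def extend(p0, p1, length):
        d = p0 - p1
        nrm = np.linalg.norm(d)
        if nrm < 1e-9:
            d = np.array([-1.0, 0.0])
            nrm = 1.0
        return p0 + d / nrm * length

    ext_len = 0.25 * math.hypot(h, w)
    pts = np.vstack([extend(pts[0], pts[1], ext_len), pts, extend(pts[-1], pts[-2], ext_len)])

    path_img = np.zeros((h, w), dtype=bool)
    ipts = np.round(pts).astype(int)
    for (r0, c0), (r1, c1) in zip(ipts[:-1], ipts[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        path_img[rr[ok], cc[ok]] = True
    path_img = morph_thin(path_img)
    chain = _chain_from_skeleton(path_img)
    chain_img = np.zeros((h, w), dtype=bool)
    chain_img[chain[:, 0], chain[:, 1]] = True

    rest = mask & ~chain_img
    labels = cc_label(rest, connectivity=1)
    n_comp = int(labels.max())
    if n_comp < 2:
        raise ValueError(
            f"midline path fails to transect the mask ({n_comp} component(s) remain); "
            f"path spans rows {chain[:, 0].min()}..{chain[:, 0].max()}"
        )
    # path column as a function of row, for side assignment
    by_row: dict[int, list[int]] = {}
    for r, c in chain:
        by_row.setdefault(int(r), []).append(int(c))
    rows_sorted = np.array(sorted(by_row))
    col_at = np.array([np.mean(by_row[r]) for r in rows_sorted])

    left = np.zeros((h, w), dtype=bool)
    right = np.zeros((h, w), dtype=bool)
    for lab in range(1, n_comp + 1):
        comp = labels == lab
        rr, cc = np.nonzero(comp)
        ref = np.interp(rr.mean(), rows_sorted, col_at)
        if cc.mean() <= ref:
            left |= comp
        else:
            right |= comp

    on_mask = mask[chain[:, 0], chain[:, 1]]
    return MidlineResult(path=chain[on_mask], left_mask=left, right_mask=right)
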