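"""Parametric active contours (snakes) for closed boundaries and open curves.

A snake is an ordered list of snaxels v(s) = [row(s), col(s)] minimizing

    E = sum_i  alpha |v_i - v_{i-1}|^2 + beta |v_{i+1} - 2 v_i + v_{i-1}|^2
        + sum_i  E_ext(v_i)

The internal terms (tension and rigidity) are handled semi-implicitly: each
step solves (I + 2*tau*A) v_new = v + tau * F_ext(v), where A is the
(cyclic or natural-boundary) pentadiagonal internal-energy matrix.  For
closed contours driven by a scalar external energy field the step size is
backtracked whenever the total discrete energy would increase, which makes
the evolution monotone in energy.  Open curves driven by a vector force
field (gradient vector flow) use the same implicit core with pinned endpoint
rows, so the endpoints slide along the superior/inferior boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.linalg import lu_factor, lu_solve

__all__ = ["Contour", "EnergyField", "evolve_snake", "evolve_open_curve"]


@dataclass
class Contour:
    """Ordered snaxel curve; points are float (row, col) pairs."""

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must have shape (N, 2)")
        if len(self.points) < (3 if self.closed else 2):
            raise ValueError("contour needs at least 3 (closed) or 2 (open) snaxels")

    def perimeter(self) -> float:
        d = np.diff(self.points, axis=0, append=self.points[:1]) if self.closed else np.diff(self.points, axis=0)
        return float(np.sqrt((d**2).sum(axis=1)).sum())

    def resample(self, n: int | None = None) -> "Contour":
        """Uniform-arclength resampling (endpoints preserved for open curves)."""
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        seg = np.sqrt((np.diff(pts, axis=0) ** 2).sum(axis=1))
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        if total <= 0:
            raise ValueError("degenerate contour: zero length")
        n = n if n is not None else len(self.points)
        if self.closed:
            t = np.linspace(0.0, total, n, endpoint=False)
        else:
            t = np.linspace(0.0, total, n)
        out = np.column_stack(
            [np.interp(t, s, pts[:, 0]), np.interp(t, s, pts[:, 1])]
        )
        return Contour(out, closed=self.closed)

    def signed_area(self) -> float:
        y, x = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(
            np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        )

    def ensure_ccw(self) -> "Contour":
        """Counter-clockwise in image coordinates (row down, col right)."""
        if not self.closed:
            return self
        if self.signed_area() > 0:
            return Contour(self.points[::-1].copy(), closed=True)
        return self


@dataclass
class EnergyField:
    """Scalar external energy map with its gradient-based force."""

    energy: np.ndarray
    gamma: float = 1.0
    sigma: float = 2.0
    _force: tuple[np.ndarray, np.ndarray] = field(init=False, repr=False, default=None)

    def force_maps(self) -> tuple[np.ndarray, np.ndarray]:
        if self._force is None:
            gr, gc = np.gradient(self.energy)
            self._force = (-gr, -gc)
        return self._force

    def sample_energy(self, pts: np.ndarray) -> np.ndarray:
        return ndi.map_coordinates(self.energy, pts.T, order=1, mode="nearest")

    def sample_force(self, pts: np.ndarray) -> np.ndarray:
        fr, fc = self.force_maps()
        return np.column_stack(
            [
                ndi.map_coordinates(fr, pts.T, order=1, mode="nearest"),
                ndi.map_coordinates(fc, pts.T, order=1, mode="nearest"),
            ]
        )


def _internal_matrix(n: int, alpha: float, beta: float, closed: bool) -> np.ndarray:
    """A with internal-energy gradient = 2 A v (pentadiagonal, cyclic if closed)."""
    if closed:
        idx = np.arange(n)
        d1 = np.zeros((n, n))
        d1[idx, idx] = 1.0
        d1[idx, (idx + 1) % n] = -1.0
        d2 = np.zeros((n, n))
        d2[idx, idx] = -2.0
        d2[idx, (idx + 1) % n] = 1.0
        d2[idx, (idx - 1) % n] = 1.0
    else:
        d1 = np.zeros((n - 1, n))
        r = np.arange(n - 1)
        d1[r, r] = 1.0
        d1[r, r + 1] = -1.0
        d2 = np.zeros((max(n - 2, 0), n))
        r = np.arange(max(n - 2, 0))
        d2[r, r] = 1.0
        d2[r, r + 1] = -2.0
        d2[r, r + 2] = 1.0
    return alpha * d1.T @ d1 + beta * d2.T @ d2


def _internal_energy(pts: np.ndarray, alpha: float, beta: float, closed: bool) -> float:
    if closed:
        d1 = np.roll(pts, -1, axis=0) - pts
        d2 = np.roll(pts, -1, axis=0) - 2 * pts + np.roll(pts, 1, axis=0)
        return float(alpha * (d1**2).sum() + beta * (d2**2).sum())
    d1 = np.diff(pts, axis=0)
    d2 = np.diff(pts, 2, axis=0)
    return float(alpha * (d1**2).sum() + beta * (d2**2).sum())


def snake_energy(
    contour: Contour, field: EnergyField, alpha: float, beta: float
) -> float:
    """Total discrete snake energy (internal + sampled external)."""
    e_int = _internal_energy(contour.points, alpha, beta, contour.closed)
    return e_int + float(field.sample_energy(contour.points).sum())


def evolve_snake(
    init: Contour,
    field: EnergyField,
    alpha: float = 1.4,
    beta: float = 1.4,
    max_iters: int = 300,
    tol: float = 0.1,
    tau: float = 1.0,
    resample_every: int = 10,
    track_energy: bool = False,
) -> Contour | tuple[Contour, list[float]]:
    """Evolve a closed snake on a scalar energy field to a local minimum.

    The external force field is normalized to unit peak magnitude (the
    customary conditioning for gradient-derived snake forces), so snaxels
    move at most ~``tau`` px per iteration regardless of the image scale.
    Each step is backtracked (halved up to 8 times) whenever it would raise
    the total discrete energy, making the recorded energy non-increasing;
    evolution stops when the largest snaxel displacement falls below
    ``tol`` px or no energy-decreasing step exists.
    """
    if not init.closed:
        raise ValueError("evolve_snake expects a closed contour")
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    contour = init.ensure_ccw()
    n = len(contour.points)
    fr, fc = field.force_maps()
    fmax = max(float(np.abs(fr).max()), float(np.abs(fc).max()))
    fscale = 1.0 / fmax if fmax > 0 else 1.0
    tau_eff = tau
    a_mat = _internal_matrix(n, alpha, beta, closed=True)
    shape = field.energy.shape
    energies: list[float] = [snake_energy(contour, field, alpha, beta)]

    pts = contour.points
    for it in range(max_iters):
        force = field.sample_force(pts) * fscale
        e_old = energies[-1]
        step = tau_eff
        accepted = False
        for _ in range(8):
            lhs = np.eye(n) + 2.0 * step * a_mat
            lu = lu_factor(lhs)
            new_pts = np.column_stack(
                [
                    lu_solve(lu, pts[:, 0] + step * force[:, 0]),
                    lu_solve(lu, pts[:, 1] + step * force[:, 1]),
                ]
            )
            new_pts[:, 0] = np.clip(new_pts[:, 0], 0, shape[0] - 1)
            new_pts[:, 1] = np.clip(new_pts[:, 1], 0, shape[1] - 1)
            cand = Contour(new_pts, closed=True)
            e_new = snake_energy(cand, field, alpha, beta)
            if e_new <= e_old:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        disp = float(np.sqrt(((new_pts - pts) ** 2).sum(axis=1)).max())
        pts = new_pts
        if resample_every and (it + 1) % resample_every == 0:
            res = Contour(pts, closed=True).resample(n)
            e_res = snake_energy(res, field, alpha, beta)
            if e_res <= e_new + 1e-12 * (1.0 + abs(e_new)):
                pts = res.points
                e_new = e_res
        energies.append(e_new)
        if disp < tol:
            break
    out = Contour(pts, closed=True)
    if len(out.points) < 3:
        raise ValueError("contour collapsed below 3 snaxels")
    return (out, energies) if track_energy else out


def evolve_open_curve(
    init: Contour,
    force_u: np.ndarray,
    force_v: np.ndarray,
    alpha: float = 1.4,
    beta: float = 1.4,
    max_iters: int = 200,
    tol: float = 0.1,
    tau: float = 1.0,
    resample_every: int = 10,
    pin_rows: tuple[float, float] | None = None,
) -> Contour:
    """Advect an open curve in a vector force field (e.g. gradient vector flow).

    ``force_u``/``force_v`` are the column- and row-direction force
    components sampled on the image grid.  When ``pin_rows`` is given the
    first/last snaxel rows are fixed to those values and the endpoints only
    slide laterally; all snaxels are clamped inside the field domain.
    """
    if init.closed:
        raise ValueError("evolve_open_curve expects an open contour")
    n = len(init.points)
    a_mat = _internal_matrix(n, alpha, beta, closed=False)
    lhs = np.eye(n) + 2.0 * tau * a_mat
    lu = lu_factor(lhs)
    shape = force_u.shape
    pts = init.points.copy()

    def clamp(p: np.ndarray) -> np.ndarray:
        p[:, 0] = np.clip(p[:, 0], 0, shape[0] - 1)
        p[:, 1] = np.clip(p[:, 1], 0, shape[1] - 1)
        return p

    for it in range(max_iters):
        f_col = ndi.map_coordinates(force_u, pts.T, order=1, mode="nearest")
        f_row = ndi.map_coordinates(force_v, pts.T, order=1, mode="nearest")
        rhs_r = pts[:, 0] + tau * f_row
        rhs_c = pts[:, 1] + tau * f_col
        if pin_rows is not None:
            rhs_r[0], rhs_r[-1] = pin_rows  # endpoints keep their boundary rows
        new_pts = np.column_stack([lu_solve(lu, rhs_r), lu_solve(lu, rhs_c)])
        if pin_rows is not None:
            new_pts[0, 0], new_pts[-1, 0] = pin_rows
        new_pts = clamp(new_pts)
        disp = float(np.sqrt(((new_pts - pts) ** 2).sum(axis=1)).max())
        pts = new_pts
        if resample_every and (it + 1) % resample_every == 0:
            res = Contour(pts, closed=False).resample(n).points
            if pin_rows is not None:
                res[0] = pts[0]
                res[-1] = pts[-1]
            pts = clamp(res)
        if disp < tol:
            break
    return Contour(pts, closed=False)
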