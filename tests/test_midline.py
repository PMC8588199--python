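"""Medial strip, endpoint detection, GVF and hemisphere splitting."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from ttcseg import (
    PhantomSpec,
    detect_endpoints,
    evaluate_masks,
    evolve_midline,
    gvf_field,
    gvf_residual,
    initial_midline,
    make_slice_phantom,
    medial_subimage,
    split_hemispheres,
    split_slice,
)
from ttcseg.midline import DEFAULT_MU_G, DEFAULT_W
from ttcseg.snakes import Contour, evolve_open_curve


def ellipse_slice(shape=(320, 480), center=(160, 240), axes=(110, 140)):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = ((yy - center[0]) / axes[0]) ** 2 + ((xx - center[1]) / axes[1]) ** 2 <= 1
    img = np.zeros(shape + (3,), dtype=np.uint8)
    img[mask] = (200, 60, 70)
    return img, mask


class TestMedialSubimage:
    def test_default_strip_width_is_thirty_six(self):
        import inspect

        assert DEFAULT_W == 36
        assert inspect.signature(medial_subimage).parameters["w"].default == 36

    def test_strip_centered_on_truth_midline(self):
        spec = PhantomSpec(n_slices=1, midline_tilt_deg=0, midline_curvature_amp=0, seed=1)
        img, truth = make_slice_phantom(spec)
        sub = medial_subimage(img, truth.slice_masks[0])
        strip_center = (sub.col_range[0] + sub.col_range[1]) / 2.0
        truth_col = truth.midline_paths[0][:, 1].mean()
        assert abs(strip_center - truth_col) <= 2.0

    def test_coordinate_round_trip_is_exact(self):
        spec = PhantomSpec(n_slices=1, midline_tilt_deg=7, seed=2)
        img, truth = make_slice_phantom(spec)
        sub = medial_subimage(img, truth.slice_masks[0])
        pts = np.array([[10.0, 5.0], [40.0, 20.0], [100.0, 35.0]])
        back = sub.from_slice(sub.to_slice(pts))
        np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_narrow_mask_warns_and_shrinks_strip(self):
        img = np.zeros((100, 60, 3), dtype=np.uint8)
        mask = np.zeros((100, 60), dtype=bool)
        mask[10:90, 25:45] = True  # 20 px wide < 36
        img[mask] = (200, 60, 70)
        with pytest.warns(UserWarning):
            sub = medial_subimage(img, mask)
        assert sub.width == 20

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            medial_subimage(np.zeros((10, 10, 3), dtype=np.uint8), np.zeros((10, 10), bool))


class TestEndpoints:
    def test_groove_found_at_truth_notch(self):
        spec = PhantomSpec(n_slices=1, midline_tilt_deg=0, midline_curvature_amp=0, seed=3)
        img, truth = make_slice_phantom(spec)
        sub = medial_subimage(img, truth.slice_masks[0])
        groove, concave, fallback = detect_endpoints(sub)
        assert not fallback
        truth_col = truth.midline_paths[0][:, 1].mean() - sub.col_range[0]
        assert abs(groove[1] - truth_col) <= 2.0
        assert groove[0] < concave[0]

    def test_grooveless_ellipse_falls_back_to_mass_center(self):
        img, mask = ellipse_slice()
        sub = medial_subimage(img, mask)
        groove, concave, fallback = detect_endpoints(sub)
        assert fallback
        com_col = np.nonzero(mask)[1].mean() - sub.col_range[0]
        assert abs(groove[1] - com_col) <= 2.0
        assert abs(concave[1] - com_col) <= 2.0

    def test_curved_midline_concave_near_truth_inferior_end(self):
        spec = PhantomSpec(n_slices=1, midline_tilt_deg=0, midline_curvature_amp=4, seed=4)
        img, truth = make_slice_phantom(spec)
        sub = medial_subimage(img, truth.slice_masks[0])
        _, concave, fallback = detect_endpoints(sub)
        assert not fallback
        inferior = truth.midline_paths[0][-1].astype(float)
        concave_slice = sub.to_slice(concave[None, :])[0]
        assert np.linalg.norm(concave_slice - inferior) <= 3.0


class TestInitialMidline:
    def test_vertical_segment_snaxels_collinear(self):
        c = initial_midline(np.array([10.0, 5.0]), np.array([40.0, 5.0]), n_points=31)
        assert np.allclose(c.points[:, 1], 5.0)
        assert c.points[0, 0] == 10.0 and c.points[-1, 0] == 40.0

    def test_endpoints_exact_and_degenerate_two_points(self):
        a, b = np.array([3.0, 4.0]), np.array([20.0, 9.0])
        c = initial_midline(a, b, n_points=2)
        np.testing.assert_allclose(c.points, [a, b])

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            initial_midline(np.array([1.0, 1.0]), np.array([1.0, 1.0]))


class TestGvf:
    def test_default_regularization_weight(self):
        import inspect

        assert DEFAULT_MU_G == 0.2
        assert inspect.signature(gvf_field).parameters["mu"].default == 0.2

    def test_constant_edge_map_gives_zero_field(self):
        f = gvf_field(np.full((30, 30), 0.4), n_iters=50)
        assert np.abs(f.u).max() == 0.0 and np.abs(f.v).max() == 0.0

    def test_unstable_time_step_rejected(self):
        with pytest.raises(ValueError):
            gvf_field(np.zeros((10, 10)), mu=0.2, dt=10.0)

    def test_converged_field_satisfies_euler_equations(self):
        em = np.zeros((60, 40))
        em[:, 18:22] = 1.0
        em = ndi.gaussian_filter(em, 1.5)
        field = gvf_field(em, mu=0.2, n_iters=5000)
        assert gvf_residual(field) < 1e-3

    def test_field_tracks_gradient_where_edges_dominate(self):
        em = np.zeros((60, 40))
        em[:, 18:22] = 1.0
        em = ndi.gaussian_filter(em, 1.5)
        field = gvf_field(em, mu=0.2, n_iters=3000)
        gy, gx = np.gradient(em)
        strong = gx**2 + gy**2 > 100 * field.mu
        if strong.any():
            rel = np.abs(field.u[strong] - gx[strong]) / np.abs(gx[strong]).max()
            assert rel.max() < 0.05


class TestMidlineEvolution:
    def make_band_subimage(self, offset=0.0, width=60, height=200):
        img = np.full((height, width), 0.9)
        band_col = width / 2.0 + offset
        cols = np.arange(width)
        img[:, np.abs(cols - band_col) <= 1.5] = 0.2
        return img, band_col

    def test_converges_onto_dark_band(self):
        from skimage.filters import sobel

        img, band_col = self.make_band_subimage()
        edges = sobel(img)
        edges /= edges.max()
        field = gvf_field(ndi.gaussian_filter(edges, 1.0), n_iters=400)
        init = initial_midline(
            np.array([2.0, band_col - 5]), np.array([197.0, band_col - 5]), n_points=60
        )
        out = evolve_midline(init, field, max_iters=300)
        lateral = np.abs(out.points[5:-5, 1] - band_col)
        assert lateral.mean() <= 1.0

    def test_zero_field_straightens_curve(self):
        u = np.zeros((100, 60))
        v = np.zeros((100, 60))
        rows = np.linspace(5, 95, 40)
        cols = 30 + 8 * np.sin(np.linspace(0, 3 * np.pi, 40))
        init = Contour(np.column_stack([rows, cols]), closed=False)
        out = evolve_open_curve(init, u, v, max_iters=500, tol=0.0, pin_rows=(5.0, 95.0))
        chord = np.interp(out.points[:, 0], [5, 95], [out.points[0, 1], out.points[-1, 1]])
        assert np.abs(out.points[:, 1] - chord).max() < 1.0


class TestSplit:
    def test_partition_contract_and_thin_path(self):
        spec = PhantomSpec(n_slices=1, seed=5, midline_curvature_amp=3, midline_tilt_deg=6)
        img, truth = make_slice_phantom(spec)
        res = split_slice(img, truth.slice_masks[0])
        m = truth.slice_masks[0]
        L, R, P = res.midline.left_mask, res.midline.right_mask, res.midline.path
        pimg = np.zeros_like(m)
        pimg[P[:, 0], P[:, 1]] = True
        assert np.array_equal(L | R | pimg, m)
        assert not (L & R).any() and not (L & pimg).any() and not (R & pimg).any()
        pset = set(map(tuple, P))
        for r, c in pset:
            nbrs = sum(
                ((r + dr, c + dc) in pset)
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)
            )
            assert nbrs <= 2

    def test_symmetric_phantom_balances_areas(self):
        spec = PhantomSpec(n_slices=1, seed=6, midline_curvature_amp=0, midline_tilt_deg=0)
        img, truth = make_slice_phantom(spec)
        res = split_slice(img, truth.slice_masks[0])
        L, R = res.midline.left_mask.sum(), res.midline.right_mask.sum()
        assert abs(int(L) - int(R)) / truth.slice_masks[0].sum() <= 0.02

    def test_non_transecting_path_raises(self):
        img, mask = ellipse_slice()
        sub = medial_subimage(img, mask)
        # a short horizontal stub far outside the mask cannot split it
        curve = Contour(np.array([[5.0, 1.0], [5.0, 8.0]]), closed=False)
        with pytest.raises(ValueError, match="transect"):
            split_hemispheres(img, mask, curve, sub)

    def test_tilt_equivariance_of_hemisphere_dice(self):
        dices = []
        for tilt in (0.0, 8.0):
            spec = PhantomSpec(
                n_slices=1, seed=7, midline_curvature_amp=2, midline_tilt_deg=tilt
            )
            img, truth = make_slice_phantom(spec)
            res = split_slice(img, truth.slice_masks[0])
            dices.append(evaluate_masks(res.midline.left_mask, truth.left_masks[0]).dice)
        assert abs(dices[0] - dices[1]) < 1.0

    def test_midline_close_to_truth_on_curved_phantom(self):
        spec = PhantomSpec(n_slices=1, seed=8, midline_curvature_amp=4, midline_tilt_deg=5)
        img, truth = make_slice_phantom(spec)
        res = split_slice(img, truth.slice_masks[0])
        dist = cKDTree(truth.midline_paths[0]).query(res.midline.path)[0].mean()
        assert dist <= 2.0
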