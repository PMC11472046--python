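"""Ripley K/H statistics, normalization, and heatmap rendering."""

import numpy as np
import pandas as pd
import pytest

import hpdyn
from hpdyn.ripley import (
    PointPattern,
    _circle_fraction_inside,
    aggregate_cells,
    normalized_H,
    render_heatmap,
    ripley_H,
    ripley_K,
)

UNIT_ROI = (0.0, 0.0, 1.0)


def brute_force_K(points, roi, r_grid):
    """Literal double-loop evaluation of the K formula (no edge correction)."""
    points = np.asarray(points)
    n = len(points)
    lam = n / (np.pi * roi[2] ** 2)
    K = np.zeros(len(r_grid))
    for a, r in enumerate(r_grid):
        s = 0.0
        for i in range(n):
            for j in range(n):
                if i != j and np.hypot(*(points[i] - points[j])) < r:
                    s += 1.0
        K[a] = s / (lam * n)
    return K


class TestRipleyK:
    def test_two_points_below_separation_gives_zero(self):
        pts = [[-0.2, 0.0], [0.2, 0.0]]  # distance 0.4
        K = ripley_K(PointPattern(pts, UNIT_ROI), np.array([0.1, 0.3]), edge_correction=False)
        assert np.all(K == 0.0)

    def test_coincident_points_match_printed_formula(self):
        # n coincident points: K(r) = (n-1)/lambda for every r > 0
        n = 7
        pat = PointPattern(np.zeros((n, 2)), UNIT_ROI)
        K = ripley_K(pat, np.array([0.05, 0.4]))
        assert np.allclose(K, (n - 1) / pat.density, rtol=1e-12)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-0.6, 0.6, size=(20, 2))
        r_grid = np.linspace(0.05, 1.0, 12)
        got = ripley_K(PointPattern(pts, UNIT_ROI), r_grid, edge_correction=False)
        assert np.allclose(got, brute_force_K(pts, UNIT_ROI, r_grid), rtol=1e-12)

    def test_K_nondecreasing_in_radius(self):
        rng = np.random.default_rng(1)
        th = rng.uniform(0, 2 * np.pi, 100)
        rr = np.sqrt(rng.uniform(0, 1, 100))
        pts = np.column_stack([rr * np.cos(th), rr * np.sin(th)])
        K = ripley_K(PointPattern(pts, UNIT_ROI), np.linspace(0.02, 1.0, 50))
        assert np.all(np.diff(K) >= -1e-12)

    def test_interior_csr_close_to_pi_r_squared(self):
        # points well inside the ROI at small radii: no edge effect
        rng = np.random.default_rng(2)
        th = rng.uniform(0, 2 * np.pi, 4000)
        rr = 0.5 * np.sqrt(rng.uniform(0, 1, 4000))
        pts = np.column_stack([rr * np.cos(th), rr * np.sin(th)])
        pat = PointPattern(pts, (0.0, 0.0, 0.5))
        r = np.array([0.05, 0.1])
        K = ripley_K(pat, r)
        assert np.allclose(K, np.pi * r**2, rtol=0.1)

    def test_radius_beyond_roi_diameter_warns(self):
        pts = [[-0.2, 0.0], [0.2, 0.0]]
        with pytest.warns(UserWarning, match="diameter"):
            ripley_K(PointPattern(pts, UNIT_ROI), np.array([2.5]))


def test_circle_fraction_geometry():
    # circle fully inside; closed form 1 - arccos(-rho/2R)/pi on the boundary
    assert _circle_fraction_inside(np.array([0.5]), np.array([0.2]), 1.0)[0] == 1.0
    for rho in (0.01, 0.1, 0.5):
        got = _circle_fraction_inside(np.array([1.0]), np.array([rho]), 1.0)[0]
        assert got == pytest.approx(1 - np.arccos(-rho / 2) / np.pi, abs=1e-12)


class TestRipleyH:
    def test_csr_expectation_maps_to_zero(self):
        r = np.linspace(0.1, 1.0, 5)
        assert np.allclose(ripley_H(np.pi * r**2, r), 0.0, atol=1e-12)

    def test_empty_K_maps_to_minus_r(self):
        r = np.linspace(0.1, 1.0, 5)
        assert np.allclose(ripley_H(np.zeros(5), r), -r)

    def test_arithmetic_example(self):
        assert ripley_H(np.array([4 * np.pi]), np.array([1.0]))[0] == pytest.approx(1.0)

    def test_negative_K_rejected(self):
        with pytest.raises(ValueError):
            ripley_H(np.array([-1.0]), np.array([0.1]))


class TestAggregation:
    def test_single_cell_identity(self):
        H = np.array([[1.0, 2.0, 3.0]])
        assert np.allclose(aggregate_cells(H, np.array([5.0])), H[0])

    def test_equal_density_is_plain_mean(self):
        H = np.array([[0.0, 2.0], [4.0, 6.0]])
        assert np.allclose(aggregate_cells(H, np.array([3.0, 3.0])), [2.0, 4.0])

    def test_weighted_mean_example(self):
        got = aggregate_cells(np.array([[0.0], [4.0]]), np.array([1.0, 3.0]))
        assert got[0] == pytest.approx(3.0)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            aggregate_cells(np.ones((2, 3)), np.zeros(2))


def _foci_trajectories(seed=0, n_tracks=60, foci=((0.3, 0.0), (-0.3, 0.0)), spread=0.05):
    """Tracks jittering inside two tight foci of a 1-um nucleus."""
    rng = np.random.default_rng(seed)
    rows = []
    for tid in range(n_tracks):
        fx, fy = foci[tid % len(foci)]
        L = 6
        x = fx + rng.normal(scale=spread, size=L)
        y = fy + rng.normal(scale=spread, size=L)
        rows.append(pd.DataFrame({"track_id": tid, "frame": range(L), "x_um": x, "y_um": y, "cell_id": 0}))
    df = pd.concat(rows, ignore_index=True)
    rois = pd.DataFrame({"cell_id": [0], "cx_um": [0.0], "cy_um": [0.0], "r_um": [1.0]})
    return hpdyn.TrajectorySet(df=df, dt_frame=0.04, sigma_loc=0.01, rois=rois)


class TestNormalizedH:
    def test_matched_resample_is_self_consistent(self, chp2_like_data):
        # analyzing a replicate produced by the matched resampler against the
        # resampler's own null: H_norm should sit inside the envelope almost
        # everywhere (confined to a single cell to keep it cheap)
        sub_df = chp2_like_data.df[chp2_like_data.df.cell_id == 0].drop(columns="state")
        sub = hpdyn.TrajectorySet(
            df=sub_df, dt_frame=0.04, sigma_loc=0.02, rois=chp2_like_data.rois
        )
        null = hpdyn.resample_matched_trajectories(sub, n_reps=1, seed=5)[0]
        res = normalized_H(null, n_reps=40, seed=6, r_grid=np.linspace(0.05, 0.5, 12))
        inside = (res.H >= res.sim_envelope[0]) & (res.H <= res.sim_envelope[1])
        assert inside.mean() >= 0.75

    def test_clustered_foci_detected(self):
        data = _foci_trajectories()
        res = normalized_H(data, n_reps=40, seed=7, r_grid=np.linspace(0.05, 0.5, 12))
        band = (res.r_grid >= 0.1) & (res.r_grid <= 0.3)
        assert np.all(res.H_norm[band] > 0)
        assert np.all(res.H[band] > res.sim_envelope[1][band])

    def test_state_restriction_uses_run_segments(self, chp2_like_data):
        sub = hpdyn.subset_by_state(chp2_like_data, 0)
        assert sub.n_localizations > 0
        assert len(sub.steps()) == (chp2_like_data.steps()["state"] == 0).sum()

    def test_too_few_points_rejected(self, tiny_tracks):
        with pytest.warns(UserWarning, match="fewer than 10"):
            with pytest.raises(ValueError):
                normalized_H(tiny_tracks, n_reps=5, seed=1)


class TestHeatmap:
    def _single_loc_set(self, x=0.2, y=-0.1):
        df = pd.DataFrame(
            {"track_id": [0, 0], "frame": [0, 1], "x_um": [x, x], "y_um": [y, y], "cell_id": 0}
        )
        rois = pd.DataFrame({"cell_id": [0], "cx_um": [0.0], "cy_um": [0.0], "r_um": [1.0]})
        return hpdyn.TrajectorySet(df=df, dt_frame=0.04, sigma_loc=0.01, rois=rois)

    def test_maximum_at_localization_position(self):
        img = render_heatmap(self._single_loc_set(), cell_id=0, pixel_um=0.01)
        assert img.image.max() == 1.0
        iy, ix = np.unravel_index(np.argmax(img.image), img.image.shape)
        x = img.extent[0] + ix * img.pixel_um
        y = img.extent[2] + iy * img.pixel_um
        assert abs(x - 0.2) <= 0.011 and abs(y - (-0.1)) <= 0.011

    def test_two_equal_foci_equal_maxima(self):
        data = _foci_trajectories(spread=0.0, n_tracks=2)
        img = render_heatmap(data, cell_id=0, pixel_um=0.01)
        half = img.image.shape[1] // 2
        assert img.image[:, :half].max() == pytest.approx(img.image[:, half:].max(), rel=1e-9)

    def test_total_intensity_conserves_localization_count(self):
        data = _foci_trajectories(n_tracks=10)
        img = render_heatmap(data, cell_id=0, pixel_um=0.01, psf_sigma_um=0.05)
        assert img.total_intensity == pytest.approx(data.n_localizations, rel=1e-3)

    def test_invalid_pixel_size_rejected(self):
        with pytest.raises(ValueError):
            render_heatmap(self._single_loc_set(), cell_id=0, pixel_um=0.0)
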