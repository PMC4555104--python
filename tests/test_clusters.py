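import numpy as np
import pandas as pd
import pytest

from ccpalm.clusters import (
    FWHM_FACTOR,
    RoiPolygon,
    analyze_rois,
    fit_cluster,
    fits_to_table,
    propose_rois,
    select_in_roi,
    summarize_clusters,
)


def pts_df(xy):
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame({"x_nm": xy[:, 0], "y_nm": xy[:, 1]})


def ray_casting_inside(px, py, poly):
    """Independent even-odd (ray casting) oracle; excludes boundary handling."""
    n = len(poly)
    inside = False
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside


class TestSelectInRoi:
    SQUARE = RoiPolygon(np.array([[0, 0], [100, 0], [100, 100], [0, 100]], dtype=float))

    def test_square_containment(self):
        pts = pts_df([[50, 50], [10, 90], [99, 1], [150, 50], [-5, 50]])
        sel = select_in_roi(pts, self.SQUARE)
        assert list(sel.index) == [0, 1, 2]

    def test_boundary_point_included(self):
        pts = pts_df([[100.0, 50.0], [0.0, 0.0]])
        sel = select_in_roi(pts, self.SQUARE)
        assert len(sel) == 2

    def test_agrees_with_ray_casting_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            # random simple (star-shaped) polygon around its centroid
            k = rng.integers(5, 10)
            ang = np.sort(rng.uniform(0, 2 * np.pi, k))
            rad = rng.uniform(50, 200, k)
            poly = np.column_stack([300 + rad * np.cos(ang), 300 + rad * np.sin(ang)])
            roi = RoiPolygon(poly)
            pts = rng.uniform(0, 600, (100, 2))
            sel = select_in_roi(pts_df(pts), roi)
            for i, (x, y) in enumerate(pts):
                # skip points within numerical reach of the boundary
                if abs(roi.as_shapely().exterior.distance(
                        __import__("shapely.geometry", fromlist=["Point"]).Point(x, y))) < 1e-6:
                    continue
                assert (i in sel.index) == ray_casting_inside(x, y, poly)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            RoiPolygon(np.array([[0, 0], [1, 1], [2, 2]], dtype=float))


class TestProposeRois:
    def test_single_tight_cluster_one_roi(self):
        rng = np.random.default_rng(1)
        xy = rng.normal(0, 40, (50, 2)) + 2000.0
        rois = propose_rois(pts_df(xy), grid_nm=100.0, min_count=5)
        assert len(rois) == 1
        assert len(select_in_roi(pts_df(xy), rois[0])) == 50

    def test_two_distant_clusters_two_rois(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 40, (40, 2)) + [1000.0, 1000.0]
        b = rng.normal(0, 40, (40, 2)) + [3000.0, 1000.0]
        rois = propose_rois(pts_df(np.vstack([a, b])), grid_nm=100.0, min_count=5)
        assert len(rois) == 2

    def test_empty_input(self):
        assert propose_rois(pts_df(np.empty((0, 2)))) == []

    def test_sparse_points_below_min_count_ignored(self):
        xy = np.array([[0.0, 0.0], [5000.0, 5000.0]])
        assert propose_rois(pts_df(xy), grid_nm=100.0, min_count=5) == []


class TestFitCluster:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(3)
        th = np.deg2rad(30.0)
        n = 10_000
        u = rng.normal(0, 90.0, n)
        v = rng.normal(0, 30.0, n)
        x = 5000 + u * np.cos(th) - v * np.sin(th)
        y = 5000 + u * np.sin(th) + v * np.cos(th)
        f = fit_cluster(pts_df(np.column_stack([x, y])))
        assert f.sigma_minor_nm == pytest.approx(30.0, rel=0.05)
        assert f.sigma_major_nm == pytest.approx(90.0, rel=0.05)
        assert np.rad2deg(f.theta) == pytest.approx(30.0, abs=2.0)
        assert f.retained

    def test_collinear_points_degenerate(self):
        xy = np.column_stack([np.linspace(0, 100, 5), np.linspace(0, 50, 5)])
        f = fit_cluster(pts_df(xy))
        assert f.thickness_nm == pytest.approx(0.0, abs=1e-9)
        assert not f.retained

    def test_circle_is_isotropic(self):
        ang = np.linspace(0, 2 * np.pi, 36, endpoint=False)
        xy = np.column_stack([100 * np.cos(ang), 100 * np.sin(ang)])
        f = fit_cluster(pts_df(xy))
        assert f.sigma_minor_nm == pytest.approx(f.sigma_major_nm, rel=1e-9)
        assert f.thickness_nm == pytest.approx(f.length_nm, rel=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_cluster(pts_df(np.zeros((4, 2))))

    def test_thickness_below_resolution_discarded(self):
        rng = np.random.default_rng(4)
        xy = np.column_stack([rng.normal(0, 5.0, 100), rng.normal(0, 80.0, 100)])
        f = fit_cluster(pts_df(xy), resolution_nm=25.0)
        assert not f.retained

    def test_translation_invariance_rotation_equivariance(self):
        rng = np.random.default_rng(5)
        xy = np.column_stack([rng.normal(0, 80.0, 500), rng.normal(0, 30.0, 500)])
        f0 = fit_cluster(pts_df(xy))
        f_shift = fit_cluster(pts_df(xy + [1234.5, -678.9]))
        assert f_shift.sigma_minor_nm == pytest.approx(f0.sigma_minor_nm, rel=1e-9)
        assert f_shift.theta == pytest.approx(f0.theta, abs=1e-9)
        rot = np.deg2rad(40.0)
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        f_rot = fit_cluster(pts_df(xy @ R.T))
        assert f_rot.sigma_major_nm == pytest.approx(f0.sigma_major_nm, rel=1e-9)
        assert f_rot.theta % np.pi == pytest.approx((f0.theta + rot) % np.pi, abs=1e-6)

    def test_fwhm_factor(self):
        assert FWHM_FACTOR == pytest.approx(2.3548, abs=1e-4)
        rng = np.random.default_rng(6)
        xy = np.column_stack([rng.normal(0, 50.0, 200), rng.normal(0, 20.0, 200)])
        f = fit_cluster(pts_df(xy))
        assert f.thickness_nm == pytest.approx(FWHM_FACTOR * f.sigma_minor_nm, rel=1e-12)
        assert f.length_nm == pytest.approx(FWHM_FACTOR * f.sigma_major_nm, rel=1e-12)
        assert f.thickness_nm <= f.length_nm


class TestSummarize:
    def _fit(self, n, thickness=60.0, length=120.0, retained=True):
        from ccpalm.clusters import ClusterFit
        return ClusterFit(label="", n_molecules=n, center=(0, 0),
                          sigma_minor_nm=thickness / FWHM_FACTOR,
                          sigma_major_nm=length / FWHM_FACTOR,
                          theta=0.0, thickness_nm=thickness, length_nm=length,
                          retained=retained)

    def test_mean_content(self):
        s = summarize_clusters([self._fit(20), self._fit(20), self._fit(21)])
        assert s.mean_molecules == pytest.approx(61 / 3)

    def test_exact_log_model_recovered(self):
        ns = np.array([5, 10, 20, 50, 100, 200])
        fits = [self._fit(int(n), thickness=40.0 * np.log(n) + 5.0) for n in ns]
        s = summarize_clusters(fits)
        a, b = s.thickness_fit
        assert a == pytest.approx(40.0, rel=1e-9)
        assert b == pytest.approx(5.0, abs=1e-6)

    def test_discarded_counted_not_included(self):
        fits = [self._fit(10), self._fit(1000, retained=False)]
        s = summarize_clusters(fits)
        assert s.n_clusters == 2
        assert s.n_discarded_small == 1
        assert s.max_molecules == 10

    def test_fraction_below_50(self):
        fits = [self._fit(n) for n in (10, 20, 30, 60)]
        s = summarize_clusters(fits)
        assert s.fraction_below_50 == pytest.approx(0.75)

    def test_all_discarded_raises(self):
        with pytest.raises(ValueError):
            summarize_clusters([self._fit(10, retained=False)])

    def test_phantom_population_statistics(self):
        # content lognormal with mean ~20 -> most clusters below 50 molecules
        from ccpalm.synthetic import build_phantom, cord_layout
        ns = []
        for seed in range(40):
            layout = cord_layout(n_clusters=10, seed=seed)
            ns.extend(c[4] for c in layout.clusters)
        frac = np.mean(np.asarray(ns) < 50)
        assert 0.85 <= frac <= 0.97


class TestAnalyzeRois:
    def test_roi_with_few_points_skipped(self):
        rng = np.random.default_rng(7)
        xy = rng.normal(0, 40, (30, 2)) + 1000.0
        rois = propose_rois(pts_df(xy), grid_nm=100.0, min_count=5)
        rois.append(RoiPolygon(np.array([[5000, 5000], [5100, 5000], [5050, 5100]], dtype=float),
                               label="empty"))
        with pytest.warns(UserWarning):
            fits = analyze_rois(pts_df(xy), rois)
        assert len(fits) == 1
        assert fits[0].n_molecules == 30

    def test_fits_table_columns(self):
        rng = np.random.default_rng(8)
        xy = rng.normal(0, 40, (30, 2))
        fits = [fit_cluster(pts_df(xy), label="a")]
        df = fits_to_table(fits)
        assert df.loc[0, "label"] == "a"
        assert df.loc[0, "thickness_nm"] <= df.loc[0, "length_nm"]

    def test_phantom_fitted_sizes_respect_bounds(self):
        # generated with FWHM thickness < 200 and length < 450: fitted population
        # reproduces those bounds for >= 95% of clusters
        from ccpalm.synthetic import build_phantom, cord_layout
        rng = np.random.default_rng(9)
        ok, total = 0, 0
        for seed in range(8):
            layout = cord_layout(n_clusters=10, seed=100 + seed)
            ems = build_phantom(layout, seed=seed)
            df = pd.DataFrame({"x_nm": [e.x for e in ems], "y_nm": [e.y for e in ems],
                               "cid": [e.cluster_id for e in ems]})
            for cid, g in df.groupby("cid"):
                if len(g) < 5:
                    continue
                f = fit_cluster(g)
                total += 1
                if f.thickness_nm < 200.0 and f.length_nm < 450.0:
                    ok += 1
        assert ok / total >= 0.95
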