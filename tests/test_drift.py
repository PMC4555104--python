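import numpy as np
import pandas as pd
import pytest

from ccpalm.drift import (
    DriftTrajectory,
    batch_localizations,
    correct_drift,
    estimate_drift,
    fit_drift,
    histogram_image,
    phase_correlate,
)


def clustered_locs(n_emitters=300, reappearances=20, n_frames=4000, jitter=15.0, seed=0):
    """Fixed emitters in small clusters, each re-detected in random frames."""
    rng = np.random.default_rng(seed)
    centers = rng.uniform(1000, 12000, (40, 2))
    ex = np.repeat(centers[:, 0], n_emitters // 40 + 1)[:n_emitters] + rng.normal(0, 40, n_emitters)
    ey = np.repeat(centers[:, 1], n_emitters // 40 + 1)[:n_emitters] + rng.normal(0, 40, n_emitters)
    rows = []
    for i in range(n_emitters):
        for f in rng.integers(0, n_frames, reappearances):
            rows.append((int(f), ex[i] + rng.normal(0, jitter), ey[i] + rng.normal(0, jitter)))
    df = pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm"])
    return df.sort_values("frame").reset_index(drop=True)


class TestBatching:
    def test_partition_sizes(self):
        locs = pd.DataFrame({"frame": np.arange(2500), "x_nm": 0.0, "y_nm": 0.0})
        sizes = [len(b) for b in batch_localizations(locs, 1000)]
        assert sizes == [1000, 1000, 500]

    def test_frame_ranges_disjoint_increasing(self):
        rng = np.random.default_rng(1)
        locs = pd.DataFrame({"frame": np.sort(rng.integers(0, 500, 1200)),
                             "x_nm": 0.0, "y_nm": 0.0})
        batches = batch_localizations(locs, 400)
        for a, b in zip(batches, batches[1:]):
            assert a["frame"].max() <= b["frame"].min()

    def test_union_is_input(self):
        rng = np.random.default_rng(2)
        locs = pd.DataFrame({"frame": rng.integers(0, 100, 700),
                             "x_nm": rng.uniform(0, 1000, 700),
                             "y_nm": rng.uniform(0, 1000, 700)})
        batches = batch_localizations(locs, 300)
        merged = pd.concat(batches)
        assert len(merged) == len(locs)
        assert sorted(merged["x_nm"]) == pytest.approx(sorted(locs["x_nm"]))

    def test_too_few_batches_refused(self):
        locs = pd.DataFrame({"frame": np.arange(150), "x_nm": 0.0, "y_nm": 0.0})
        with pytest.raises(ValueError):
            batch_localizations(locs, 100)


class TestHistogramImage:
    def test_single_point(self):
        df = pd.DataFrame({"x_nm": [55.0], "y_nm": [25.0]})
        img = histogram_image(df, 10.0, extent=(0.0, 0.0), shape=(5, 8))
        assert img.sum() == 1
        assert img[2, 5] == 1

    def test_sum_equals_cardinality(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x_nm": rng.uniform(0, 5000, 400), "y_nm": rng.uniform(0, 5000, 400)})
        img = histogram_image(df, 100.0)
        assert img.sum() == 400

    def test_edge_point_goes_to_higher_bin(self):
        df = pd.DataFrame({"x_nm": [100.0], "y_nm": [0.0]})
        img = histogram_image(df, 100.0, extent=(0.0, 0.0), shape=(2, 3))
        assert img[0, 1] == 1  # exactly on the edge between bin 0 and 1

    def test_empty_subset_raises(self):
        with pytest.raises(ValueError):
            histogram_image(pd.DataFrame({"x_nm": [], "y_nm": []}), 10.0)


class TestPhaseCorrelate:
    def test_identical_images_zero_shift(self):
        rng = np.random.default_rng(3)
        img = rng.poisson(2.0, (64, 64)).astype(float)
        d0, d1 = phase_correlate(img, img)
        assert abs(d0) < 0.05 and abs(d1) < 0.05

    def test_integer_circular_shift(self):
        rng = np.random.default_rng(4)
        img = rng.poisson(2.0, (64, 64)).astype(float)
        b = np.roll(img, (3, -2), axis=(0, 1))
        d0, d1 = phase_correlate(img, b)
        assert d0 == pytest.approx(3.0, abs=0.05)
        assert d1 == pytest.approx(-2.0, abs=0.05)

    def test_subpixel_shift_of_binned_points(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(500, 5500, (4000, 2))
        a = pd.DataFrame({"x_nm": pts[:, 0], "y_nm": pts[:, 1]})
        b = pd.DataFrame({"x_nm": pts[:, 0] + 40.0, "y_nm": pts[:, 1]})
        kw = dict(extent=(0.0, 0.0), shape=(70, 70))
        d0, d1 = phase_correlate(histogram_image(a, 100.0, **kw), histogram_image(b, 100.0, **kw))
        assert d1 == pytest.approx(0.4, abs=0.1)
        assert d0 == pytest.approx(0.0, abs=0.1)

    def test_shape_mismatch_and_zero_image(self):
        with pytest.raises(ValueError):
            phase_correlate(np.ones((4, 4)), np.ones((5, 5)))
        with pytest.raises(ValueError):
            phase_correlate(np.zeros((8, 8)), np.ones((8, 8)))


class TestFitDrift:
    def test_zero_shifts_zero_trajectory(self):
        shifts = [(100.0, 0.0, 0.0), (300.0, 0.0, 0.0), (500.0, 0.0, 0.0)]
        traj = fit_drift(shifts, 1, 600)
        assert np.allclose(traj.dx_nm, 0.0)
        assert np.allclose(traj.dy_nm, 0.0)

    def test_exact_linear_interpolation(self):
        mids = [100.0, 300.0, 500.0]
        shifts = [(m, 0.5 * m - 50.0, -0.2 * m + 20.0) for m in mids]
        traj = fit_drift(shifts, 1, 600)
        for m, sx, sy in shifts:
            assert traj.dx_nm[int(m)] - traj.dx_nm[100] == pytest.approx(sx - shifts[0][1], abs=1e-6)
            assert traj.dy_nm[int(m)] - traj.dy_nm[100] == pytest.approx(sy - shifts[0][2], abs=1e-6)

    def test_anchored_at_first_batch_midpoint(self):
        shifts = [(50.0, 10.0, -5.0), (150.0, 30.0, -15.0), (250.0, 60.0, -30.0)]
        traj = fit_drift(shifts, 2, 300)
        assert traj.dx_nm[50] == pytest.approx(0.0, abs=1e-9)
        assert traj.dy_nm[50] == pytest.approx(0.0, abs=1e-9)

    def test_degree_too_high(self):
        with pytest.raises(ValueError):
            fit_drift([(0.0, 0.0, 0.0), (10.0, 1.0, 1.0)], 2, 20)


class TestCorrectDrift:
    def test_zero_trajectory_identity(self):
        locs = clustered_locs(n_emitters=50, reappearances=3, n_frames=100)
        traj = DriftTrajectory(np.zeros(100), np.zeros(100))
        out = correct_drift(locs, traj)
        assert np.allclose(out["x_nm"], locs["x_nm"])

    def test_involution(self):
        locs = clustered_locs(n_emitters=50, reappearances=3, n_frames=100)
        rng = np.random.default_rng(0)
        traj = DriftTrajectory(rng.normal(0, 20, 100), rng.normal(0, 20, 100))
        out = correct_drift(correct_drift(locs, traj), traj.negated())
        assert np.allclose(out["x_nm"], locs["x_nm"], atol=1e-9)
        assert np.allclose(out["y_nm"], locs["y_nm"], atol=1e-9)

    def test_frame_outside_trajectory(self):
        locs = pd.DataFrame({"frame": [5], "x_nm": [0.0], "y_nm": [0.0]})
        with pytest.raises(ValueError):
            correct_drift(locs, DriftTrajectory(np.zeros(3), np.zeros(3)))


class TestEndToEnd:
    def _inject(self, locs, n_frames, ax=400.0, bx=0.0, ay=-300.0, by=150.0):
        f = locs["frame"].to_numpy() / n_frames
        out = locs.copy()
        out["x_nm"] = out["x_nm"] + ax * f**2 + bx * f
        out["y_nm"] = out["y_nm"] + ay * f + by * f**2
        ff = np.arange(n_frames) / n_frames
        return out, ax * ff**2 + bx * ff, ay * ff + by * ff**2

    def test_quadratic_drift_recovery(self):
        n_frames = 4000
        locs = clustered_locs(n_emitters=300, reappearances=20, n_frames=n_frames, seed=6)
        drifted, tdx, tdy = self._inject(locs, n_frames)
        traj = estimate_drift(drifted, n_frames, batch_size=1000, bin_size_nm=100.0, degree=2)
        m0 = int(traj.batch_shifts[0][0])
        rms = np.sqrt(np.mean((traj.dx_nm - (tdx - tdx[m0])) ** 2 +
                              (traj.dy_nm - (tdy - tdy[m0])) ** 2))
        assert rms <= 25.0  # bin_size / 4

    def test_correction_tightens_single_emitter(self):
        n_frames = 4000
        rng = np.random.default_rng(7)
        locs = clustered_locs(n_emitters=300, reappearances=20, n_frames=n_frames, seed=8)
        # one bright repeatedly-blinking emitter
        extra = pd.DataFrame({
            "frame": np.sort(rng.integers(0, n_frames, 100)),
            "x_nm": 7000.0 + rng.normal(0, 10, 100),
            "y_nm": 7000.0 + rng.normal(0, 10, 100),
        })
        locs = pd.concat([locs, extra], ignore_index=True).sort_values("frame").reset_index(drop=True)
        tag = np.hypot(locs["x_nm"] - 7000, locs["y_nm"] - 7000) < 60
        drifted, _, _ = self._inject(locs, n_frames)
        traj = estimate_drift(drifted, n_frames, batch_size=1000, bin_size_nm=100.0, degree=2)
        corrected = correct_drift(drifted, traj)
        std_before = drifted.loc[tag, ["x_nm", "y_nm"]].std().mean()
        std_after = corrected.loc[tag, ["x_nm", "y_nm"]].std().mean()
        assert std_after < std_before
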