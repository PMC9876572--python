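import numpy as np
import pandas as pd
import pytest

from desmonet import (
    GaitConfig,
    KeypointTrack,
    acicular_angles,
    bodyline_axis,
    fit_sinusoid,
    gait_angle_series,
    gait_heatmap,
    generate_gait_tracks,
    inter_acicular,
    normalize_range,
    phase_lag_deg,
)


def make_track(points, n=1, likelihood=0.99):
    """Build a track from {part: (x, y)} static image coordinates."""
    data = {}
    for part, (x, y) in points.items():
        data[f"{part}_x"] = [float(x)] * n
        data[f"{part}_y"] = [float(y)] * n
        data[f"{part}_likelihood"] = [likelihood] * n
    return KeypointTrack.from_frame(pd.DataFrame(data, index=pd.RangeIndex(n)))


def base_points(**overrides):
    pts = {
        "pharynx": (0.0, 0.0),
        "proctodeum": (0.0, 10.0),
        "sg1l_not_prox": (5.0, 5.0),
        "sg1l_not_dist": (5.0, 8.0),
        "sg1l_neu_prox": (6.0, 5.0),
        "sg1l_neu_dist": (6.0, 8.0),
    }
    pts.update(overrides)
    return pts


def rotate(points, deg, about=(0.0, 0.0)):
    """Rotate image-space points (counterclockwise in image coords)."""
    th = np.radians(deg)
    c, s = np.cos(th), np.sin(th)
    out = {}
    for part, (x, y) in points.items():
        dx, dy = x - about[0], y - about[1]
        out[part] = (about[0] + c * dx - s * dy, about[1] + s * dx + c * dy)
    return out


class TestBodylineAxis:
    def test_vertical_bodyline_points_down_in_yup_frame(self):
        track = make_track(base_points())
        axis = bodyline_axis(track, 0)
        np.testing.assert_allclose(axis, [0.0, -1.0], atol=1e-12)

    def test_coincident_anchors_error(self):
        track = make_track(base_points(proctodeum=(0.0, 0.0)))
        with pytest.raises(ValueError, match="coincide"):
            bodyline_axis(track, 0)

    def test_axis_corotates_with_rigid_rotation(self):
        track = make_track(base_points())
        rot = make_track(rotate(base_points(), 30.0))
        a = bodyline_axis(track, 0)
        b = bodyline_axis(rot, 0)
        # image-frame rotation by +30 deg is a -30 deg rotation in y-up
        th = np.radians(-30.0)
        expected = np.array([
            np.cos(th) * a[0] - np.sin(th) * a[1],
            np.sin(th) * a[0] + np.cos(th) * a[1],
        ])
        np.testing.assert_allclose(b, expected, atol=1e-12)

    def test_low_likelihood_anchor_rejected(self):
        track = make_track(base_points(), likelihood=0.5)
        with pytest.raises(ValueError, match="likelihood"):
            bodyline_axis(track, 0)


class TestAcicularAngles:
    def test_parallel_acicula_is_zero_degrees(self):
        track = make_track(base_points())  # acicula along the bodyline
        ang = acicular_angles(track, "sg1l", lobe="not")
        assert ang.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_acicula_is_ninety_degrees(self):
        track = make_track(base_points(sg1l_not_dist=(8.0, 5.0)))
        ang = acicular_angles(track, "sg1l", lobe="not")
        assert ang.iloc[0] == pytest.approx(90.0, abs=1e-9)

    def test_rotation_translation_scale_invariance(self):
        pts = base_points(sg1l_not_dist=(7.0, 7.5))
        ref = acicular_angles(make_track(pts), "sg1l").iloc[0]
        rot = acicular_angles(make_track(rotate(pts, 73.0)), "sg1l").iloc[0]
        shifted = {p: (x + 40, y - 7) for p, (x, y) in pts.items()}
        sca = {p: (3 * x, 3 * y) for p, (x, y) in pts.items()}
        assert rot == pytest.approx(ref, abs=1e-9)
        assert acicular_angles(make_track(shifted), "sg1l").iloc[0] == \
            pytest.approx(ref, abs=1e-9)
        assert acicular_angles(make_track(sca), "sg1l").iloc[0] == \
            pytest.approx(ref, abs=1e-9)

    def test_low_likelihood_frames_become_missing(self):
        pts = base_points()
        df_rows = []
        for frame in range(10):
            row = {}
            for part, (x, y) in pts.items():
                row[f"{part}_x"] = x
                row[f"{part}_y"] = y
                row[f"{part}_likelihood"] = 0.2 if frame == 5 else 0.99
            df_rows.append(row)
        track = KeypointTrack.from_frame(pd.DataFrame(df_rows))
        # a single bad frame sits in a short gap: interpolated by default
        ang = acicular_angles(track, "sg1l", max_gap=3)
        assert not ang.isna().any()
        # with interpolation disabled the frame stays missing
        ang2 = acicular_angles(track, "sg1l", max_gap=0)
        assert ang2.isna().sum() == 1 and np.isnan(ang2.iloc[5])

    def test_unknown_parapodium_rejected(self):
        with pytest.raises(KeyError, match="sg9r"):
            acicular_angles(make_track(base_points()), "sg9r")

    def test_recovery_from_noisy_synthetic_gait(self):
        cfg = GaitConfig(n_frames=500, amplitude_deg=30.0, noise_sd_px=1.0,
                         seed=4)
        track = generate_gait_tracks(cfg)
        truth = gait_angle_series(cfg)
        for pp in ("sg1l", "sg2r"):
            rec = acicular_angles(track, pp, lobe="not")
            rmse = float(np.sqrt(np.mean((rec - truth[pp]["not"]) ** 2)))
            assert rmse < 2.0


class TestNormalizeRange:
    def test_linear_map_to_0_100(self):
        s = pd.Series([10.0, 20.0, 30.0])
        assert list(normalize_range(s)) == [0.0, 50.0, 100.0]

    def test_constant_series_warns_and_is_missing(self):
        with pytest.warns(UserWarning, match="zero angular range"):
            out = normalize_range(pd.Series([5.0, 5.0, 5.0]))
        assert out.isna().all()

    @pytest.mark.parametrize("a,b", [(2.0, 0.0), (0.5, -3.0), (7.0, 100.0)])
    def test_affine_invariance(self, a, b):
        s = pd.Series([3.0, 1.0, 4.0, 1.5, 9.0])
        pd.testing.assert_series_equal(
            normalize_range(a * s + b), normalize_range(s), atol=1e-9)

    def test_missing_values_propagate(self):
        s = pd.Series([0.0, np.nan, 10.0])
        out = normalize_range(s)
        assert np.isnan(out.iloc[1])
        assert out.iloc[2] == 100.0


class TestInterAcicular:
    def test_parallel_pair_is_zero(self):
        ang = inter_acicular(make_track(base_points()), "sg1l")
        assert ang.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_counterclockwise_rotation_is_positive_fifty(self):
        pts = base_points()
        # rotate the neuropodial acicula by +50 deg in the y-up frame
        prox = np.array(pts["sg1l_neu_prox"])
        vec_img = np.array(pts["sg1l_neu_dist"]) - prox
        vec_up = np.array([vec_img[0], -vec_img[1]])
        th = np.radians(50.0)
        rot_up = np.array([
            np.cos(th) * vec_up[0] - np.sin(th) * vec_up[1],
            np.sin(th) * vec_up[0] + np.cos(th) * vec_up[1],
        ])
        pts["sg1l_neu_dist"] = tuple(prox + np.array([rot_up[0], -rot_up[1]]))
        ang = inter_acicular(make_track(pts), "sg1l")
        assert ang.iloc[0] == pytest.approx(50.0, abs=1e-9)

    def test_sign_flips_under_mirror(self):
        pts = base_points(sg1l_neu_dist=(8.0, 7.0))
        mirrored = {p: (-x, y) for p, (x, y) in pts.items()}
        a = inter_acicular(make_track(pts), "sg1l").iloc[0]
        b = inter_acicular(make_track(mirrored), "sg1l").iloc[0]
        assert b == pytest.approx(-a, abs=1e-9)

    def test_zero_length_vector_warns_and_is_missing(self):
        pts = base_points(sg1l_neu_dist=base_points()["sg1l_neu_prox"])
        with pytest.warns(UserWarning, match="zero-length"):
            ang = inter_acicular(make_track(pts), "sg1l")
        assert np.isnan(ang.iloc[0])


class TestGaitHeatmapAndSpectra:
    def test_rows_span_exactly_0_to_100(self):
        cfg = GaitConfig(n_frames=300, seed=1)
        truth = gait_angle_series(cfg)
        matrix, _ = gait_heatmap({pp: truth[pp]["not"] for pp in cfg.parapodia})
        assert np.allclose(matrix.min(axis=1), 0.0)
        assert np.allclose(matrix.max(axis=1), 100.0)

    def test_constant_phase_gives_zero_lag(self):
        cfg = GaitConfig(n_frames=400, phase_lag_deg=0.0, noise_sd_px=0.0,
                         seed=0)
        truth = gait_angle_series(cfg)
        _, lags = gait_heatmap({pp: truth[pp]["not"] for pp in cfg.parapodia})
        for v in lags.values():
            assert v == pytest.approx(0.0, abs=1e-6)

    def test_planted_lag_recovered_from_noisy_tracks(self):
        cfg = GaitConfig(n_frames=500, phase_lag_deg=40.0, noise_sd_px=1.0,
                         seed=12)
        track = generate_gait_tracks(cfg)
        series = {pp: acicular_angles(track, pp, lobe="not")
                  for pp in cfg.parapodia}
        _, lags = gait_heatmap(series)
        for key, v in lags.items():
            assert abs(v) == pytest.approx(40.0, abs=5.0)

    def test_sinusoid_fit_recovers_amplitude_and_mean(self):
        t = np.arange(480)
        s = pd.Series(60.0 + 30.0 * np.sin(2 * np.pi * t / 40 + 0.7))
        fit = fit_sinusoid(s)
        assert fit["amplitude"] == pytest.approx(30.0, abs=1e-6)
        assert fit["mean"] == pytest.approx(60.0, abs=1e-6)
        assert fit["freq"] == pytest.approx(1 / 40, abs=1e-9)
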