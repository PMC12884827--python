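"""Kinematics, bout segmentation, burst-movement alignment, and curvature."""

import numpy as np
import pytest

from thetaburst.behavior import (
    MotionBout,
    burst_movement_alignment,
    curvature_permutation_test,
    detect_bouts,
    egocentric_curvature,
    heading_distribution,
    kinematics,
    movement_initiations,
    periburst_velocity,
)
from thetaburst.bursts import BurstEvent
from thetaburst.session import TrackingData
from thetaburst.spectral import THETA

FPS = 20.0


def _tracking_from_path(xy, fps=FPS, heading=None, nose_on_path=False):
    """Tracking whose centre point follows ``xy``.

    With ``nose_on_path`` the nose itself traces ``xy`` (used by curvature
    tests, which analyse the nose trajectory); otherwise the nose sits 2 cm
    ahead of the centre along the heading, as on a real animal.
    """
    n = len(xy)
    if heading is None:
        d = np.gradient(xy, axis=0)
        heading = np.arctan2(d[:, 1], d[:, 0])
    u = np.column_stack([np.cos(heading), np.sin(heading)])
    nose = xy if nose_on_path else xy + 2.0 * u
    return TrackingData(
        time_s=np.arange(n) / fps,
        landmarks={
            "nose": nose,
            "back": xy - 0.5 * u,
            "tail_base": nose - 3.5 * u,
        },
        frame_rate=fps,
    )


def _tracking_from_speed(speed, fps=FPS):
    """Straight-line trajectory with a prescribed speed profile."""
    x = np.concatenate(([0.0], np.cumsum(speed[:-1]) / fps))
    xy = np.column_stack([x, np.zeros_like(x)])
    return _tracking_from_path(xy, fps, heading=np.zeros(len(x)))


def _ev(start, dur=0.4):
    return BurstEvent(region="CA1", band=THETA, start_s=start, end_s=start + dur)


class TestKinematics:
    def test_stationary_animal(self):
        trk = _tracking_from_speed(np.zeros(200))
        kin = kinematics(trk)
        assert np.all(kin.velocity_cm_s < 0.01)
        assert np.all(np.isnan(kin.heading_rad))

    def test_linear_motion(self):
        trk = _tracking_from_speed(np.full(400, 3.0))
        kin = kinematics(trk)
        core = slice(10, -10)
        np.testing.assert_allclose(kin.velocity_cm_s[core], 3.0, atol=0.05)
        np.testing.assert_allclose(kin.heading_rad[core], 0.0, atol=0.05)

    def test_circular_path_heading_rate(self):
        r, speed = 5.0, 4.0
        n = 600
        t = np.arange(n) / FPS
        theta = speed * t / r
        xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        kin = kinematics(_tracking_from_path(xy))
        core = slice(20, -20)
        rate = np.abs(np.gradient(np.unwrap(kin.heading_rad), kin.time_s))
        np.testing.assert_allclose(rate[core], speed / r, rtol=0.1)

    def test_single_frame_rejected(self):
        trk = _tracking_from_speed(np.zeros(2))
        trk.time_s = trk.time_s[:1]
        trk.landmarks = {k: v[:1] for k, v in trk.landmarks.items()}
        with pytest.raises(ValueError):
            kinematics(trk)


class TestBouts:
    def _designed_speed(self, n_bouts=12, fps=FPS):
        rest = np.zeros(int(6 * fps))
        segs = [rest]
        onsets = []
        t = len(rest)
        for _ in range(n_bouts):
            ramp = np.linspace(0, 4.0, int(0.25 * fps))
            hold = np.full(int(2.0 * fps), 4.0)
            bout = np.concatenate([ramp, hold, ramp[::-1]])
            onsets.append(t / fps)
            segs += [bout, rest]
            t += len(bout) + len(rest)
        return np.concatenate(segs), np.array(onsets)

    def test_designed_bouts_recovered(self):
        speed, onsets = self._designed_speed()
        kin = kinematics(_tracking_from_speed(speed))
        bouts = [b for b in detect_bouts(kin) if b.kind == "motion"]
        assert len(bouts) == len(onsets)
        det = np.array([b.start_s for b in bouts])
        # onset = upward crossing of 1.5 cm/s; ramp reaches 1.5 within ~2 frames
        assert np.all(np.abs(det - onsets) <= 4 / FPS)

    def test_zero_velocity_one_rest_no_motion(self):
        kin = kinematics(_tracking_from_speed(np.zeros(600)))
        bouts = detect_bouts(kin)
        assert sum(b.kind == "motion" for b in bouts) == 0
        rests = [b for b in bouts if b.kind == "rest"]
        assert len(rests) == 1
        assert rests[0].duration_s > 25.0

    def test_brief_spike_is_not_a_bout(self):
        speed = np.zeros(600)
        speed[300:310] = 3.0  # 0.5 s spike
        kin = kinematics(_tracking_from_speed(speed))
        assert sum(b.kind == "motion" for b in detect_bouts(kin)) == 0

    def test_bouts_and_rests_never_overlap(self):
        speed, _ = self._designed_speed()
        kin = kinematics(_tracking_from_speed(speed))
        bouts = detect_bouts(kin)
        motion = [b for b in bouts if b.kind == "motion"]
        rests = [b for b in bouts if b.kind == "rest"]
        for m in motion:
            for r in rests:
                assert m.end_s <= r.start_s or r.end_s <= m.start_s

    def test_idempotent(self):
        speed, _ = self._designed_speed()
        kin = kinematics(_tracking_from_speed(speed))
        a = detect_bouts(kin)
        b = detect_bouts(kin)
        assert [(x.kind, x.start_s, x.end_s) for x in a] == [(x.kind, x.start_s, x.end_s) for x in b]


class TestAlignment:
    def test_initiations_require_prior_rest(self):
        speed = np.zeros(int(30 * FPS))
        speed[int(10 * FPS) : int(13 * FPS)] = 3.0  # after 10 s rest -> initiation
        speed[int(14 * FPS) : int(17 * FPS)] = 3.0  # only 1 s gap -> not an initiation
        kin = kinematics(_tracking_from_speed(speed))
        inits = movement_initiations(kin)
        assert len(inits) == 1
        assert inits[0].start_s == pytest.approx(10.0, abs=0.3)

    def test_single_burst_at_onset_peaks_density_at_zero(self):
        inits = [MotionBout(kind="initiation", start_s=50.0, end_s=53.0)]
        out = burst_movement_alignment([_ev(50.0)], inits)
        assert out["pct_initiations_with_burst"] == 100.0
        peak_bin = out["bin_centers_s"][np.argmax(out["smoothed_density"])]
        assert abs(peak_bin) < 0.15

    def test_no_initiations(self):
        out = burst_movement_alignment([_ev(10.0)], [])
        assert out["pct_initiations_with_burst"] == 0.0
        assert out["smoothed_density"] is None

    def test_density_unit_area(self, rng):
        inits = [MotionBout(kind="initiation", start_s=s, end_s=s + 2) for s in np.arange(20, 580, 20.0)]
        bursts = [_ev(s) for s in rng.uniform(0, 600, 200)]
        out = burst_movement_alignment(bursts, inits)
        bin_w = out["bin_centers_s"][1] - out["bin_centers_s"][0]
        assert np.sum(out["smoothed_density"]) * bin_w == pytest.approx(1.0, abs=1e-9)


class TestPeriburstVelocity:
    def _kin(self, speed):
        return kinematics(_tracking_from_speed(speed))

    def test_constant_velocity_no_significant_bins(self):
        speed = np.full(int(600 * FPS), 3.0)
        kins = {f"s{i}": self._kin(speed) for i in range(4)}
        bursts = {f"s{i}": [_ev(t) for t in np.arange(20, 580, 20.0)] for i in range(4)}
        out = periburst_velocity(bursts, kins)
        assert out["n_significant_bins"] == 0

    def test_velocity_step_after_bursts_detected(self, rng):
        onsets = np.arange(20, 580, 20.0)
        kins, bursts = {}, {}
        for i in range(5):
            speed = 0.5 + 0.05 * rng.standard_normal(int(600 * FPS))
            for t in onsets:
                i0 = int((t + 0.2) * FPS)
                speed[i0 : i0 + int(1.5 * FPS)] += 2.0  # step 0.2-1.7 s after onset
            kins[f"s{i}"] = self._kin(np.abs(speed))
            bursts[f"s{i}"] = [_ev(t) for t in onsets]
        out = periburst_velocity(bursts, kins)
        assert out["n_significant_bins"] >= 10
        sig_times = out["bin_centers_s"][out["significant_mask"]]
        assert sig_times.min() > 0.0 and sig_times.max() < 2.5

    def test_bursts_near_edges_excluded(self):
        speed = np.full(int(20 * FPS), 3.0)
        kin = self._kin(speed)
        out = periburst_velocity({"a": [_ev(0.5)], "b": [_ev(1.0)]}, {"a": kin, "b": kin})
        assert out["n_subjects"] == 0


class TestHeading:
    def test_directional_bursts(self):
        trk = _tracking_from_speed(np.full(int(60 * FPS), 3.0))
        kin = kinematics(trk)
        out = heading_distribution([_ev(t) for t in np.arange(5, 55, 2.0)], kin)
        assert out["rayleigh"].p < 1e-4
        assert abs(out["rayleigh"].mean_direction) < 0.2

    def test_uniform_headings_not_directional(self, rng):
        n = int(600 * FPS)
        heading = rng.uniform(-np.pi, np.pi, n)
        xy = np.cumsum(np.column_stack([np.cos(heading), np.sin(heading)]) * 3.0 / FPS, axis=0)
        kin = kinematics(_tracking_from_path(xy))
        out = heading_distribution([_ev(t) for t in rng.uniform(5, 590, 300)], kin)
        assert out["rayleigh"].p > 0.01

    def test_too_few_valid_headings_flagged(self):
        trk = _tracking_from_speed(np.zeros(400))
        kin = kinematics(trk)
        out = heading_distribution([_ev(5.0)], kin)
        assert "too_few_valid_headings" in out["flags"]


def _semicircle_tracking(r=5.0, n=200, rotate=0.0):
    th = np.linspace(0, np.pi, n)
    xy = np.column_stack([r * np.cos(th), r * np.sin(th)])
    tangent = th + np.pi / 2
    if rotate:
        rot = np.array([[np.cos(rotate), -np.sin(rotate)], [np.sin(rotate), np.cos(rotate)]])
        xy = xy @ rot.T
        tangent = tangent + rotate
    return _tracking_from_path(xy, heading=tangent, nose_on_path=True)


class TestCurvature:
    def test_straight_bout_flat_profile(self):
        trk = _tracking_from_speed(np.full(100, 4.0))
        prof = egocentric_curvature(MotionBout(kind="motion", start_s=0.0, end_s=4.9), trk)
        assert prof.auc < 0.05
        assert np.all(np.abs(prof.curvature) < 0.05)

    def test_semicircle_curvature_and_auc(self):
        r = 5.0
        prof = egocentric_curvature(MotionBout(kind="motion", start_s=0.0, end_s=9.9), _semicircle_tracking(r))
        interior = np.abs(prof.curvature[5:-5])
        np.testing.assert_allclose(interior, 1 / r, rtol=0.05)
        assert prof.auc == pytest.approx(np.pi, rel=0.05)
        assert prof.path_length_cm == pytest.approx(np.pi * r, rel=0.02)
        assert len(prof.curvature) == 100

    def test_rotation_invariance(self):
        bout = MotionBout(kind="motion", start_s=0.0, end_s=9.9)
        a = egocentric_curvature(bout, _semicircle_tracking())
        b = egocentric_curvature(bout, _semicircle_tracking(rotate=1.1))
        assert abs(a.auc - b.auc) / a.auc < 1e-6

    def test_reversed_path_same_auc(self):
        th = np.linspace(0, 2.5, 300)
        xy = np.column_stack([np.cos(3 * th) + th, np.sin(2 * th)]) * 3.0
        bout = MotionBout(kind="motion", start_s=0.0, end_s=14.9)
        a = egocentric_curvature(bout, _tracking_from_path(xy, nose_on_path=True))
        b = egocentric_curvature(bout, _tracking_from_path(xy[::-1], nose_on_path=True))
        assert a.auc == pytest.approx(b.auc, rel=0.05)

    def test_zigzag_exceeds_straight(self):
        n = 240
        x = np.linspace(0, 20, n)
        zig = np.column_stack([x, 2.0 * np.abs((x % 4) - 2) - 1])
        straight = np.column_stack([x, np.zeros(n)])
        bout = MotionBout(kind="motion", start_s=0.0, end_s=11.9)
        a = egocentric_curvature(bout, _tracking_from_path(zig, nose_on_path=True))
        b = egocentric_curvature(bout, _tracking_from_path(straight, nose_on_path=True))
        assert a.auc > b.auc

    def test_short_path_excluded(self):
        trk = _tracking_from_speed(np.full(100, 0.1))
        assert egocentric_curvature(MotionBout(kind="motion", start_s=0.0, end_s=4.9), trk) is None


class TestPermutation:
    def test_identical_groups_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        out = curvature_permutation_test(a, a.copy())
        assert out["p_perm"] == 1.0

    def test_exact_enumeration_all_positive(self, rng):
        a = 1.0 + np.abs(rng.normal(0, 0.2, 8))
        out = curvature_permutation_test(a, np.zeros(8))
        assert out["method"] == "exact"
        assert out["p_perm"] == pytest.approx(2 / 256)

    def test_monte_carlo_agrees_with_exact(self, rng):
        a = 1.0 + np.abs(rng.normal(0, 0.2, 8))
        exact = curvature_permutation_test(a, np.zeros(8))["p_perm"]
        mc = curvature_permutation_test(a, np.zeros(8), n_perm=10000, seed=3, exact_max_n=0)["p_perm"]
        assert abs(mc - exact) < 0.005

    def test_null_calibration(self, rng):
        ps = []
        for _ in range(300):
            d = rng.normal(0, 1, 8)
            ps.append(curvature_permutation_test(d, np.zeros(8))["p_perm"])
        assert np.mean(np.array(ps) < 0.05) < 0.12

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            curvature_permutation_test([1.0, 2.0], [0.0, 1.0])
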