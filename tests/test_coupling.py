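"""Burst pairing, phase locking, circular statistics, and envelope lag."""

import numpy as np
import pytest
from scipy.special import i0, i1

from thetaburst.bursts import BurstEvent, detect_bursts, filter_min_duration
from thetaburst.coupling import (
    circular_mean,
    classify_coupled,
    envelope_lag,
    fisher_z,
    latency_split_correlation,
    mww,
    pair_bursts,
    periburst_plv,
    plv,
    postburst_phase_offset,
    rayleigh,
    session_plv,
    watson_williams,
)
from thetaburst.session import WindowSpec
from thetaburst.spectral import THETA, analytic, event_bandpass
from thetaburst.synth import SessionParams, generate_lfp_session

FS = 1017.0


def _ev(start, end, region="MS"):
    return BurstEvent(region=region, band=THETA, start_s=start, end_s=end)


class TestPairing:
    def test_simple_pair_and_exclusion(self):
        ms = [_ev(9.5, 10.0)]
        ca1_near = [_ev(10.3, 10.7, "CA1")]
        ca1_far = [_ev(11.5, 11.9, "CA1")]
        pairs = pair_bursts(ms, ca1_near, max_delay_s=1.0)
        assert len(pairs) == 1 and pairs[0].delay_s == pytest.approx(0.3)
        assert pair_bursts(ms, ca1_far, max_delay_s=1.0) == []

    def test_each_ca1_used_once(self):
        ms = [_ev(0.0, 0.5), _ev(1.0, 1.5)]
        ca1 = [_ev(0.7, 0.9, "CA1")]
        pairs = pair_bursts(ms, ca1, max_delay_s=1.0)
        assert len(pairs) == 1 and pairs[0].ms_event.start_s == 0.0

    def test_delay_recovery_on_coupled_only_session(self):
        params = SessionParams(
            duration_s=900.0,
            regions=("MS", "CA1"),
            burst_rate_per_min={"MS": 8.0, "CA1": 0.0},
            coupling_probability=1.0,
            ms_to_ca1_delay_mean_s=0.2,
            ms_to_ca1_delay_sd_s=0.1,
            seed=31,
        )
        rec, truth = generate_lfp_session(params)
        ms = filter_min_duration(detect_bursts(rec.signals["MS"], FS, THETA, region="MS"), min_duration_s=0.2)
        ca1 = filter_min_duration(detect_bursts(rec.signals["CA1"], FS, THETA, region="CA1"), min_duration_s=0.2)
        pairs = pair_bursts(ms, ca1, max_delay_s=1.0)
        delays = np.array([p.delay_s for p in pairs])
        se = delays.std(ddof=1) / np.sqrt(len(delays))
        assert len(pairs) > 50
        assert abs(delays.mean() - 0.2) < 3 * se + 0.02  # 3 SE plus boundary-estimation slack


class TestCoupledClassification:
    def test_window_examples(self):
        ms = [_ev(9.5, 10.0)]
        ca1 = [_ev(10.3, 10.7, "CA1")]
        assert classify_coupled(ca1, ms, window_s=0.4).tolist() == [True]
        assert classify_coupled(ca1, ms, window_s=0.2).tolist() == [False]

    def test_no_ms_bursts_all_uncoupled(self):
        ca1 = [_ev(1.0, 1.4, "CA1"), _ev(5.0, 5.3, "CA1")]
        assert classify_coupled(ca1, [], window_s=1.0).tolist() == [False, False]

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            classify_coupled([], [], window_s=0.0)

    def test_widening_window_monotone_over_random_sessions(self, rng):
        for _ in range(20):
            ms = sorted(rng.uniform(0, 600, 40))
            ca1 = sorted(rng.uniform(0, 600, 40))
            ms_ev = [_ev(s, s + 0.3) for s in ms]
            ca1_ev = [_ev(s, s + 0.3, "CA1") for s in ca1]
            counts = [int(np.sum(classify_coupled(ca1_ev, ms_ev, w))) for w in (0.2, 0.4, 1.0)]
            assert counts[0] <= counts[1] <= counts[2]


class TestLatencySplit:
    def test_construction_short_r_exceeds_long_r(self, rng):
        pairs = []
        for _ in range(200):
            d_ms = rng.uniform(0.2, 0.6)
            delay = rng.uniform(0.0, 1.0)
            # durations correlate only for short delays
            d_ca1 = d_ms + rng.normal(0, 0.02) if delay < 0.5 else rng.uniform(0.2, 0.6)
            ms = _ev(0.0, d_ms)
            ca1 = _ev(d_ms + delay, d_ms + delay + d_ca1, "CA1")
            pairs.append(type("P", (), {})())
            pairs[-1].ms_event, pairs[-1].ca1_event, pairs[-1].delay_s, pairs[-1].latency_class = ms, ca1, delay, None
        out = latency_split_correlation(pairs)
        assert out["short"][0] > out["long"][0]

    def test_identical_durations_r_one(self):
        pairs = []
        for i in range(20):
            d = 0.2 + 0.02 * i
            ms = _ev(i * 10.0, i * 10.0 + d)
            ca1 = _ev(i * 10.0 + d + 0.1 + 0.01 * i, i * 10.0 + d + 0.1 + 0.01 * i + d, "CA1")
            p = type("P", (), {})()
            p.ms_event, p.ca1_event, p.delay_s, p.latency_class = ms, ca1, 0.1 + 0.01 * i, None
            pairs.append(p)
        out = latency_split_correlation(pairs)
        assert out["short"][0] == pytest.approx(1.0)

    def test_fisher_z_zero_for_equal_correlations(self):
        z, p = fisher_z(0.5, 100, 0.5, 100)
        assert z == 0.0 and p == pytest.approx(1.0)


class TestPLV:
    def test_constant_offset_gives_one(self, rng):
        pa = rng.uniform(-np.pi, np.pi, int(60 * FS))
        res = session_plv(pa, pa - 0.7, FS)
        assert np.all(res.window_values > 1 - 1e-12)
        assert res.session_plv == pytest.approx(1.0, abs=1e-12)

    def test_common_rotation_invariance(self, rng):
        pa = rng.uniform(-np.pi, np.pi, 5000)
        pb = rng.uniform(-np.pi, np.pi, 5000)
        assert plv(pa, pb) == pytest.approx(plv(pa + 1.3, pb + 1.3), abs=1e-12)

    def test_symmetry(self, rng):
        pa = rng.uniform(-np.pi, np.pi, 5000)
        pb = rng.uniform(-np.pi, np.pi, 5000)
        assert plv(pa, pb) == pytest.approx(plv(pb, pa), abs=1e-12)

    def test_von_mises_closed_form(self, rng):
        kappa = 4.0
        n = int(120 * FS)
        pa = rng.uniform(-np.pi, np.pi, n)
        pb = pa - rng.vonmises(0.5, kappa, n)
        assert plv(pa, pb) == pytest.approx(i1(kappa) / i0(kappa), abs=0.05)

    def test_independent_phases_low(self, rng):
        pa = rng.uniform(-np.pi, np.pi, int(64 * FS))
        pb = rng.uniform(-np.pi, np.pi, int(64 * FS))
        res = session_plv(pa, pb, FS, window_s=8.0)
        assert np.all(res.window_values < 0.2)


class TestPeriBurstPLV:
    def test_post_exceeds_pre_with_coupled_tails(self, coupled_session):
        _, rec, _ = coupled_session
        ms = filter_min_duration(detect_bursts(rec.signals["MS"], FS, THETA, region="MS"), min_duration_s=0.2)
        ca1 = filter_min_duration(detect_bursts(rec.signals["CA1"], FS, THETA, region="CA1"), min_duration_s=0.2)
        pairs = pair_bursts(ms, ca1, max_delay_s=1.0)
        _, pm = analytic(event_bandpass(rec.signals["MS"], FS, THETA))
        _, pc = analytic(event_bandpass(rec.signals["CA1"], FS, THETA))
        peri = periburst_plv(pairs, pm, pc, FS)
        assert len(peri) >= 20
        assert np.mean([d["post"] for d in peri]) > np.mean([d["pre"] for d in peri])

    def test_null_ratio_centred_at_one(self, rng):
        # constructed pairs over independent phases: log-ratio mean near 0
        n = int(600 * FS)
        pm = rng.uniform(-np.pi, np.pi, n)
        pc = rng.uniform(-np.pi, np.pi, n)
        pairs = []
        for s in np.arange(5.0, 590.0, 5.0):
            p = type("P", (), {})()
            p.ms_event, p.ca1_event, p.delay_s = _ev(s, s + 0.3), _ev(s + 0.5, s + 0.8, "CA1"), 0.2
            pairs.append(p)
        peri = periburst_plv(pairs, pm, pc, FS)
        ratios = np.array([d["ratio"] for d in peri])
        assert len(ratios) >= 100
        assert abs(np.mean(np.log(ratios))) < 0.1

    def test_pair_near_edge_excluded(self, rng):
        pm = rng.uniform(-np.pi, np.pi, int(10 * FS))
        pc = rng.uniform(-np.pi, np.pi, int(10 * FS))
        p = type("P", (), {})()
        p.ms_event, p.ca1_event, p.delay_s = _ev(0.5, 0.8), _ev(1.0, 1.3, "CA1"), 0.2
        assert periburst_plv([p], pm, pc, FS, pre_s=2.0) == []


class TestPostburstOffset:
    def _pairs(self, starts):
        out = []
        for s in starts:
            p = type("P", (), {})()
            p.ms_event, p.ca1_event, p.delay_s = _ev(s - 0.5, s - 0.1), _ev(s, s + 0.3, "CA1"), 0.1
            out.append(p)
        return out

    def test_constant_offset_recovered_exactly(self):
        n = int(120 * FS)
        base = np.linspace(0, 2 * np.pi * 8 * 120, n) % (2 * np.pi) - np.pi
        pairs = self._pairs(np.arange(5.0, 115.0, 5.0))
        offs = postburst_phase_offset(pairs, base, base - np.pi / 4, FS)
        np.testing.assert_allclose(offs, np.pi / 4, atol=1e-9)

    def test_von_mises_offsets_mean_recovered(self, rng):
        n = int(300 * FS)
        base = rng.uniform(-np.pi, np.pi, n)
        phase_ca1 = base.copy()
        starts = np.arange(5.0, 295.0, 5.0)
        pairs = self._pairs(starts)
        for s in starts:
            i0_, i1_ = int(s * FS), int((s + 1.25) * FS)
            phase_ca1[i0_:i1_] = base[i0_:i1_] - rng.vonmises(0.5, 8.0)
        offs = postburst_phase_offset(pairs, base, phase_ca1, FS)
        assert abs(circular_mean(offs) - 0.5) < 0.1

    def test_uniform_phases_give_uniform_offsets(self, rng):
        n = int(300 * FS)
        pm = rng.uniform(-np.pi, np.pi, n)
        pc = rng.uniform(-np.pi, np.pi, n)
        offs = postburst_phase_offset(self._pairs(np.arange(5.0, 295.0, 5.0)), pm, pc, FS)
        assert rayleigh(offs).p > 0.01


class TestCircularStats:
    def test_identical_angles_maximal_concentration(self):
        res = rayleigh(np.ones(100))
        assert res.resultant_length == pytest.approx(1.0)
        assert res.p < 1e-12
        assert res.mean_direction == pytest.approx(1.0)

    def test_rayleigh_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        angles = rng.vonmises(0.3, 2.0, 75)
        z_ref, p_ref = pg.circ_rayleigh(angles)
        res = rayleigh(angles)
        assert res.statistic == pytest.approx(z_ref, rel=1e-9)
        assert res.p == pytest.approx(p_ref, rel=1e-6)

    def test_rayleigh_type_i_error_calibrated(self, rng):
        n_sim, n = 500, 200
        rej = sum(rayleigh(rng.uniform(-np.pi, np.pi, n)).p < 0.05 for _ in range(n_sim))
        assert 0.02 <= rej / n_sim <= 0.08

    def test_group_tests_detect_mean_shift(self, rng):
        g = [rng.vonmises(0.0, 4.0, 200), rng.vonmises(1.0, 4.0, 200)]
        assert watson_williams(g).p < 0.001
        assert mww(g).p < 0.001

    def test_group_tests_null_behaviour(self, rng):
        g = [rng.vonmises(0.5, 4.0, 100), rng.vonmises(0.5, 4.0, 100)]
        assert watson_williams(g).p > 0.001
        u = [rng.uniform(-np.pi, np.pi, 100), rng.uniform(-np.pi, np.pi, 100)]
        assert mww(u).p > 0.001

    def test_degenerate_identical_angles_flagged(self):
        res = watson_williams([np.ones(10), np.ones(10)])
        assert "degenerate_identical_angles" in res.flags

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            rayleigh(np.ones(3))
        with pytest.raises(ValueError):
            mww([np.ones(3), np.ones(10)])


class TestEnvelopeLag:
    def test_known_delay_recovered_within_one_sample(self, rng):
        n = int(120 * FS)
        base = np.abs(np.convolve(rng.standard_normal(n), np.hanning(200), "same"))
        d = int(round(0.05 * FS))
        ca1 = np.roll(base, d)  # MS leads by 50 ms
        res = envelope_lag(base, ca1, FS)
        assert res.median_lag_s == pytest.approx(0.05, abs=1.5 / FS)

    def test_identical_envelopes_zero_lag_zero_sd(self, rng):
        env = np.abs(rng.standard_normal(int(60 * FS)))
        res = envelope_lag(env, env, FS)
        assert res.median_lag_s == 0.0
        assert res.lag_sd_s == 0.0

    def test_independent_envelopes_near_uniform_lags(self, rng):
        n = int(400 * FS)
        a = np.abs(np.convolve(rng.standard_normal(n), np.hanning(150), "same"))
        b = np.abs(np.convolve(rng.standard_normal(n), np.hanning(150), "same"))
        res = envelope_lag(a, b, FS, max_lag_s=0.5)
        assert res.lag_sd_s == pytest.approx(0.5 / np.sqrt(3), rel=0.35)

    def test_antisymmetric_under_swap(self, rng):
        n = int(60 * FS)
        a = np.abs(np.convolve(rng.standard_normal(n), np.hanning(150), "same"))
        b = np.roll(a, int(0.03 * FS))
        r1 = envelope_lag(a, b, FS)
        r2 = envelope_lag(b, a, FS)
        np.testing.assert_allclose(r1.window_lags, -r2.window_lags)

    def test_constant_window_skipped(self):
        env = np.ones(int(30 * FS))
        res = envelope_lag(env, env, FS)
        assert len(res.window_lags) == 0
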