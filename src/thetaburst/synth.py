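"""Ground-truthed synthetic multi-region LFP sessions and yoked tracking.

Each region's trace is 1/f background noise plus Hanning-enveloped sinusoidal
bursts with frequencies drawn from the theta range.  MS bursts spawn CA1
bursts with a configurable probability at a delay drawn from a truncated
normal, and the spawned CA1 sinusoid is phase-shifted from its parent by a
von Mises angle, so interregional delay, coupling, and phase-offset analyses
all have recoverable ground truth.  An optional low-amplitude shared theta
"tail" follows each coupled event, emulating post-burst interregional
synchrony while staying below the burst detector's high threshold.

Burst amplitude is parameterised as an SNR: peak amplitude = SNR x the
broadband background-noise RMS.  Theta bursts visibly dominate the raw CA1
trace, so SNR of a few is the physiologically plausible regime; because the
1/f background carries only a small fraction of its power inside the theta
band, an SNR-4 burst stands far above the theta-band noise envelope.

The ``etoh`` condition applies multiplicative effects (defaults: burst rate
x1.5 in all regions, CA1 burst duration x0.7, locomotor speed x0.7, MS->CA1
delay SD x0.6), mirroring the direction of the pharmacological effects the
pipeline is designed to measure.

Tracking is a smooth trajectory of six body landmarks (20 frames/s)
alternating rest epochs and motion bouts; a configurable fraction of bout
onsets is placed 0-2 s after a true CA1 burst so burst-movement alignment
has ground truth too.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .behavior import MotionBout
from .bursts import BurstEvent
from .session import LANDMARKS, SessionRecording, TrackingData
from .spectral import THETA, analytic, bandpass

__all__ = [
    "SessionParams",
    "GroundTruth",
    "DEFAULT_ETOH_EFFECTS",
    "generate_lfp_session",
    "generate_tracking",
    "generate_cohort",
    "powerlaw_noise",
]

DEFAULT_ETOH_EFFECTS: dict[str, float] = {
    "burst_rate": 1.5,
    "ca1_burst_duration": 0.7,
    "velocity": 0.7,
    "delay_sd": 0.6,
}


@dataclass
class SessionParams:
    """Parameters of one synthetic foraging session (defaults: 20 min at 1017 Hz)."""

    duration_s: float = 1200.0
    fs: float = 1017.0
    regions: tuple[str, ...] = ("MS", "CA1", "mPFC")
    noise_exponent: float = 2.0
    burst_rate_per_min: dict[str, float] = field(default_factory=lambda: {"MS": 6.0, "CA1": 3.0, "mPFC": 3.0})
    burst_duration_mean_s: dict[str, float] = field(default_factory=lambda: {"MS": 0.45, "CA1": 0.40, "mPFC": 0.45})
    burst_duration_sd_s: dict[str, float] = field(default_factory=lambda: {"MS": 0.10, "CA1": 0.06, "mPFC": 0.10})
    burst_freq_range: tuple[float, float] = (5.0, 12.0)
    burst_snr: float = 4.0
    ms_to_ca1_delay_mean_s: float = 0.20
    ms_to_ca1_delay_sd_s: float = 0.10
    coupling_probability: float = 0.7
    phase_offset_mean_rad: float = 0.5
    phase_offset_kappa: float = 4.0
    coupled_tail_s: float = 1.5
    coupled_tail_gain: float = 2.0  # x median theta-band noise envelope; below detection thresholds
    # tracking
    frame_rate: float = 20.0
    arena_cm: tuple[float, float] = (20.0, 33.0)
    motion_fraction: float = 0.4
    bout_after_burst_frac: float = 0.6
    velocity_scale: float = 1.0
    # condition
    condition: str = "saline"
    effect_multipliers: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ETOH_EFFECTS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs <= 2 * self.burst_freq_range[1]:
            raise ValueError("fs must exceed twice the highest burst frequency")
        if not (0 <= self.coupling_probability <= 1):
            raise ValueError("coupling_probability must lie in [0, 1]")
        if self.ms_to_ca1_delay_sd_s < 0:
            raise ValueError("delay SD must be non-negative")
        if self.phase_offset_kappa < 0:
            raise ValueError("phase offset kappa must be non-negative")
        if any(v <= 0 for v in self.burst_duration_mean_s.values()):
            raise ValueError("burst duration means must be positive")
        if not (0 <= self.bout_after_burst_frac <= 1):
            raise ValueError("bout_after_burst_frac must lie in [0, 1]")
        if not (0 <= self.motion_fraction < 1):
            raise ValueError("motion_fraction must lie in [0, 1)")

    def effective(self) -> "SessionParams":
        """Resolve condition effect multipliers into concrete parameter values."""
        if self.condition != "etoh":
            return self
        m = self.effect_multipliers
        rates = {r: v * m.get("burst_rate", 1.0) for r, v in self.burst_rate_per_min.items()}
        dur_mean = dict(self.burst_duration_mean_s)
        dur_sd = dict(self.burst_duration_sd_s)
        ca1_mult = m.get("ca1_burst_duration", 1.0)
        dur_mean["CA1"] = dur_mean.get("CA1", 0.4) * ca1_mult
        dur_sd["CA1"] = dur_sd.get("CA1", 0.06) * ca1_mult
        return replace(
            self,
            burst_rate_per_min=rates,
            burst_duration_mean_s=dur_mean,
            burst_duration_sd_s=dur_sd,
            ms_to_ca1_delay_sd_s=self.ms_to_ca1_delay_sd_s * m.get("delay_sd", 1.0),
            velocity_scale=self.velocity_scale * m.get("velocity", 1.0),
            condition="etoh_resolved",
        )


@dataclass
class GroundTruth:
    """Exact injected events, pairings, and behavioural bouts of one session."""

    true_bursts: dict[str, list[BurstEvent]]
    true_pairs: list[tuple[int, int, float]]  # (MS index, CA1 index, delay s)
    true_bouts: list[MotionBout] = field(default_factory=list)
    condition: str = "saline"


def powerlaw_noise(n: int, exponent: float, rng: np.random.Generator, fs: float = 1.0) -> np.ndarray:
    """Gaussian noise with power spectrum proportional to 1/f**exponent, unit SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    return x / x.std()


@dataclass
class _Injected:
    start_s: float
    end_s: float
    freq: float
    phase: float  # phase of cos at start_s
    amp: float
    parent: int | None = None  # index into MS injected list for coupled CA1 events


def _draw_events(
    rng: np.random.Generator,
    rate_per_min: float,
    duration_s: float,
    dur_mean: float,
    dur_sd: float,
    freq_range: tuple[float, float],
) -> list[_Injected]:
    events = []
    if rate_per_min <= 0:
        return events
    rate = rate_per_min / 60.0
    t = rng.exponential(1.0 / rate)
    while t < duration_s:
        dur = max(rng.normal(dur_mean, dur_sd), 0.12)
        f = rng.uniform(*freq_range)
        events.append(_Injected(start_s=t, end_s=min(t + dur, duration_s), freq=f, phase=rng.uniform(-np.pi, np.pi), amp=1.0))
        t += dur + rng.exponential(1.0 / rate)
    return events


def _merge_overlaps(events: list[_Injected]) -> tuple[list[_Injected], np.ndarray]:
    """Merge overlapping injected events (detectors cannot separate them).

    Returns merged events and a map from original index to merged index.
    """
    order = np.argsort([e.start_s for e in events])
    merged: list[_Injected] = []
    idx_map = np.full(len(events), -1, dtype=int)
    for oi in order:
        ev = events[oi]
        if merged and ev.start_s < merged[-1].end_s:
            merged[-1].end_s = max(merged[-1].end_s, ev.end_s)
            idx_map[oi] = len(merged) - 1
        else:
            merged.append(_Injected(**vars(ev)))
            idx_map[oi] = len(merged) - 1
    return merged, idx_map


def _render(sig: np.ndarray, fs: float, ev: _Injected) -> None:
    i0, i1 = int(round(ev.start_s * fs)), int(round(ev.end_s * fs))
    i1 = min(i1, len(sig))
    if i1 - i0 < 2:
        return
    t = np.arange(i0, i1) / fs
    env = np.hanning(i1 - i0)
    sig[i0:i1] += ev.amp * env * np.cos(2 * np.pi * ev.freq * (t - ev.start_s) + ev.phase)


def _render_tail(sig: np.ndarray, fs: float, start_s: float, tail_s: float, freq: float, phase_at_start: float, amp: float) -> None:
    i0 = int(round(start_s * fs))
    i1 = min(i0 + int(round(tail_s * fs)), len(sig))
    if i1 - i0 < 2:
        return
    t = np.arange(i0, i1) / fs
    n = i1 - i0
    env = 0.5 * (1 + np.cos(np.pi * np.arange(n) / n))  # smooth decay 1 -> 0
    sig[i0:i1] += amp * env * np.cos(2 * np.pi * freq * (t - start_s) + phase_at_start)


def generate_lfp_session(params: SessionParams) -> tuple[SessionRecording, GroundTruth]:
    """Synthesize one session's LFP traces and exact ground truth.

    Deterministic given ``params.seed``: running twice with the same
    parameters yields bit-identical signals and events.
    """
    p = params.effective()
    rng = np.random.default_rng(params.seed)
    n = int(round(p.duration_s * p.fs))

    signals: dict[str, np.ndarray] = {}
    amp_scale: dict[str, float] = {}
    theta_env_med: dict[str, float] = {}
    for region in p.regions:
        noise = powerlaw_noise(n, p.noise_exponent, rng, fs=p.fs)  # unit SD
        amp_scale[region] = p.burst_snr
        env, _ = analytic(bandpass(noise, p.fs, THETA))
        theta_env_med[region] = float(np.median(env))
        signals[region] = noise

    injected: dict[str, list[_Injected]] = {r: [] for r in p.regions}
    for region in p.regions:
        evs = _draw_events(
            rng,
            p.burst_rate_per_min.get(region, 0.0),
            p.duration_s,
            p.burst_duration_mean_s.get(region, 0.4),
            p.burst_duration_sd_s.get(region, 0.08),
            p.burst_freq_range,
        )
        for ev in evs:
            ev.amp = amp_scale[region] * float(np.exp(rng.normal(0.0, 0.1)))
        injected[region].extend(evs)

    # MS bursts spawn CA1 bursts at a truncated-normal delay with a von Mises phase shift
    raw_pairs: list[tuple[int, int, float]] = []
    if "MS" in injected and "CA1" in p.regions:
        ca1_mean = p.burst_duration_mean_s.get("CA1", 0.4)
        ca1_sd = p.burst_duration_sd_s.get("CA1", 0.06)
        for mi, ms_ev in enumerate(injected["MS"]):
            if rng.uniform() >= p.coupling_probability:
                continue
            delay = rng.normal(p.ms_to_ca1_delay_mean_s, p.ms_to_ca1_delay_sd_s) if p.ms_to_ca1_delay_sd_s > 0 else p.ms_to_ca1_delay_mean_s
            delay = max(delay, 0.0)
            onset = ms_ev.end_s + delay
            if onset >= p.duration_s - 0.05:
                continue
            dur = max(rng.normal(ca1_mean, ca1_sd), 0.12)
            dphi = rng.vonmises(p.phase_offset_mean_rad, p.phase_offset_kappa) if p.phase_offset_kappa > 0 else p.phase_offset_mean_rad
            # choose CA1 phase so that phi_MS - phi_CA1 = dphi at the CA1 onset
            ms_phase_at_onset = 2 * np.pi * ms_ev.freq * (onset - ms_ev.start_s) + ms_ev.phase
            ca1_ev = _Injected(
                start_s=onset,
                end_s=min(onset + dur, p.duration_s),
                freq=ms_ev.freq,
                phase=float(np.mod(ms_phase_at_onset - dphi + np.pi, 2 * np.pi) - np.pi),
                amp=amp_scale.get("CA1", 1.0) * float(np.exp(rng.normal(0.0, 0.1))),
                parent=mi,
            )
            injected["CA1"].append(ca1_ev)
            raw_pairs.append((mi, len(injected["CA1"]) - 1, delay))

            if p.coupled_tail_s > 0 and p.coupled_tail_gain > 0:
                # tail amplitude in units of the theta-band noise envelope median:
                # strong enough to dominate theta phase, weak enough to stay
                # below the burst detector's thresholds
                tail_amp_ca1 = p.coupled_tail_gain * theta_env_med.get("CA1", 0.1)
                tail_amp_ms = p.coupled_tail_gain * theta_env_med.get("MS", 0.1)
                ca1_phase_at_end = 2 * np.pi * ca1_ev.freq * (ca1_ev.end_s - ca1_ev.start_s) + ca1_ev.phase
                _render_tail(signals["CA1"], p.fs, ca1_ev.end_s, p.coupled_tail_s, ca1_ev.freq, ca1_phase_at_end, tail_amp_ca1)
                _render_tail(signals["MS"], p.fs, ca1_ev.end_s, p.coupled_tail_s, ca1_ev.freq, ca1_phase_at_end + dphi, tail_amp_ms)

    for region in p.regions:
        for ev in injected[region]:
            _render(signals[region], p.fs, ev)

    # ground truth: overlapping events merged per region
    true_bursts: dict[str, list[BurstEvent]] = {}
    maps: dict[str, np.ndarray] = {}
    for region in p.regions:
        merged, idx_map = _merge_overlaps(injected[region])
        maps[region] = idx_map
        true_bursts[region] = [
            BurstEvent(region=region, band=THETA, start_s=ev.start_s, end_s=ev.end_s, peak_amplitude=ev.amp)
            for ev in merged
        ]
    true_pairs = []
    if raw_pairs:
        for mi, ci, delay in raw_pairs:
            true_pairs.append((int(maps["MS"][mi]), int(maps["CA1"][ci]), float(delay)))

    rec = SessionRecording(signals=signals, fs=p.fs, subject_id=f"subj{params.seed}", condition=params.condition)
    truth = GroundTruth(true_bursts=true_bursts, true_pairs=true_pairs, condition=params.condition)
    return rec, truth


# ---------------------------------------------------------------------------
# tracking


def generate_tracking(params: SessionParams, truth: GroundTruth) -> tuple[TrackingData, GroundTruth]:
    """Synthesize yoked six-landmark tracking at 20 frames/s.

    Alternates rest epochs (speed under the 0.25 cm/s rest threshold) and
    motion bouts (trapezoidal speed profile peaking at 3-8 cm/s, scaled by
    the condition's velocity multiplier); a fraction
    ``params.bout_after_burst_frac`` of bout onsets is placed 0-2 s after a
    true CA1 burst onset.  Appends the ground-truth bout list to ``truth``.
    """
    p = params.effective()
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed) % (2**31), 17]))
    fr = p.frame_rate
    n_frames = int(round(p.duration_s * fr))
    dt = 1.0 / fr

    speed = np.abs(rng.normal(0.0, 0.05, size=n_frames))  # rest-level jitter
    bouts: list[MotionBout] = []
    ca1_onsets = np.array(sorted(e.start_s for e in truth.true_bursts.get("CA1", [])))

    if p.motion_fraction > 0:
        bout_mean = 3.0
        rest_mean = max(bout_mean * (1 - p.motion_fraction) / p.motion_fraction, 3.0)
        t = max(rng.uniform(2.5, 6.0), 2.5)
        while t < p.duration_s - 6.0:
            yoked = False
            if rng.uniform() < p.bout_after_burst_frac and len(ca1_onsets):
                nxt = ca1_onsets[np.searchsorted(ca1_onsets, t)] if np.searchsorted(ca1_onsets, t) < len(ca1_onsets) else None
                if nxt is not None and nxt < p.duration_s - 8.0:
                    t = float(nxt + rng.uniform(0.1, 1.9))
                    yoked = True
            dur = float(np.clip(rng.normal(bout_mean, 1.0), 1.6, 6.0))
            peak = rng.uniform(3.0, 8.0) * p.velocity_scale
            i0, i1 = int(round(t * fr)), min(int(round((t + dur) * fr)), n_frames)
            if i1 - i0 > 4:
                prof = np.full(i1 - i0, peak)
                ramp = min(int(0.3 * fr), (i1 - i0) // 3)
                if ramp > 0:
                    up = np.linspace(0, 1, ramp + 1)[1:]
                    prof[:ramp] = peak * up
                    prof[-ramp:] = peak * up[::-1]
                speed[i0:i1] = prof
                bouts.append(
                    MotionBout(
                        kind="motion", start_s=t, end_s=t + dur,
                        mean_velocity=float(prof.mean()),
                        preceded_by_burst=yoked or bool(len(ca1_onsets) and np.any((t - ca1_onsets > 0) & (t - ca1_onsets <= 2.0))),
                    )
                )
            t = t + dur + max(rng.exponential(rest_mean), 2.6)

    # heading: persistent random walk during movement, frozen at rest
    heading = np.empty(n_frames)
    heading[0] = rng.uniform(-np.pi, np.pi)
    steps = rng.normal(0.0, 0.12, size=n_frames)
    moving = speed > 0.5
    w, h = p.arena_cm
    pos = np.empty((n_frames, 2))
    pos[0] = (w / 2, h / 2)
    for i in range(1, n_frames):
        heading[i] = heading[i - 1] + (steps[i] if moving[i] else 0.0)
        step = speed[i] * dt
        cand = pos[i - 1] + step * np.array([np.cos(heading[i]), np.sin(heading[i])])
        # steer back toward the arena centre at the walls
        if not (1.0 < cand[0] < w - 1.0 and 1.0 < cand[1] < h - 1.0):
            to_center = np.arctan2(h / 2 - pos[i - 1, 1], w / 2 - pos[i - 1, 0])
            heading[i] = to_center + rng.normal(0.0, 0.3)
            cand = pos[i - 1] + step * np.array([np.cos(heading[i]), np.sin(heading[i])])
        pos[i] = cand

    u = np.column_stack([np.cos(heading), np.sin(heading)])
    perp = np.column_stack([-np.sin(heading), np.cos(heading)])
    offsets = {"nose": 2.0, "head": 1.2, "back": -0.5, "tail_base": -1.5}
    side = {"left_ear": 0.5, "right_ear": -0.5}
    landmarks = {}
    for name in LANDMARKS:
        base = pos + offsets.get(name, 0.8) * u if name not in side else pos + 0.8 * u + side[name] * perp
        landmarks[name] = base + rng.normal(0.0, 0.03, size=base.shape)

    trk = TrackingData(time_s=np.arange(n_frames) / fr, landmarks=landmarks, frame_rate=fr)
    truth.true_bouts = bouts
    return trk, truth


# ---------------------------------------------------------------------------
# cohorts


def generate_cohort(
    n_subjects: int,
    params_by_condition: dict[str, SessionParams],
    seed: int = 0,
    with_tracking: bool = True,
) -> list[tuple[SessionRecording, TrackingData | None, GroundTruth]]:
    """One session per subject per condition, with subject-specific offsets.

    Each subject carries small random baselines shared across its conditions
    (a delay/lag offset up to ±50 ms, a duration scale, a velocity scale),
    mirroring stable inter-animal differences; condition effects then apply
    on top.  Deterministic under ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not params_by_condition:
        raise ValueError("params_by_condition must not be empty")
    sessions = []
    for i in range(n_subjects):
        subj_rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), i]))
        delay_offset = subj_rng.uniform(-0.05, 0.05)
        dur_scale = float(np.exp(subj_rng.normal(0.0, 0.05)))
        vel_scale = subj_rng.uniform(0.9, 1.1)
        for j, (cond, base) in enumerate(params_by_condition.items()):
            params = replace(
                base,
                condition=cond,
                seed=int((seed * 1009 + i * 31 + j * 7 + 1) % (2**31)),
                ms_to_ca1_delay_mean_s=max(base.ms_to_ca1_delay_mean_s + delay_offset, 0.02),
                burst_duration_mean_s={k: v * dur_scale for k, v in base.burst_duration_mean_s.items()},
                velocity_scale=base.velocity_scale * vel_scale,
            )
            rec, truth = generate_lfp_session(params)
            rec.subject_id = f"subj{i}"
            trk = None
            if with_tracking:
                trk, truth = generate_tracking(params, truth)
            sessions.append((rec, trk, truth))
    return sessions
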