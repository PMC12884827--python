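"""Kinematics, behavioural epoching, burst-movement alignment, and
egocentric trajectory curvature.

Velocity is taken from the smoothed centre point (midpoint of the back and
tail-base landmarks when both are tracked, else the nose).  A motion bout
starts at an upward crossing of 1.5 cm/s sustained for at least 1 s and ends
when velocity falls below 0.5 cm/s for at least 1 s; rest is velocity below
0.25 cm/s for more than 2 s; a movement initiation is a motion-bout onset
preceded by at least 2 s with velocity under 0.5 cm/s.  Heading is the
arctangent of the velocity components and is undefined (NaN) below the rest
threshold, where the angle is noise-dominated.

Trajectory geometry is summarised in egocentric coordinates: the bout-onset
tail-base-to-nose vector defines the forward (+y) axis, the path is resampled
by arc length to 100 points, and curvature is the change in heading per unit
distance.  The integral of |curvature| over arc length (the curvature AUC, in
radians) is the total turning of the path, an index of tortuosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as spstats
from scipy.ndimage import gaussian_filter1d
from statsmodels.stats.multitest import multipletests

from .bursts import BurstEvent
from .coupling import CircularStatResult, mww, rayleigh
from .session import TrackingData

__all__ = [
    "Kinematics",
    "MotionBout",
    "CurvatureProfile",
    "kinematics",
    "detect_bouts",
    "movement_initiations",
    "burst_movement_alignment",
    "periburst_velocity",
    "heading_distribution",
    "egocentric_curvature",
    "curvature_permutation_test",
]

MOTION_ENTER_CM_S = 1.5
MOTION_EXIT_CM_S = 0.5
REST_CM_S = 0.25
HEADING_FLOOR_CM_S = 0.25


@dataclass
class Kinematics:
    time_s: np.ndarray
    position: np.ndarray  # (n, 2) centre point, cm
    velocity_cm_s: np.ndarray
    acceleration_cm_s2: np.ndarray
    heading_rad: np.ndarray  # NaN where speed < HEADING_FLOOR_CM_S
    frame_rate: float


@dataclass
class MotionBout:
    kind: str  # motion | rest | initiation
    start_s: float
    end_s: float
    mean_velocity: float = np.nan
    preceded_by_burst: bool | None = None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class CurvatureProfile:
    arc_positions: np.ndarray  # 100 points, normalised 0..1
    curvature: np.ndarray  # rad/cm at each point
    auc: float  # integral of |curvature| over arc length, rad
    path_length_cm: float


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    pad = np.pad(x, (w // 2, w - 1 - w // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def kinematics(tracking: TrackingData, smooth_window_frames: int = 5) -> Kinematics:
    """Centre-point position, velocity, acceleration, and heading."""
    if tracking.n_frames < 2:
        raise ValueError("kinematics requires at least 2 frames")
    lm = tracking.landmarks
    if "back" in lm and "tail_base" in lm:
        center = 0.5 * (lm["back"] + lm["tail_base"])
    elif "nose" in lm:
        center = lm["nose"]
    else:
        center = next(iter(lm.values()))
    pos = np.column_stack([_smooth(center[:, 0], smooth_window_frames), _smooth(center[:, 1], smooth_window_frames)])
    t = tracking.time_s
    vx = np.gradient(pos[:, 0], t)
    vy = np.gradient(pos[:, 1], t)
    speed = np.hypot(vx, vy)
    accel = np.gradient(speed, t)
    heading = np.arctan2(vy, vx)
    heading[speed < HEADING_FLOOR_CM_S] = np.nan
    return Kinematics(
        time_s=t,
        position=pos,
        velocity_cm_s=speed,
        acceleration_cm_s2=accel,
        heading_rad=heading,
        frame_rate=tracking.frame_rate,
    )


def _sustained(mask: np.ndarray, min_frames: int) -> np.ndarray:
    """Start indices of runs of True lasting at least min_frames."""
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    keep = (ends - starts) >= min_frames
    return np.column_stack([starts[keep], ends[keep]]) if keep.any() else np.empty((0, 2), dtype=int)


def detect_bouts(kin: Kinematics, rest_thresh_cm_s: float = REST_CM_S) -> list[MotionBout]:
    """Segment motion bouts and rest periods from the velocity trace.

    Hysteresis rule: a bout begins at an upward crossing of 1.5 cm/s that is
    sustained at least 1 s, and ends at the start of the first subsequent
    interval at least 1 s long with velocity below 0.5 cm/s.  Rest periods
    are maximal intervals below ``rest_thresh_cm_s`` lasting over 2 s.
    """
    v = kin.velocity_cm_s
    fr = kin.frame_rate
    one_s = max(int(round(fr)), 1)
    t = kin.time_s

    bouts: list[MotionBout] = []
    high_runs = _sustained(v > MOTION_ENTER_CM_S, one_s)
    low_runs = _sustained(v < MOTION_EXIT_CM_S, one_s)
    cursor = 0
    for hs, _he in high_runs:
        if hs < cursor:
            continue  # still inside the previous bout
        after = low_runs[low_runs[:, 0] > hs]
        end = int(after[0, 0]) if len(after) else len(v) - 1
        bouts.append(
            MotionBout(
                kind="motion",
                start_s=float(t[hs]),
                end_s=float(t[min(end, len(t) - 1)]),
                mean_velocity=float(v[hs:end].mean()) if end > hs else float(v[hs]),
            )
        )
        cursor = end

    rest_runs = _sustained(v < rest_thresh_cm_s, int(round(2 * fr)) + 1)
    rests = [
        MotionBout(kind="rest", start_s=float(t[s]), end_s=float(t[min(e, len(t) - 1)]), mean_velocity=float(v[s:e].mean()))
        for s, e in rest_runs
    ]
    return sorted(bouts + rests, key=lambda b: b.start_s)


def movement_initiations(
    kin: Kinematics, bouts: list[MotionBout] | None = None, ramp_grace_s: float = 1.0
) -> list[MotionBout]:
    """Motion-bout onsets preceded by >= 2 s of velocity below 0.5 cm/s.

    The rest requirement is evaluated just before the acceleration ramp: the
    last sub-0.5 cm/s frame within ``ramp_grace_s`` of the 1.5 cm/s crossing
    anchors the 2-s look-back, so the brief rise through 0.5-1.5 cm/s at
    movement onset does not disqualify a genuine rest-to-movement transition.
    """
    if bouts is None:
        bouts = detect_bouts(kin)
    v, t, fr = kin.velocity_cm_s, kin.time_s, kin.frame_rate
    two_s = int(round(2 * fr))
    grace = int(round(ramp_grace_s * fr))
    out = []
    for b in bouts:
        if b.kind != "motion":
            continue
        i = int(np.searchsorted(t, b.start_s))
        below = np.flatnonzero(v[max(i - grace, 0) : i] < MOTION_EXIT_CM_S)
        if len(below) == 0:
            continue
        j = max(i - grace, 0) + int(below[-1]) + 1  # end of the pre-ramp rest
        if j >= two_s and np.all(v[j - two_s : j] < MOTION_EXIT_CM_S):
            out.append(MotionBout(kind="initiation", start_s=b.start_s, end_s=b.end_s, mean_velocity=b.mean_velocity))
    return out


def burst_movement_alignment(
    bursts: list[BurstEvent],
    initiations: list[MotionBout],
    window_s: float = 2.0,
    n_bins: int = 40,
    sigma_bins: float = 1.0,
) -> dict:
    """Temporal alignment of burst onsets with movement initiations.

    Returns the percentage of initiations with a burst onset within
    ±``window_s`` (the condition-comparison metric), the complementary
    percentage of bursts near any initiation, and a unit-area
    Gaussian-smoothed density of burst-minus-onset times over the window.
    """
    onsets = np.array([b.start_s for b in bursts])
    inits = np.array([b.start_s for b in initiations])
    if len(inits) == 0 or len(onsets) == 0:
        return {"pct_initiations_with_burst": 0.0, "pct_bursts_near_onset": 0.0,
                "bin_centers_s": None, "smoothed_density": None}
    diff = onsets[:, None] - inits[None, :]
    pct_init = 100.0 * np.mean(np.min(np.abs(diff), axis=0) <= window_s)
    pct = 100.0 * np.mean(np.min(np.abs(diff), axis=1) <= window_s)
    rel = (onsets[:, None] - inits[None, :]).ravel()
    rel = rel[np.abs(rel) <= window_s]
    edges = np.linspace(-window_s, window_s, n_bins + 1)
    hist, _ = np.histogram(rel, bins=edges)
    dens = gaussian_filter1d(hist.astype(float), sigma=sigma_bins)
    bin_w = edges[1] - edges[0]
    area = dens.sum() * bin_w
    if area > 0:
        dens = dens / area
    centers = 0.5 * (edges[:-1] + edges[1:])
    return {"pct_initiations_with_burst": float(pct_init), "pct_bursts_near_onset": float(pct),
            "bin_centers_s": centers, "smoothed_density": dens}


def periburst_velocity(
    bursts_by_subject: dict[str, list[BurstEvent]],
    kin_by_subject: dict[str, Kinematics],
    window_s: tuple[float, float] = (-3.0, 3.0),
    bin_s: float = 0.1,
    min_duration_s: float = 0.2,
    alpha: float = 0.05,
) -> dict:
    """Velocity aligned to burst onset, with binwise baseline tests.

    For each subject, velocity (interpolated onto a ``bin_s`` grid) is
    averaged across all bursts of at least ``min_duration_s``; bursts too
    close to the session edges are excluded.  Each post-onset bin is compared
    to the per-subject pre-onset baseline mean with a paired t-test across
    subjects, Benjamini-Hochberg corrected.
    """
    offsets = np.arange(window_s[0] + bin_s / 2, window_s[1], bin_s)
    subj_traces = []
    for subj, events in bursts_by_subject.items():
        kin = kin_by_subject[subj]
        t0, t1 = kin.time_s[0], kin.time_s[-1]
        traces = []
        for ev in events:
            if ev.duration_s < min_duration_s:
                continue
            if ev.start_s + window_s[0] < t0 or ev.start_s + window_s[1] > t1:
                continue
            traces.append(np.interp(ev.start_s + offsets, kin.time_s, kin.velocity_cm_s))
        if traces:
            subj_traces.append(np.mean(traces, axis=0))
    result = {
        "bin_centers_s": offsets,
        "n_subjects": len(subj_traces),
        "group_mean": None,
        "group_sem": None,
        "n_significant_bins": 0,
        "significant_mask": None,
        "pvals_fdr": None,
    }
    if len(subj_traces) < 2:
        return result
    traces = np.asarray(subj_traces)
    result["group_mean"] = traces.mean(axis=0)
    result["group_sem"] = traces.std(axis=0, ddof=1) / np.sqrt(len(traces))
    pre = offsets < 0
    post = np.flatnonzero(offsets >= 0)
    baseline = traces[:, pre].mean(axis=1)

    def _paired_p(j: int) -> float:
        d = traces[:, j] - baseline
        if np.std(d) < 1e-9:  # exactly flat response: no evidence of change
            return 1.0
        return float(spstats.ttest_rel(traces[:, j], baseline).pvalue)

    pvals = np.array([_paired_p(j) for j in post])
    rej, p_fdr, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    result["n_significant_bins"] = int(rej.sum())
    mask = np.zeros(len(offsets), dtype=bool)
    mask[post] = rej
    result["significant_mask"] = mask
    result["pvals_fdr"] = p_fdr
    return result


def heading_distribution(
    bursts: list[BurstEvent], kin: Kinematics, n_bins: int = 36, sigma_bins: float = 1.0
) -> dict:
    """Heading angles at burst onsets: smoothed circular histogram + Rayleigh test."""
    onsets = np.array([b.start_s for b in bursts])
    idx = np.searchsorted(kin.time_s, onsets).clip(0, len(kin.time_s) - 1)
    headings = kin.heading_rad[idx]
    valid = headings[~np.isnan(headings)]
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    hist, _ = np.histogram(valid, bins=edges)
    smoothed = gaussian_filter1d(hist.astype(float), sigma=sigma_bins, mode="wrap")
    out = {
        "bin_centers_rad": 0.5 * (edges[:-1] + edges[1:]),
        "histogram": smoothed,
        "n_valid": int(len(valid)),
        "rayleigh": None,
        "flags": [],
    }
    if len(valid) >= 5:
        out["rayleigh"] = rayleigh(valid)
    else:
        out["flags"].append("too_few_valid_headings")
    return out


def heading_condition_test(headings_a: np.ndarray, headings_b: np.ndarray) -> CircularStatResult:
    """Mardia-Watson-Wheeler comparison of heading distributions."""
    return mww([headings_a, headings_b])


def egocentric_curvature(
    bout: MotionBout,
    tracking: TrackingData,
    n_points: int = 100,
    min_length_cm: float = 2.0,
    min_frames: int = 10,
) -> CurvatureProfile | None:
    """Curvature profile of one bout's nose trajectory in egocentric frame.

    The nose path during the bout is rotated so the tail-base-to-nose vector
    at bout onset points along +y and translated to the origin, resampled to
    ``n_points`` equally spaced arc-length positions, and differentiated:
    curvature_i = d(heading)/d(arc length) via central differences (one-sided
    at the endpoints).  Returns None (excluded) for paths shorter than
    ``min_length_cm`` or ``min_frames``.
    """
    t = tracking.time_s
    sel = (t >= bout.start_s) & (t <= bout.end_s)
    if sel.sum() < min_frames:
        return None
    nose = tracking.landmarks.get("nose")
    if nose is None:
        nose = next(iter(tracking.landmarks.values()))
    path = nose[sel]
    tail = tracking.landmarks.get("tail_base", nose)[sel]

    fwd = path[0] - tail[0]
    norm = np.linalg.norm(fwd)
    if norm == 0:
        fwd = np.array([0.0, 1.0])
        norm = 1.0
    fwd = fwd / norm
    # rotation taking fwd -> +y
    rot = np.array([[fwd[1], -fwd[0]], [fwd[0], fwd[1]]])
    ego = (path - path[0]) @ rot.T

    steps = np.linalg.norm(np.diff(ego, axis=0), axis=1)
    s = np.concatenate(([0.0], np.cumsum(steps)))
    length = s[-1]
    if length < min_length_cm:
        return None
    # collapse duplicate arc positions (stationary frames)
    keep = np.concatenate(([True], np.diff(s) > 1e-9))
    s_u, ego_u = s[keep], ego[keep]
    s_grid = np.linspace(0.0, length, n_points)
    rx = np.interp(s_grid, s_u, ego_u[:, 0])
    ry = np.interp(s_grid, s_u, ego_u[:, 1])

    dx = np.gradient(rx, s_grid)
    dy = np.gradient(ry, s_grid)
    heading = np.unwrap(np.arctan2(dy, dx))
    curv = np.gradient(heading, s_grid)
    auc = float(np.trapezoid(np.abs(curv), s_grid))
    return CurvatureProfile(
        arc_positions=np.linspace(0.0, 1.0, n_points),
        curvature=curv,
        auc=auc,
        path_length_cm=float(length),
    )


def curvature_permutation_test(
    auc_a: np.ndarray, auc_b: np.ndarray, n_perm: int = 10000, seed: int | None = None, exact_max_n: int = 12
) -> dict:
    """Paired sign-flip permutation test on per-subject curvature AUCs.

    p is the fraction of sign-flip assignments whose |mean difference| is at
    least the observed |mean difference| — enumerated exactly for up to
    ``exact_max_n`` pairs, else ``n_perm`` Monte-Carlo flips (the observed
    assignment included).  A paired t-test p-value is reported alongside.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 paired values")
    d = a - b
    obs = abs(d.mean())
    n = len(d)
    tol = 1e-12
    if n <= exact_max_n:
        signs = np.array(list(product([1.0, -1.0], repeat=n)))
        means = np.abs(signs @ d) / n
        p = float(np.mean(means >= obs - tol))
        method = "exact"
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(n_perm, n))
        means = np.abs(signs @ d) / n
        p = float((np.sum(means >= obs - tol) + 1) / (n_perm + 1))
        method = "monte_carlo"
    t_p = float(spstats.ttest_rel(a, b).pvalue)
    return {"p_perm": p, "p_ttest": t_p, "observed_mean_diff": float(d.mean()), "method": method}
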