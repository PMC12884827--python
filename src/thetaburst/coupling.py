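"""MS-CA1 burst pairing, phase-locking, circular statistics, and
amplitude-envelope lag estimation.

Conventions
-----------
* A burst pair joins an MS theta burst to the next CA1 theta burst onset
  after the MS burst's completion; the delay is CA1 onset minus MS offset,
  pairs beyond a maximum delay (default 1 s) are excluded, and each CA1
  burst is used at most once (greedy earliest match).
* PLV is the magnitude of the circular mean of instantaneous phase
  differences; it lies in [0, 1] and is invariant to any common rotation of
  both phase series.
* Envelope lag is the argmax of the normalised cross-correlation of
  mean-subtracted theta amplitude envelopes in sliding windows; positive lag
  means MS leads CA1.  Lags are taken on the sample grid (no sub-sample
  interpolation), so resolution is one sample (~1 ms at 1017 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .bursts import BurstEvent
from .session import WindowSpec, segment

__all__ = [
    "BurstPair",
    "PLVResult",
    "CircularStatResult",
    "LagResult",
    "pair_bursts",
    "classify_coupled",
    "latency_split_correlation",
    "fisher_z",
    "plv",
    "session_plv",
    "periburst_plv",
    "postburst_phase_offset",
    "circular_mean",
    "resultant_length",
    "rayleigh",
    "watson_williams",
    "mww",
    "envelope_lag",
]


@dataclass
class BurstPair:
    ms_event: BurstEvent
    ca1_event: BurstEvent
    delay_s: float  # CA1 onset - MS offset
    coupled: bool | None = None
    latency_class: str | None = None  # short | mid | long


@dataclass
class PLVResult:
    session_plv: float
    window_values: np.ndarray
    window_starts_s: np.ndarray
    binned_5min: np.ndarray
    bin_starts_s: np.ndarray
    pre_plv: float | None = None
    post_plv: float | None = None
    ratio: float | None = None


@dataclass
class CircularStatResult:
    test: str
    statistic: float
    p: float
    mean_direction: float
    resultant_length: float
    n: int
    flags: list[str] = field(default_factory=list)


@dataclass
class LagResult:
    window_lags: np.ndarray  # signed, s; MS leading positive
    window_starts_s: np.ndarray
    median_lag_s: float
    centered_lags: np.ndarray  # lag - session median
    lag_sd_s: float  # SD of signed window lags
    abs_lag_sd_s: float  # SD of |window lags| (within-session lag variability)


# ---------------------------------------------------------------------------
# burst pairing


def pair_bursts(
    ms_events: list[BurstEvent], ca1_events: list[BurstEvent], max_delay_s: float = 1.0
) -> list[BurstPair]:
    """Pair each MS burst with the next unused CA1 burst onset after its offset.

    Pairs with delay beyond ``max_delay_s`` are excluded; pairing is greedy
    in time so each CA1 burst belongs to at most one pair.
    """
    ms_sorted = sorted(ms_events, key=lambda e: e.start_s)
    ca1_sorted = sorted(ca1_events, key=lambda e: e.start_s)
    pairs: list[BurstPair] = []
    j = 0
    for ms in ms_sorted:
        while j < len(ca1_sorted) and ca1_sorted[j].start_s < ms.end_s:
            j += 1
        if j == len(ca1_sorted):
            break
        delay = ca1_sorted[j].start_s - ms.end_s
        if delay <= max_delay_s:
            pairs.append(BurstPair(ms_event=ms, ca1_event=ca1_sorted[j], delay_s=delay))
            j += 1
    return pairs


def classify_coupled(
    ca1_events: list[BurstEvent], ms_events: list[BurstEvent], window_s: float
) -> np.ndarray:
    """Flag each CA1 burst as coupled: an MS burst ended within ``window_s`` before its onset.

    ``window_s`` is a required argument: different analyses use 0.2, 0.4, or
    1.0 s windows, and no silent default is applied.
    """
    if window_s <= 0:
        raise ValueError(f"coupling window must be positive, got {window_s}")
    ms_ends = np.sort([e.end_s for e in ms_events])
    flags = np.zeros(len(ca1_events), dtype=bool)
    for i, ev in enumerate(ca1_events):
        k = np.searchsorted(ms_ends, ev.start_s, side="right")
        if k > 0 and ev.start_s - ms_ends[k - 1] <= window_s:
            flags[i] = True
    return flags


def latency_split_correlation(pairs: list[BurstPair]) -> dict:
    """MS-CA1 duration correlation in short- vs long-latency pairs.

    Pairs below the 25th percentile of the delay distribution form the short
    class and those above the 75th the long class; within each class the
    Pearson r between MS and CA1 burst durations is returned, together with
    a Fisher r-to-z comparison of the two classes (the same z statistic
    compares a class across conditions).  Classes with fewer than 4 pairs
    yield NaN.
    """
    if len(pairs) < 10:
        raise ValueError(f"need >= 10 pairs, got {len(pairs)}")
    delays = np.array([p.delay_s for p in pairs])
    q25, q75 = np.percentile(delays, [25, 75])
    out = {}
    for label, mask in (("short", delays <= q25), ("long", delays >= q75)):
        sel = [p for p, m in zip(pairs, mask) if m]
        for p in sel:
            p.latency_class = label
        if len(sel) < 4:
            out[label] = (np.nan, len(sel))
            continue
        ms_d = [p.ms_event.duration_s for p in sel]
        ca_d = [p.ca1_event.duration_s for p in sel]
        out[label] = (float(np.corrcoef(ms_d, ca_d)[0, 1]), len(sel))
    for p in pairs:
        if p.latency_class is None:
            p.latency_class = "mid"
    (r1, n1), (r2, n2) = out["short"], out["long"]
    if np.isfinite(r1) and np.isfinite(r2) and min(n1, n2) > 3 and max(abs(r1), abs(r2)) < 1:
        out["fisher_z"] = fisher_z(r1, n1, r2, n2)
    else:
        out["fisher_z"] = (np.nan, np.nan)
    return out


def fisher_z(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher r-to-z comparison of two independent correlations."""
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2 * spstats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# phase-locking


def plv(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Magnitude of the mean vector of phase differences."""
    return float(np.abs(np.mean(np.exp(1j * (np.asarray(phase_a) - np.asarray(phase_b))))))


def session_plv(
    phase_a: np.ndarray,
    phase_b: np.ndarray,
    fs: float,
    window_s: float = 8.0,
    bin_minutes: float = 5.0,
) -> PLVResult:
    """Session PLV from non-overlapping windows, plus per-5-min-bin means."""
    if len(phase_a) != len(phase_b):
        raise ValueError("phase sequences must have equal length")
    spec = WindowSpec(length_s=window_s)
    dphi = np.asarray(phase_a) - np.asarray(phase_b)
    starts, vals = [], []
    for start_s, seg in segment(dphi, fs, spec):
        starts.append(start_s)
        vals.append(float(np.abs(np.mean(np.exp(1j * seg)))))
    starts = np.asarray(starts)
    vals = np.asarray(vals)
    bin_s = bin_minutes * 60.0
    bin_starts = np.arange(0.0, (starts[-1] + window_s) if len(starts) else 0.0, bin_s)
    binned = np.array(
        [vals[(starts >= b0) & (starts < b0 + bin_s)].mean() if ((starts >= b0) & (starts < b0 + bin_s)).any() else np.nan for b0 in bin_starts]
    )
    return PLVResult(
        session_plv=float(vals.mean()) if len(vals) else np.nan,
        window_values=vals,
        window_starts_s=starts,
        binned_5min=binned,
        bin_starts_s=bin_starts,
    )


def periburst_plv(
    pairs: list[BurstPair],
    phase_ms: np.ndarray,
    phase_ca1: np.ndarray,
    fs: float,
    pre_s: float = 2.0,
    post_s: float = 2.0,
) -> list[dict]:
    """Pre- vs post-burst PLV per pair.

    The pre window spans ``pre_s`` seconds before the MS burst onset; the
    post window spans ``post_s`` seconds after the CA1 burst offset.  Pairs
    whose windows would be truncated by the recording edges are excluded.
    """
    dphi = np.asarray(phase_ms) - np.asarray(phase_ca1)
    n = len(dphi)
    out = []
    for pair in pairs:
        pre0 = int(round((pair.ms_event.start_s - pre_s) * fs))
        pre1 = int(round(pair.ms_event.start_s * fs))
        post0 = int(round(pair.ca1_event.end_s * fs))
        post1 = int(round((pair.ca1_event.end_s + post_s) * fs))
        if pre0 < 0 or post1 > n:
            continue
        pre = float(np.abs(np.mean(np.exp(1j * dphi[pre0:pre1]))))
        post = float(np.abs(np.mean(np.exp(1j * dphi[post0:post1]))))
        out.append({"pre": pre, "post": post, "ratio": post / pre if pre > 0 else np.nan, "pair": pair})
    return out


def postburst_phase_offset(
    pairs: list[BurstPair],
    phase_ms: np.ndarray,
    phase_ca1: np.ndarray,
    fs: float,
    window_s: float = 1.25,
    precede_s: float = 0.2,
) -> np.ndarray:
    """Circular-mean MS-CA1 phase offset in the window following each CA1 burst.

    Only pairs whose MS burst ended within ``precede_s`` of the CA1 onset are
    used; the offset is the circular mean of (phi_MS - phi_CA1) over
    ``window_s`` seconds from the CA1 burst onset.  Truncated windows are
    excluded.
    """
    dphi = np.asarray(phase_ms) - np.asarray(phase_ca1)
    n = len(dphi)
    offsets = []
    for pair in pairs:
        if pair.delay_s > precede_s:
            continue
        i0 = int(round(pair.ca1_event.start_s * fs))
        i1 = i0 + int(round(window_s * fs))
        if i0 < 0 or i1 > n:
            continue
        offsets.append(circular_mean(dphi[i0:i1]))
    return np.asarray(offsets)


# ---------------------------------------------------------------------------
# circular statistics


def circular_mean(angles: np.ndarray) -> float:
    return float(np.angle(np.mean(np.exp(1j * np.asarray(angles)))))


def resultant_length(angles: np.ndarray) -> float:
    return float(np.abs(np.mean(np.exp(1j * np.asarray(angles)))))


def rayleigh(angles: np.ndarray) -> CircularStatResult:
    """Rayleigh test of circular uniformity.

    Z = n * Rbar^2; p uses the standard approximation with small-sample
    correction, p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n)) with
    R = n * Rbar (Zar 1999, eq. 27.4), accurate for n >= 5.
    """
    angles = np.asarray(angles, dtype=float)
    n = len(angles)
    if n < 5:
        raise ValueError(f"Rayleigh test requires n >= 5, got {n}")
    rbar = resultant_length(angles)
    z = n * rbar**2
    big_r = n * rbar
    p = float(np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - big_r**2)) - (1 + 2 * n)))
    return CircularStatResult(
        test="rayleigh", statistic=float(z), p=min(p, 1.0), mean_direction=circular_mean(angles), resultant_length=rbar, n=n
    )


def _kappa_from_rbar(rbar: float) -> float:
    # maximum-likelihood von Mises concentration (Fisher 1993 approximations)
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1 / (rbar**3 - 4 * rbar**2 + 3 * rbar)


def watson_williams(groups: list[np.ndarray]) -> CircularStatResult:
    """Watson-Williams circular ANOVA for equality of mean directions.

    F = c * ((N - k)(sum R_i - R)) / ((k - 1)(N - sum R_i)) with the
    concentration correction c = 1 + 3/(8 kappa); kappa is estimated from
    the pooled within-group resultant.  Assumes von Mises samples with
    common, reasonably high concentration (Rbar >= ~0.45).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 5 for g in groups):
        raise ValueError("Watson-Williams requires >= 2 groups, each n >= 5")
    flags = []
    all_angles = np.concatenate(groups)
    n_tot = len(all_angles)
    k = len(groups)
    r_i = [len(g) * resultant_length(g) for g in groups]
    big_r = n_tot * resultant_length(all_angles)
    rbar_w = sum(r_i) / n_tot
    if rbar_w > 1 - 1e-12:
        flags.append("degenerate_identical_angles")
        return CircularStatResult(
            test="watson_williams", statistic=np.inf, p=np.nan,
            mean_direction=circular_mean(all_angles), resultant_length=resultant_length(all_angles),
            n=n_tot, flags=flags,
        )
    if rbar_w < 0.45:
        flags.append("low_concentration")
    kappa = _kappa_from_rbar(rbar_w)
    corr = 1 + 3 / (8 * kappa)
    denom = (k - 1) * (n_tot - sum(r_i))
    f = corr * ((n_tot - k) * (sum(r_i) - big_r)) / denom if denom > 0 else np.inf
    p = float(spstats.f.sf(f, k - 1, n_tot - k))
    return CircularStatResult(
        test="watson_williams", statistic=float(f), p=p,
        mean_direction=circular_mean(all_angles), resultant_length=resultant_length(all_angles),
        n=n_tot, flags=flags,
    )


def mww(groups: list[np.ndarray]) -> CircularStatResult:
    """Mardia-Watson-Wheeler uniform-scores test for homogeneity of circular samples.

    Pooled angles are replaced by uniform scores beta = 2 pi rank / N (average
    ranks for ties); W = 2 sum_i (C_i^2 + S_i^2) / n_i is chi-squared with
    2(k-1) degrees of freedom under the null.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 5 for g in groups):
        raise ValueError("MWW requires >= 2 groups, each n >= 5")
    all_angles = np.concatenate(groups)
    n_tot = len(all_angles)
    ranks = spstats.rankdata(np.mod(all_angles, 2 * np.pi))
    beta = 2 * np.pi * ranks / n_tot
    w = 0.0
    start = 0
    for g in groups:
        b = beta[start : start + len(g)]
        start += len(g)
        w += (np.cos(b).sum() ** 2 + np.sin(b).sum() ** 2) / len(g)
    w *= 2.0
    dof = 2 * (len(groups) - 1)
    p = float(spstats.chi2.sf(w, dof))
    return CircularStatResult(
        test="mww", statistic=float(w), p=p,
        mean_direction=circular_mean(all_angles), resultant_length=resultant_length(all_angles), n=n_tot,
    )


# ---------------------------------------------------------------------------
# amplitude-envelope lag


def envelope_lag(
    env_ms: np.ndarray,
    env_ca1: np.ndarray,
    fs: float,
    window: WindowSpec | None = None,
    max_lag_s: float = 0.5,
    var_eps: float = 1e-12,
) -> LagResult:
    """Per-window MS->CA1 lag from envelope cross-correlation.

    In each window the lag maximising the normalised cross-correlation of the
    mean-subtracted envelopes within ±``max_lag_s`` is recorded; a positive
    lag means the MS envelope leads the CA1 envelope.  Windows with
    near-constant envelopes are skipped.
    """
    if window is None:
        window = WindowSpec(length_s=10.0, overlap_s=5.0)
    env_ms = np.asarray(env_ms, dtype=float)
    env_ca1 = np.asarray(env_ca1, dtype=float)
    if len(env_ms) != len(env_ca1):
        raise ValueError("envelopes must have equal length")
    max_lag = int(round(max_lag_s * fs))
    lags_s, starts = [], []
    segs_ms = segment(env_ms, fs, window)
    segs_ca1 = segment(env_ca1, fs, window)
    for (start_s, a), (_, b) in zip(segs_ms, segs_ca1):
        a = a - a.mean()
        b = b - b.mean()
        va, vb = np.dot(a, a), np.dot(b, b)
        if va < var_eps or vb < var_eps:
            continue
        # c[k] peaks at k = d when b(t) = a(t - d): a leading by d
        c = sps.correlate(b, a, mode="full", method="fft")
        lag_axis = np.arange(-len(a) + 1, len(b))
        sel = np.abs(lag_axis) <= max_lag
        k = lag_axis[sel][np.argmax(c[sel])]
        lags_s.append(k / fs)
        starts.append(start_s)
    lags = np.asarray(lags_s)
    median = float(np.median(lags)) if len(lags) else np.nan
    return LagResult(
        window_lags=lags,
        window_starts_s=np.asarray(starts),
        median_lag_s=median,
        centered_lags=lags - median if len(lags) else lags,
        lag_sd_s=float(np.std(lags, ddof=1)) if len(lags) > 1 else np.nan,
        abs_lag_sd_s=float(np.std(np.abs(lags), ddof=1)) if len(lags) > 1 else np.nan,
    )
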