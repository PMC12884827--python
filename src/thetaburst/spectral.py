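"""Filtering, Welch power spectra, analytic signal, and lagged coherence.

All band-limited operations are zero-phase.  The bandpass is a windowed-sinc
FIR (Hamming window) whose symmetric impulse response is applied by FFT
convolution with exact group-delay alignment, so the output has no phase
distortion; the 60 Hz notch is a narrow IIR notch applied forward-backward.

Band conventions (Hz): Delta 0.5-4, Theta 5-12, Beta 13-20, LowGamma 30-55,
HighGamma 65-100.  Relative band power normalises by total power in 0-55 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .session import WindowSpec, segment

__all__ = [
    "BandDefinition",
    "BANDS",
    "THETA",
    "PSDResult",
    "LaggedCoherenceResult",
    "notch_60hz",
    "bandpass",
    "event_bandpass",
    "event_kernel",
    "welch_psd",
    "analytic",
    "lagged_coherence",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"need 0 < low < high, got {self.low}, {self.high}")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def transition_hz(self) -> float:
        # narrow transitions for the low bands, wider for gamma
        return 0.5 if self.low < 25 else 2.0


BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 0.5, 4.0),
    "theta": BandDefinition("theta", 5.0, 12.0),
    "beta": BandDefinition("beta", 13.0, 20.0),
    "low_gamma": BandDefinition("low_gamma", 30.0, 55.0),
    "high_gamma": BandDefinition("high_gamma", 65.0, 100.0),
}
THETA = BANDS["theta"]


@dataclass
class PSDResult:
    freqs: np.ndarray
    power: np.ndarray
    band_power: dict[str, float]
    relative_power: dict[str, float]
    flags: list[str] = field(default_factory=list)


@dataclass
class LaggedCoherenceResult:
    band: BandDefinition
    value: float
    window_values: np.ndarray  # per time bin; NaN where a bin was too short
    bin_starts_s: np.ndarray
    n_cycles: int
    lag_cycles: int


def notch_60hz(x: np.ndarray, fs: float, q: float = 30.0) -> np.ndarray:
    """Remove 60 Hz line noise with a zero-phase IIR notch (forward-backward)."""
    if fs <= 120:
        raise ValueError(f"fs must exceed 120 Hz for a 60 Hz notch, got {fs}")
    b, a = sps.iirnotch(60.0, Q=q, fs=fs)
    return sps.filtfilt(b, a, np.asarray(x, dtype=np.float64))


def fir_kernel(band: BandDefinition, fs: float) -> np.ndarray:
    """Symmetric (linear-phase) windowed-sinc bandpass kernel for ``band``."""
    if band.high >= fs / 2:
        raise ValueError(f"band high cutoff {band.high} Hz >= Nyquist ({fs / 2} Hz)")
    # Hamming-window design: ~3.3 / (transition width) seconds of taps
    numtaps = int(np.ceil(3.3 * fs / band.transition_hz)) | 1
    return sps.firwin(numtaps, [band.low, band.high], pass_zero=False, window="hamming", fs=fs)


def bandpass(x: np.ndarray, fs: float, band: BandDefinition) -> np.ndarray:
    """Zero-phase FIR bandpass of a raw trace.

    The symmetric kernel is applied once by FFT convolution and re-aligned by
    its (integer) group delay, which is exactly zero-phase.  If the signal is
    shorter than the designed kernel, the kernel is truncated (with a warning)
    at the cost of a wider transition band.
    """
    x = np.asarray(x, dtype=np.float64)
    h = fir_kernel(band, fs)
    if len(h) > len(x):
        warnings.warn(
            f"signal ({len(x)} samples) shorter than FIR kernel ({len(h)}); using a shorter kernel",
            stacklevel=2,
        )
        numtaps = max(3, (len(x) - 1) | 1)
        h = sps.firwin(numtaps, [band.low, band.high], pass_zero=False, window="hamming", fs=fs)
    return sps.fftconvolve(x, h, mode="same")


def edge_samples(band: BandDefinition, fs: float) -> int:
    """Half-kernel length: samples at each end affected by filter edge effects."""
    return (len(fir_kernel(band, fs)) - 1) // 2


def event_kernel(band: BandDefinition, fs: float, n_cycles: float = 3.0) -> np.ndarray:
    """Short symmetric FIR kernel spanning ``n_cycles`` of the band centre.

    Complements :func:`fir_kernel`: the narrow-transition kernel is the right
    tool for stationary spectral estimates, but its several-second impulse
    response smears transient bursts, so instantaneous phase and envelope
    around discrete events use this cycle-scale kernel instead (the standard
    wavelet-like time-frequency trade-off).
    """
    numtaps = int(round(n_cycles * fs / band.center)) | 1
    return sps.firwin(numtaps, [band.low, band.high], pass_zero=False, window="hamming", fs=fs)


def event_bandpass(x: np.ndarray, fs: float, band: BandDefinition, n_cycles: float = 3.0) -> np.ndarray:
    """Zero-phase event-scale bandpass (see :func:`event_kernel`)."""
    x = np.asarray(x, dtype=np.float64)
    h = event_kernel(band, fs, n_cycles)
    if len(h) > len(x):
        raise ValueError("signal shorter than the event kernel")
    return sps.fftconvolve(x, h, mode="same")


def welch_psd(
    x: np.ndarray,
    fs: float,
    win_s: float = 6.0,
    nfft: int = 8096,
    bands: dict[str, BandDefinition] | None = None,
    total_range: tuple[float, float] = (0.0, 55.0),
) -> PSDResult:
    """Welch PSD with Hann-tapered non-overlapping windows, plus band powers.

    Band power integrates the density over each band's limits (trapezoid);
    relative power divides by the integral over ``total_range`` (0-55 Hz).
    """
    x = np.asarray(x, dtype=np.float64)
    nperseg = int(round(win_s * fs))
    if len(x) < nperseg:
        raise ValueError(f"signal ({len(x)} samples) shorter than one {win_s}-s Welch window")
    nfft_eff = max(nfft, nperseg)
    freqs, power = sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=0, nfft=nfft_eff)
    if bands is None:
        bands = BANDS
    flags: list[str] = []

    def integrate(lo: float, hi: float) -> float:
        m = (freqs >= lo) & (freqs <= hi)
        return float(np.trapezoid(power[m], freqs[m])) if m.sum() >= 2 else 0.0

    total = integrate(*total_range)
    band_power = {name: integrate(b.low, b.high) for name, b in bands.items()}
    if total > 0:
        relative = {name: bp / total for name, bp in band_power.items()}
    else:
        relative = {name: np.nan for name in band_power}
        flags.append("zero_total_power")
    return PSDResult(freqs=freqs, power=power, band_power=band_power, relative_power=relative, flags=flags)


def analytic(x_bandpassed: np.ndarray, fs: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude envelope and instantaneous phase of a band-limited signal.

    Uses the Hilbert analytic signal.  Phase follows the cosine convention:
    it is 0 at a positive peak of the input and lies in (-pi, pi].
    """
    z = sps.hilbert(np.asarray(x_bandpassed, dtype=np.float64))
    return np.abs(z), np.angle(z)


def _lagged_coherence_band(x: np.ndarray, fs: float, band: BandDefinition, n_cycles: int, lag_cycles: int) -> float:
    """Lagged coherence averaged over integer-Hz center frequencies in ``band``.

    For each frequency f, the signal is cut into consecutive epochs of
    n_cycles/f seconds; the Fourier coefficient F_t at f is taken per epoch
    (Hann taper) and phase consistency across epochs separated by
    ``lag_cycles`` cycles is
    ``|sum F_t conj(F_{t+lag})| / sqrt(sum |F_t|^2 sum |F_{t+lag}|^2)``.
    """
    freqs = np.arange(np.ceil(band.low), np.floor(band.high) + 1.0)
    vals = []
    for f in freqs:
        n_ep = int(round(n_cycles * fs / f))
        n_epochs = len(x) // n_ep
        if n_epochs < 1 + lag_cycles + 1:
            continue
        epochs = x[: n_epochs * n_ep].reshape(n_epochs, n_ep)
        taper = np.hanning(n_ep)
        carrier = np.exp(-2j * np.pi * f * np.arange(n_ep) / fs)
        F = (epochs * taper) @ carrier
        a, b = F[:-lag_cycles] if lag_cycles else F, F[lag_cycles:] if lag_cycles else F
        num = np.abs(np.sum(a * np.conj(b)))
        den = np.sqrt(np.sum(np.abs(a) ** 2) * np.sum(np.abs(b) ** 2))
        if den > 0:
            vals.append(num / den)
    return float(np.mean(vals)) if vals else np.nan


def lagged_coherence(
    x: np.ndarray,
    fs: float,
    band: BandDefinition = THETA,
    n_cycles: int = 3,
    lag_cycles: int = 1,
    window: WindowSpec | None = None,
) -> LaggedCoherenceResult:
    """Rhythmicity of ``x`` in ``band`` as phase consistency across lagged epochs.

    The session-level value is computed over the full signal; ``window``
    (default: non-overlapping 5-min bins) gives a time-resolved trace of the
    same statistic.  Bins too short for at least two lagged epoch pairs are
    reported as NaN.
    """
    x = np.asarray(x, dtype=np.float64)
    value = _lagged_coherence_band(x, fs, band, n_cycles, lag_cycles)
    if window is None:
        window = WindowSpec(length_s=300.0)
    starts, vals = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for start_s, seg in segment(x, fs, window):
            starts.append(start_s)
            vals.append(_lagged_coherence_band(seg, fs, band, n_cycles, lag_cycles))
    return LaggedCoherenceResult(
        band=band,
        value=value,
        window_values=np.asarray(vals, dtype=float),
        bin_starts_s=np.asarray(starts, dtype=float),
        n_cycles=n_cycles,
        lag_cycles=lag_cycles,
    )
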