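"""Core data model and I/O for multi-region LFP sessions and video tracking.

A session is a set of equal-length, equal-rate voltage traces labelled by
brain region (MS, CA1, mPFC), plus subject/condition metadata.  Tracking is a
table of body-landmark positions at the video frame rate (20 frames/s).

On disk a session is one ``.npy`` array per region plus a JSON sidecar with
the sampling rate and metadata; tracking and event tables are plain CSV.
Time is expressed in seconds from recording start, and all intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SessionRecording",
    "TrackingData",
    "WindowSpec",
    "FormatError",
    "read_session",
    "write_session",
    "read_tracking",
    "write_tracking",
    "segment",
]

LANDMARKS = ("nose", "head", "left_ear", "right_ear", "back", "tail_base")


class FormatError(ValueError):
    """Raised when an on-disk session or tracking file is malformed."""


@dataclass
class SessionRecording:
    """Region-labelled LFP traces with shared sampling rate.

    Parameters
    ----------
    signals
        Mapping of region name to 1-D voltage trace (microvolts, arbitrary
        reference).  All traces must share the same length.
    fs
        Sampling rate in Hz.
    subject_id, condition
        Free-form labels (condition is typically ``"saline"`` or ``"etoh"``).
    t0
        Time of the first sample in seconds (0 by convention).
    """

    signals: dict[str, np.ndarray]
    fs: float
    subject_id: str = "subj0"
    condition: str = "saline"
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        self.signals = {r: np.asarray(x, dtype=np.float64) for r, x in self.signals.items()}
        lengths = {r: len(x) for r, x in self.signals.items()}
        if len(set(lengths.values())) > 1:
            raise FormatError(f"regions differ in length: {lengths}")

    @property
    def regions(self) -> list[str]:
        return list(self.signals)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.signals.values()))) if self.signals else 0

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class TrackingData:
    """Per-frame landmark positions from overhead video.

    ``landmarks`` maps a landmark name to an ``(n_frames, 2)`` array of
    (x_cm, y_cm).  ``gap_flags`` lists ``(landmark, start_frame, n_frames)``
    for interpolation gaps longer than the allowed maximum.
    """

    time_s: np.ndarray
    landmarks: dict[str, np.ndarray]
    frame_rate: float = 20.0
    gap_flags: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=np.float64)
        if self.frame_rate <= 0:
            raise FormatError("frame_rate must be positive")
        if len(self.time_s) > 1 and np.any(np.diff(self.time_s) <= 0):
            raise FormatError("tracking timestamps must be strictly increasing")
        self.landmarks = {k: np.asarray(v, dtype=np.float64) for k, v in self.landmarks.items()}
        for k, v in self.landmarks.items():
            if v.shape != (len(self.time_s), 2):
                raise FormatError(f"landmark {k!r} has shape {v.shape}, expected ({len(self.time_s)}, 2)")

    @property
    def n_frames(self) -> int:
        return len(self.time_s)


@dataclass(frozen=True)
class WindowSpec:
    """Tiling of a signal into fixed-length windows.

    ``overlap_s = 0`` gives non-overlapping tiling; a positive overlap gives a
    sliding window with step ``length_s - overlap_s``.
    """

    length_s: float
    overlap_s: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_s < self.length_s):
            raise ValueError(f"need 0 <= overlap_s < length_s, got {self.overlap_s}, {self.length_s}")

    @property
    def step_s(self) -> float:
        return self.length_s - self.overlap_s


def segment(signal: np.ndarray, fs: float, spec: WindowSpec) -> list[tuple[float, np.ndarray]]:
    """Tile ``signal`` into windows per ``spec``; trailing partial window dropped.

    Returns a list of ``(start_s, samples)``.  A signal shorter than one
    window yields an empty list with a warning.
    """
    signal = np.asarray(signal)
    win = int(round(spec.length_s * fs))
    step = int(round(spec.step_s * fs))
    if len(signal) < win:
        warnings.warn("signal shorter than one window; no segments returned", stacklevel=2)
        return []
    out = []
    for start in range(0, len(signal) - win + 1, step):
        out.append((start / fs, signal[start : start + win]))
    return out


# ---------------------------------------------------------------------------
# session container I/O: one .npy per region + JSON sidecar


def write_session(rec: SessionRecording, path: str | Path) -> Path:
    """Write a session to ``path`` (a directory); returns the sidecar path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for region, sig in rec.signals.items():
        np.save(path / f"{region}.npy", np.asarray(sig, dtype=np.float64))
    sidecar = {
        "fs": rec.fs,
        "regions": rec.regions,
        "subject_id": rec.subject_id,
        "condition": rec.condition,
        "t0": rec.t0,
    }
    out = path / "session.json"
    out.write_text(json.dumps(sidecar, indent=2))
    return out


def read_session(path: str | Path) -> SessionRecording:
    """Read a session written by :func:`write_session`.

    Only regions declared in the sidecar are loaded; extra ``.npy`` files are
    ignored with a warning.  Missing or inconsistent metadata raises
    :class:`FormatError`.
    """
    path = Path(path)
    sidecar_path = path / "session.json" if path.is_dir() else path
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    if "fs" not in meta or not meta["fs"]:
        raise FormatError("sidecar missing (or zero) sampling rate 'fs'")
    root = sidecar_path.parent
    signals: dict[str, np.ndarray] = {}
    for region in meta.get("regions", []):
        f = root / f"{region}.npy"
        if not f.exists():
            raise FormatError(f"declared region {region!r} has no array file")
        signals[region] = np.load(f)
    extra = {p.stem for p in root.glob("*.npy")} - set(signals)
    if extra:
        warnings.warn(f"ignoring undeclared region files: {sorted(extra)}", stacklevel=2)
    return SessionRecording(
        signals=signals,
        fs=float(meta["fs"]),
        subject_id=str(meta.get("subject_id", "subj0")),
        condition=str(meta.get("condition", "saline")),
        t0=float(meta.get("t0", 0.0)),
    )


# ---------------------------------------------------------------------------
# tracking I/O: long CSV (frame, time_s, landmark, x_cm, y_cm)


def write_tracking(trk: TrackingData, path: str | Path) -> Path:
    path = Path(path)
    frames = np.arange(trk.n_frames)
    parts = []
    for name, xy in trk.landmarks.items():
        parts.append(
            pd.DataFrame(
                {"frame": frames, "time_s": trk.time_s, "landmark": name, "x_cm": xy[:, 0], "y_cm": xy[:, 1]}
            )
        )
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)
    return path


def read_tracking(path: str | Path, max_gap_frames: int = 5) -> TrackingData:
    """Read a landmark CSV; linearly interpolate short gaps of missing frames.

    Gaps (runs of NaN positions) up to ``max_gap_frames`` frames are filled by
    linear interpolation; longer gaps are interpolated too but recorded in
    ``gap_flags`` so downstream analyses can exclude them.
    """
    df = pd.read_csv(path)
    required = {"frame", "time_s", "landmark", "x_cm", "y_cm"}
    if not required.issubset(df.columns):
        raise FormatError(f"tracking CSV missing columns {sorted(required - set(df.columns))}")
    times = np.sort(df["time_s"].unique())
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise FormatError("non-monotonic tracking timestamps")
    landmarks: dict[str, np.ndarray] = {}
    gap_flags: list[tuple] = []
    for name, grp in df.groupby("landmark", sort=False):
        grp = grp.sort_values("time_s")
        if grp["time_s"].duplicated().any():
            raise FormatError(f"duplicate timestamps for landmark {name!r}")
        xy = np.column_stack(
            [
                np.interp(times, grp["time_s"][grp["x_cm"].notna()], grp.loc[grp["x_cm"].notna(), "x_cm"]),
                np.interp(times, grp["time_s"][grp["y_cm"].notna()], grp.loc[grp["y_cm"].notna(), "y_cm"]),
            ]
        )
        # flag runs of frames that were absent/NaN and longer than max_gap_frames
        present = np.isin(times, grp.loc[grp["x_cm"].notna(), "time_s"])
        missing = ~present
        if missing.any():
            edges = np.flatnonzero(np.diff(np.concatenate(([0], missing.view(np.int8), [0]))))
            for s, e in zip(edges[::2], edges[1::2]):
                if e - s > max_gap_frames:
                    gap_flags.append((name, int(s), int(e - s)))
        landmarks[str(name)] = xy
    frame_rate = 1.0 / np.median(np.diff(times)) if len(times) > 1 else 20.0
    return TrackingData(time_s=times, landmarks=landmarks, frame_rate=float(frame_rate), gap_flags=gap_flags)
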