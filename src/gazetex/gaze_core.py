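"""Gaze-recording data model, CSV I/O, screen geometry and signal preprocessing.

A gaze recording is a timestamped sequence of on-screen gaze positions
``(GazePointX(t), GazePointY(t))`` in screen pixels, as exported by remote
video-based eye trackers, together with a per-sample validity flag.  This
module provides the containers used throughout the package plus the
preprocessing primitives the robustness experiments need: validity
filtering, integer-decimation temporal downsampling, and calibrated
spatial noise injection in units of visual angle.

Coordinate convention: origin at the top-left of the screen, x rightward,
y downward, 0-based pixel indices.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gazetex")

#: Column dialect for gaze CSV files (comma separated, UTF-8, '.' decimal).
GAZE_CSV_COLUMNS = ["subject", "trial", "question", "t", "x", "y", "valid"]


class GazeDataError(ValueError):
    """Raised for malformed, empty or otherwise unusable gaze data."""


class GazeFormatError(GazeDataError):
    """Raised when a gaze file does not follow the documented CSV dialect."""


class GazeSample(NamedTuple):
    """One gaze sample: time (s), screen position (px), validity flag."""

    t: float
    x: float
    y: float
    valid: bool


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical and logical geometry of the presentation monitor.

    Parameters
    ----------
    diagonal_mm : float
        Physical panel diagonal in millimetres (a 23-inch panel is
        ``23 * 25.4 = 584.2``).
    width_px, height_px : int
        Native resolution.
    viewing_distance_mm : float
        Eye-to-screen distance in millimetres.
    """

    diagonal_mm: float = 23.0 * 25.4
    width_px: int = 1920
    height_px: int = 1080
    viewing_distance_mm: float = 600.0

    def __post_init__(self) -> None:
        for name in ("diagonal_mm", "width_px", "height_px", "viewing_distance_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def width_mm(self) -> float:
        """Physical panel width, assuming square pixels."""
        aspect = math.hypot(self.width_px, self.height_px)
        return self.diagonal_mm * self.width_px / aspect

    @property
    def height_mm(self) -> float:
        aspect = math.hypot(self.width_px, self.height_px)
        return self.diagonal_mm * self.height_px / aspect

    @property
    def px_per_mm(self) -> float:
        """Horizontal pixel density (pixels are assumed square)."""
        return self.width_px / self.width_mm


@dataclass
class GazeRecording:
    """An ordered gaze-sample sequence for one question of one subject.

    Samples are stored as parallel numpy arrays for efficiency; the
    ``samples`` property exposes them as :class:`GazeSample` tuples.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    rate_hz: float
    subject_id: str = ""
    question_id: str = ""
    trial: int = 1

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise GazeDataError("sample arrays must have equal length")
        if n and np.any(np.diff(self.t) <= 0):
            raise GazeDataError("timestamps must be strictly increasing")
        if n and self.t[0] < 0:
            raise GazeDataError("timestamps must be non-negative")
        if self.rate_hz <= 0:
            raise GazeDataError("rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def samples(self) -> list[GazeSample]:
        return [
            GazeSample(float(t), float(x), float(y), bool(v))
            for t, x, y, v in zip(self.t, self.x, self.y, self.valid)
        ]

    @property
    def duration(self) -> float:
        """Recording span in seconds (0 for fewer than 2 samples)."""
        return float(self.t[-1] - self.t[0]) if len(self) > 1 else 0.0

    def key(self) -> tuple[str, int, str]:
        return (self.subject_id, self.trial, self.question_id)


@dataclass(frozen=True)
class ValidityReport:
    """Accounting of valid versus recorded samples."""

    n_total: int
    n_valid: int

    def __post_init__(self) -> None:
        if self.n_valid > self.n_total:
            raise ValueError("n_valid cannot exceed n_total")

    @property
    def fraction_valid(self) -> float:
        return self.n_valid / self.n_total if self.n_total else 0.0


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_gaze_csv(recordings: Sequence[GazeRecording], path) -> None:
    """Write recordings to one CSV file in the documented dialect.

    Full float repr is used for ``t``, ``x`` and ``y`` so that a
    read-back reproduces every sample bit-exactly.
    """
    recordings = list(recordings)
    if not recordings:
        raise GazeDataError("cannot write an empty sequence of recordings")
    frames = []
    for rec in recordings:
        frames.append(
            pd.DataFrame(
                {
                    "subject": rec.subject_id,
                    "trial": rec.trial,
                    "question": rec.question_id,
                    "t": rec.t,
                    "x": rec.x,
                    "y": rec.y,
                    "valid": rec.valid.astype(int),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    # repr-precision floats guarantee a lossless round-trip
    table.to_csv(path, index=False, float_format="%.17g")


def read_gaze_csv(path, geometry: ScreenGeometry | None = None,
                  rate_hz: float = 300.0) -> list[GazeRecording]:
    """Read a gaze CSV into one recording per (subject, trial, question).

    Rows with duplicated timestamps within a group are dropped with a
    warning; samples are sorted by time within each group.
    """
    try:
        # round_trip parsing keeps the repr-precision floats bit-exact
        table = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise GazeDataError(f"empty gaze file: {path}") from exc
    missing = [c for c in GAZE_CSV_COLUMNS if c not in table.columns]
    if missing:
        raise GazeFormatError(f"gaze CSV missing mandatory columns: {missing}")
    if not len(table):
        raise GazeDataError(f"gaze file has no data rows: {path}")

    recordings = []
    n_dropped = 0
    for (subject, trial, question), group in table.groupby(
        ["subject", "trial", "question"], sort=True
    ):
        group = group.sort_values("t", kind="stable")
        dup = group["t"].duplicated()
        if dup.any():
            n_dropped += int(dup.sum())
            group = group[~dup]
        recordings.append(
            GazeRecording(
                t=group["t"].to_numpy(float),
                x=group["x"].to_numpy(float),
                y=group["y"].to_numpy(float),
                valid=group["valid"].to_numpy(bool),
                rate_hz=rate_hz,
                subject_id=str(subject),
                question_id=str(question),
                trial=int(trial),
            )
        )
    if n_dropped:
        logger.warning("dropped %d duplicate-timestamp rows from %s", n_dropped, path)
    return recordings


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def filter_validity(rec: GazeRecording) -> tuple[GazeRecording, ValidityReport]:
    """Drop invalid samples, returning the cleaned recording and a report."""
    if len(rec) == 0:
        raise GazeDataError("recording has no samples")
    report = ValidityReport(n_total=len(rec), n_valid=rec.n_valid)
    if report.n_valid == 0:
        raise GazeDataError("recording has zero valid samples")
    mask = rec.valid
    cleaned = GazeRecording(
        t=rec.t[mask], x=rec.x[mask], y=rec.y[mask],
        valid=rec.valid[mask], rate_hz=rec.rate_hz,
        subject_id=rec.subject_id, question_id=rec.question_id, trial=rec.trial,
    )
    return cleaned, report


def downsample(rec: GazeRecording, target_hz: float) -> GazeRecording:
    """Temporal downsampling by pure integer decimation.

    Every k-th sample is kept starting from the first, with
    ``k = rate_hz / target_hz``; no anti-alias filtering is applied, so
    a 300 Hz recording decimated to 30 Hz keeps samples 0, 10, 20, ...
    """
    if target_hz <= 0:
        raise GazeDataError("target_hz must be positive")
    ratio = rec.rate_hz / target_hz
    k = round(ratio)
    if abs(ratio - k) > 1e-9 or k < 1:
        raise GazeDataError(
            f"target rate {target_hz} is not an integer divisor of {rec.rate_hz}"
        )
    return GazeRecording(
        t=rec.t[::k], x=rec.x[::k], y=rec.y[::k], valid=rec.valid[::k],
        rate_hz=target_hz, subject_id=rec.subject_id,
        question_id=rec.question_id, trial=rec.trial,
    )


def degrees_to_pixels(geometry: ScreenGeometry, deg: float) -> float:
    """Convert a visual angle to on-screen pixels.

    The span subtended by ``deg`` at viewing distance ``d`` is
    ``2 d tan(deg / 2)`` millimetres, converted by the horizontal pixel
    density.  For small angles this is close to ``d * deg * pi/180``
    px/mm, but the exact form is used throughout.
    """
    if deg < 0:
        raise ValueError("visual angle must be non-negative")
    span_mm = 2.0 * geometry.viewing_distance_mm * math.tan(math.radians(deg) / 2.0)
    return span_mm * geometry.px_per_mm


def pixels_to_degrees(geometry: ScreenGeometry, px: float) -> float:
    """Inverse of :func:`degrees_to_pixels` (px may be any real)."""
    span_mm = px / geometry.px_per_mm
    return math.degrees(2.0 * math.atan2(span_mm / 2.0, geometry.viewing_distance_mm))


def add_spatial_noise(rec: GazeRecording, sd_deg: float,
                      geometry: ScreenGeometry, seed: int) -> GazeRecording:
    """Add zero-mean Gaussian position noise of a given angular SD.

    Emulates an eye tracker with degraded spatial accuracy: independent
    per-axis Gaussian noise with standard deviation
    ``degrees_to_pixels(geometry, sd_deg)`` is added to every *valid*
    sample.  Timestamps and validity flags are untouched, and noised
    positions are not clamped to the screen (rendering clips instead).
    """
    if sd_deg < 0:
        raise ValueError("sd_deg must be non-negative")
    if sd_deg == 0:
        return replace(rec, t=rec.t.copy(), x=rec.x.copy(), y=rec.y.copy(),
                       valid=rec.valid.copy())
    sd_px = degrees_to_pixels(geometry, sd_deg)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sd_px, size=(len(rec), 2))
    x = rec.x.copy()
    y = rec.y.copy()
    x[rec.valid] += noise[rec.valid, 0]
    y[rec.valid] += noise[rec.valid, 1]
    return replace(rec, t=rec.t.copy(), x=x, y=y, valid=rec.valid.copy())
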