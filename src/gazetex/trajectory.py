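"""Rendering gaze recordings into square grayscale trajectory images.

The raw scanpath — not its fixation summary — is drawn onto an N x N
canvas (pixET resolution, typically 64/128/256) by connecting consecutive
valid samples with 1-px Bresenham lines.  Per-pixel intensity accumulates
by a fixed increment each time a line traverses the pixel and is clipped
at 1, producing the multi-level gray trace whose texture is the biometric
signal.  The full screen rectangle is mapped to the square canvas
anisotropically (x scaled by N/width, y by N/height) so the whole
stimulus area is preserved.

Also computes the gray-image (GI) control features: the plain mean and
standard deviation of the rendered image, used to check that texture
features carry identity information beyond overall trace density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from skimage.draw import line as bresenham_line

from .gaze_core import GazeDataError, GazeRecording, ScreenGeometry

#: Intensity added per line traversal of a pixel (clipped at 1).
DEFAULT_INCREMENT = 0.25


@dataclass
class TrajectoryImage:
    """Square grayscale rendering of one or more gaze recordings."""

    pixels: np.ndarray          # (N, N) float in [0, 1]; row = y, col = x
    size_px: int
    provenance: tuple[tuple[str, int, str], ...] = ()

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (self.size_px, self.size_px):
            raise ValueError("pixels must be size_px x size_px")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")
        if not np.any(self.pixels > 0):
            raise ValueError("trajectory image must have at least one lit pixel")


@dataclass(frozen=True)
class GIFeatures:
    """Gray-image control features: global mean and population std."""

    mean_gray: float
    std_gray: float


def _to_canvas(rec: GazeRecording, size_px: int, geometry: ScreenGeometry):
    """Map valid on-screen samples to integer canvas coordinates.

    Samples outside the screen rectangle are clipped out (they break the
    polyline rather than being clamped to the border).
    """
    on_screen = (
        rec.valid
        & (rec.x >= 0) & (rec.x < geometry.width_px)
        & (rec.y >= 0) & (rec.y < geometry.height_px)
    )
    cols = np.floor(rec.x * size_px / geometry.width_px).astype(int)
    rows = np.floor(rec.y * size_px / geometry.height_px).astype(int)
    cols = np.clip(cols, 0, size_px - 1)
    rows = np.clip(rows, 0, size_px - 1)
    return rows, cols, on_screen


def render_trajectory(recs: GazeRecording | Sequence[GazeRecording],
                      size_px: int, geometry: ScreenGeometry,
                      increment: float = DEFAULT_INCREMENT) -> TrajectoryImage:
    """Render one or more recordings onto a single N x N canvas.

    Consecutive valid samples are joined by 1-px lines; gaps across
    invalid or off-screen samples are not bridged.  Each segment adds
    ``increment`` to every pixel of its discrete line (shared endpoints
    of adjacent segments therefore receive two contributions), and the
    canvas is clipped at 1.
    """
    if isinstance(recs, GazeRecording):
        recs = [recs]
    if size_px < 32:
        raise ValueError("size_px must be at least 32")
    total_valid = sum(rec.n_valid for rec in recs)
    if total_valid < 2:
        raise GazeDataError("need at least 2 valid samples to render a trajectory")

    canvas = np.zeros((size_px, size_px), dtype=float)
    provenance = []
    for rec in recs:
        provenance.append(rec.key())
        rows, cols, usable = _to_canvas(rec, size_px, geometry)
        idx = np.flatnonzero(usable)
        if idx.size == 0:
            continue
        if idx.size == 1:
            canvas[rows[idx[0]], cols[idx[0]]] += increment
            continue
        for a, b in zip(idx[:-1], idx[1:]):
            if b != a + 1:
                continue  # gap across invalid/off-screen samples
            rr, cc = bresenham_line(rows[a], cols[a], rows[b], cols[b])
            canvas[rr, cc] += increment
    np.clip(canvas, 0.0, 1.0, out=canvas)
    if not np.any(canvas > 0):
        raise GazeDataError("no on-screen segments to render")
    return TrajectoryImage(pixels=canvas, size_px=size_px,
                           provenance=tuple(provenance))


def gi_features(img: TrajectoryImage) -> GIFeatures:
    """Mean and population standard deviation over all N^2 pixels."""
    return GIFeatures(mean_gray=float(img.pixels.mean()),
                      std_gray=float(img.pixels.std()))


def to_png(img: TrajectoryImage, path) -> None:
    """Export as 8-bit grayscale PNG, value = round(255 * intensity)."""
    from PIL import Image

    arr = np.round(img.pixels * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
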