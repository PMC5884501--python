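"""Gabor-wavelet texture features of trajectory images — the core method.

A bank of 88 complex Gabor kernels (11 scales x 8 orientations) filters
the trajectory image; the mean and the (population) standard deviation of
each magnitude response form a 176-dimensional texture descriptor.

Each kernel is a Gaussian envelope modulated by a complex plane wave::

    G(x, y) = (f^2 / (pi * gamma * eta))
              * exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2))
              * exp(i (2 pi f x' + phi))
    x' =  x cos(theta) + y sin(theta)
    y' = -x sin(theta) + y cos(theta)

with sigma = 1/f, gamma = 1, eta = 2, phi = 0.  The frequency ladder is
f_i = f_max / sqrt(2)^(i-1) with f_max = 0.5 cycles/pixel, so the lowest
of the 11 frequencies is 0.5 / sqrt(2)^10 = 1/64 = 4/256 — the classical
lower design bound f >= 4/N for an N x N image at N = 256.  Orientations
are theta_j = pi (j-1)/8.

The printed kernel above places eta only in the prefactor and gamma only
in the exponent; the conventional parameterization (envelope widths
gamma/f along x' and eta/f along y') is available as
``exponent_variant="standard"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
import scipy.fft

from .trajectory import TrajectoryImage

SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class GaborBankConfig:
    """Parameters of the Gabor filter bank.

    Defaults give the canonical 88-kernel bank; ``scale_spacing`` is the
    frequency ratio between consecutive scales (sqrt(2) = half-octave).
    """

    n_scales: int = 11
    n_orientations: int = 8
    f_max: float = 0.5
    scale_spacing: float = SQRT2
    gamma: float = 1.0
    eta: float = 2.0
    phi: float = 0.0
    exponent_variant: Literal["as-printed", "standard"] = "as-printed"

    def __post_init__(self) -> None:
        if self.n_scales < 1 or self.n_orientations < 1:
            raise ValueError("need at least one scale and one orientation")
        if not (0 < self.f_max <= 0.5):
            raise ValueError("f_max must lie in (0, 0.5]")
        if self.scale_spacing <= 1:
            raise ValueError("scale_spacing must exceed 1")

    @property
    def frequencies(self) -> np.ndarray:
        """f_i = f_max / spacing^(i-1), i = 1..n_scales."""
        i = np.arange(self.n_scales)
        return self.f_max / self.scale_spacing ** i

    @property
    def orientations(self) -> np.ndarray:
        """theta_j = pi (j-1) / n_orientations, j = 1..n_orientations."""
        j = np.arange(self.n_orientations)
        return math.pi * j / self.n_orientations

    @property
    def n_kernels(self) -> int:
        return self.n_scales * self.n_orientations

    @property
    def n_features(self) -> int:
        return 2 * self.n_kernels


@dataclass
class GaborKernel:
    """A sampled complex Gabor kernel at one (frequency, orientation)."""

    f: float
    theta: float
    values: np.ndarray  # complex, odd square grid, centre at the middle

    @property
    def half_width(self) -> int:
        return self.values.shape[0] // 2


def gabor_kernel(f: float, theta: float,
                 cfg: GaborBankConfig | None = None) -> GaborKernel:
    """Sample one Gabor kernel on an odd grid of half-width ceil(3 sigma).

    sigma = 1/f, so low frequencies produce large kernels (sigma = 64 px
    at f = 1/64).
    """
    cfg = cfg or GaborBankConfig()
    if not (0 < f <= 0.5):
        raise ValueError("frequency must lie in (0, 0.5]")
    sigma = 1.0 / f
    r = math.ceil(3.0 * sigma)
    # row index = y (downward), column index = x (rightward)
    y, x = np.mgrid[-r:r + 1, -r:r + 1].astype(float)
    xp = x * math.cos(theta) + y * math.sin(theta)
    yp = -x * math.sin(theta) + y * math.cos(theta)
    if cfg.exponent_variant == "as-printed":
        envelope = np.exp(-(xp ** 2 + cfg.gamma ** 2 * yp ** 2) / (2.0 * sigma ** 2))
    elif cfg.exponent_variant == "standard":
        envelope = np.exp(-(f ** 2) * (xp ** 2 / cfg.gamma ** 2
                                       + yp ** 2 / cfg.eta ** 2) / 2.0)
    else:  # pragma: no cover - dataclass restricts the literal
        raise ValueError(f"unknown exponent_variant {cfg.exponent_variant!r}")
    carrier = np.exp(1j * (2.0 * math.pi * f * xp + cfg.phi))
    prefactor = f ** 2 / (math.pi * cfg.gamma * cfg.eta)
    return GaborKernel(f=f, theta=theta, values=prefactor * envelope * carrier)


def build_bank(cfg: GaborBankConfig | None = None) -> list[GaborKernel]:
    """Build the scale-major list of n_scales * n_orientations kernels."""
    cfg = cfg or GaborBankConfig()
    return [
        gabor_kernel(float(f), float(theta), cfg)
        for f in cfg.frequencies
        for theta in cfg.orientations
    ]


def filter_image(img: TrajectoryImage | np.ndarray,
                 kernel: GaborKernel) -> np.ndarray:
    """Magnitude of the linear convolution of the image with one kernel.

    Linear (zero-padded) convolution in the frequency domain, cropped to
    the input size; zero padding avoids circular wrap-around, which
    matters because the largest kernels exceed the image.
    """
    pixels = img.pixels if isinstance(img, TrajectoryImage) else np.asarray(img, float)
    n0, n1 = pixels.shape
    k = kernel.values.shape[0]
    shape = (scipy.fft.next_fast_len(n0 + k - 1), scipy.fft.next_fast_len(n1 + k - 1))
    fa = scipy.fft.fft2(pixels, shape)
    fb = scipy.fft.fft2(kernel.values, shape)
    full = scipy.fft.ifft2(fa * fb)
    r = kernel.half_width
    return np.abs(full[r:r + n0, r:r + n1])


class GaborBank:
    """A filter bank with cached frequency-domain kernels per image size.

    ``extract_features`` accepts either this class or a plain kernel
    list; the cached path computes one forward FFT per image and reuses
    the kernel transforms across images, which dominates running time
    when featurizing hundreds of trajectory images.
    """

    def __init__(self, cfg: GaborBankConfig | None = None):
        self.cfg = cfg or GaborBankConfig()
        self.kernels = build_bank(self.cfg)
        self._fft_cache: dict[tuple[int, int], tuple] = {}

    def __len__(self) -> int:
        return len(self.kernels)

    def _kernel_ffts(self, shape: tuple[int, int]):
        key = shape
        if key not in self._fft_cache:
            kmax = max(k.values.shape[0] for k in self.kernels)
            pad = (scipy.fft.next_fast_len(shape[0] + kmax - 1),
                   scipy.fft.next_fast_len(shape[1] + kmax - 1))
            ffts = [scipy.fft.fft2(k.values, pad) for k in self.kernels]
            self._fft_cache[key] = (pad, ffts)
        return self._fft_cache[key]

    def transform(self, pixels: np.ndarray) -> list[np.ndarray]:
        """All magnitude responses (same size as the input), scale-major."""
        pixels = np.asarray(pixels, dtype=float)
        n0, n1 = pixels.shape
        pad, ffts = self._kernel_ffts((n0, n1))
        fa = scipy.fft.fft2(pixels, pad)
        responses = []
        for kernel, fb in zip(self.kernels, ffts):
            r = kernel.half_width
            full = scipy.fft.ifft2(fa * fb)
            responses.append(np.abs(full[r:r + n0, r:r + n1]))
        return responses


def extract_features(img: TrajectoryImage | np.ndarray,
                     bank: GaborBank | Sequence[GaborKernel] | None = None
                     ) -> np.ndarray:
    """176-dim texture descriptor: (mean, std) of each magnitude response.

    Channel order is scale-major then orientation, with the mean and the
    population standard deviation adjacent per channel.
    """
    pixels = img.pixels if isinstance(img, TrajectoryImage) else np.asarray(img, float)
    if bank is None:
        bank = GaborBank()
    if isinstance(bank, GaborBank):
        responses = bank.transform(pixels)
    else:
        responses = [filter_image(pixels, k) for k in bank]
    feats = np.empty(2 * len(responses))
    for i, resp in enumerate(responses):
        feats[2 * i] = resp.mean()
        feats[2 * i + 1] = resp.std()
    return feats


def extract_features_batch(images: Sequence[TrajectoryImage | np.ndarray],
                           bank: GaborBank | None = None) -> np.ndarray:
    """Stack per-image descriptors into an (n_images, n_features) matrix."""
    bank = bank or GaborBank()
    return np.vstack([extract_features(img, bank) for img in images])
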