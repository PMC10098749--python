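"""Hand-crafted frequency and time-frequency representations.

Three families of features:

* one-sided FFT magnitude spectra and a 4-scalar summary (total power,
  spectral centroid, peak frequency, spectral entropy) computed on the
  non-DC bins;
* multilevel DWT coefficient vectors (default: 8-level Haar with
  periodized boundaries, which for a 600-sample signal yields 603
  coefficients — together with the 4 FFT scalars a 607-dimensional
  frequency-domain block);
* CWT scalograms (analytic Morlet over a geometric scale grid) rendered as
  fixed-colormap 224x224 RGB images for the convolutional branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from matplotlib import colormaps
from PIL import Image

__all__ = [
    "SpectralBlock",
    "Scalogram",
    "fft_magnitude",
    "fft_summary",
    "dwt_coefficients",
    "dwt_coefficient_lengths",
    "inverse_dwt",
    "spectral_block",
    "cwt_scalogram",
    "render_scalogram_image",
]

RENDER_SIZE = (224, 224)
DEFAULT_WAVELET = "haar"
DEFAULT_LEVELS = 8
DEFAULT_CWT_WAVELET = "cmor1.5-1.0"
DEFAULT_N_SCALES = 64


@dataclass(frozen=True)
class SpectralBlock:
    """FFT summary scalars plus a multilevel DWT coefficient vector."""

    fft_summary: np.ndarray  # 4 scalars
    dwt_coefficients: np.ndarray

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.fft_summary, self.dwt_coefficients])


@dataclass(frozen=True)
class Scalogram:
    """CWT magnitude (scale x time) with its scale grid."""

    magnitude: np.ndarray
    scales: np.ndarray
    rendered_size: tuple[int, int] = RENDER_SIZE


def _as_signal(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal")
    return x


def fft_magnitude(signal) -> np.ndarray:
    """One-sided unnormalised FFT magnitude (length ``T//2 + 1``)."""
    x = _as_signal(signal)
    if x.size < 2:
        raise ValueError("fft_magnitude needs at least 2 samples")
    return np.abs(np.fft.rfft(x))


def fft_summary(signal, tr_seconds: float = 1.0) -> np.ndarray:
    """Summarise the non-DC one-sided spectrum by 4 scalars.

    Returns ``[total_power, centroid_hz, peak_hz, entropy_bits]``. Power is
    the sum of squared non-DC one-sided magnitudes; the centroid is the
    power-weighted mean frequency; the peak is the frequency of the largest
    power bin; the entropy is the Shannon entropy (bits) of the normalised
    power distribution. A zero signal maps to all zeros by convention.
    """
    x = _as_signal(signal)
    mag = fft_magnitude(x)
    power = mag[1:] ** 2
    total = float(power.sum())
    if total <= 0.0:
        return np.zeros(4)
    freqs = np.fft.rfftfreq(x.size, d=tr_seconds)[1:]
    p = power / total
    centroid = float(freqs @ p)
    peak = float(freqs[int(np.argmax(power))])
    nz = p[p > 0]
    entropy = float(-(nz @ np.log2(nz)))
    return np.array([total, centroid, peak, entropy])


def dwt_coefficients(
    signal,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
    mode: str = "periodization",
) -> np.ndarray:
    """Multilevel DWT coefficients as ``cA_L || cD_L || ... || cD_1``."""
    x = _as_signal(signal)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if x.size < 2**levels:
        raise ValueError(
            f"signal of length {x.size} supports at most "
            f"{int(np.log2(max(x.size, 1)))} levels, requested {levels}"
        )
    coeffs = pywt.wavedec(x, wavelet, mode=mode, level=levels)
    return np.concatenate(coeffs)


def dwt_coefficient_lengths(
    n_samples: int,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
    mode: str = "periodization",
) -> list[int]:
    """Per-band lengths ``[len(cA_L), len(cD_L), ..., len(cD_1)]``."""
    coeffs = pywt.wavedec(np.zeros(n_samples), wavelet, mode=mode, level=levels)
    return [len(c) for c in coeffs]


def inverse_dwt(
    coefficient_vector,
    n_samples: int,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
    mode: str = "periodization",
) -> np.ndarray:
    """Invert :func:`dwt_coefficients` back to a length-``n_samples`` signal."""
    vec = np.asarray(coefficient_vector, dtype=np.float64)
    lengths = dwt_coefficient_lengths(n_samples, wavelet, levels, mode)
    if vec.size != sum(lengths):
        raise ValueError("coefficient vector length inconsistent with layout")
    parts, pos = [], 0
    for ln in lengths:
        parts.append(vec[pos : pos + ln])
        pos += ln
    out = pywt.waverec(parts, wavelet, mode=mode)
    return out[:n_samples]


def spectral_block(
    signal,
    tr_seconds: float = 1.0,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
) -> SpectralBlock:
    """FFT summary and full multilevel DWT vector for one padded signal.

    Under the default preset (600 samples, Haar, 8 levels, periodization)
    the combined vector has 4 + 603 = 607 entries.
    """
    x = _as_signal(signal)
    return SpectralBlock(
        fft_summary=fft_summary(x, tr_seconds),
        dwt_coefficients=dwt_coefficients(x, wavelet, levels),
    )


def cwt_scalogram(
    signal,
    n_scales: int = DEFAULT_N_SCALES,
    wavelet: str = DEFAULT_CWT_WAVELET,
    tr_seconds: float = 1.0,
) -> Scalogram:
    """Analytic-Morlet CWT magnitude over a geometric scale grid.

    Scales span [2, T/4] geometrically so the image covers both the fast
    stimulus-locked rhythms and slow drifts of a task run.
    """
    x = _as_signal(signal)
    if x.size < 8:
        raise ValueError("cwt_scalogram needs at least 8 samples")
    if n_scales < 2:
        raise ValueError("n_scales must be >= 2")
    if not np.isfinite(x).all():
        raise ValueError("signal contains non-finite values")
    scales = np.geomspace(2.0, x.size / 4.0, n_scales)
    coefs, _ = pywt.cwt(x, scales, wavelet, sampling_period=tr_seconds)
    return Scalogram(magnitude=np.abs(coefs), scales=scales)


def render_scalogram_image(
    scalogram: Scalogram, colormap: str = "viridis"
) -> np.ndarray:
    """Render a scalogram as a 224x224x3 uint8 image.

    Magnitudes are min-max normalised (a constant field maps to a uniform
    image), passed through a fixed perceptually-uniform colormap, and
    bilinearly resized. Fully deterministic.
    """
    mag = scalogram.magnitude
    if mag.size == 0:
        raise ValueError("empty scalogram")
    lo, hi = float(mag.min()), float(mag.max())
    norm = (mag - lo) / (hi - lo) if hi > lo else np.zeros_like(mag)
    rgba = colormaps[colormap](norm)
    rgb = (rgba[..., :3] * 255.0).round().astype(np.uint8)
    img = Image.fromarray(rgb).resize(scalogram.rendered_size, Image.BILINEAR)
    return np.asarray(img)
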