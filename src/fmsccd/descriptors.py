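"""Spatial and spectral contour descriptors.

Spatial features: CCD (global-centroid distances), MSCCD (dynamic-centroid
distances at levels h = 0..H) and ASD (fore/aft neighbor angles at a set of
interval scales).  Each has a Fourier-magnitude counterpart (FCCD, FMSCCD,
FASD) obtained row-wise via the normalized DFT magnitude, truncated to
coefficients k = 0..K; magnitudes make the spectra invariant to the cyclic
start-point shift of the underlying contour.

Normalization convention: the CCD value at point i is d_uc(i) / mean(d_uc),
so every CCD sequence has mean exactly 1 and is invariant to rotation,
translation and uniform scaling.  MSCCD rows share the *same* global
denominator (sum of global-centroid distances), which makes level h = 0
identical to the CCD feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np

from fmsccd.contour_io import SampledContour

__all__ = [
    "CCDFeature",
    "MSCCDFeature",
    "SpectralFeature",
    "ASDFeature",
    "global_centroid",
    "ccd",
    "dynamic_centroids",
    "msccd",
    "dft_magnitude",
    "fccd",
    "fmsccd",
    "asd",
    "fasd",
    "default_asd_scales",
]

#: Hard cap on the multiscale level; levels h >= 10 are never used.
MAX_LEVEL = 9


@dataclass(frozen=True)
class CCDFeature:
    """Normalized centroid-contour-distance sequence, mean(values) == 1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def n_points(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MSCCDFeature:
    """Dynamic-centroid distances; row h of ``levels`` is scale level h."""

    levels: np.ndarray  # shape (H+1, Np)
    t0: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", np.asarray(self.levels, dtype=float))

    @property
    def max_level(self) -> int:
        return self.levels.shape[0] - 1

    @property
    def n_points(self) -> int:
        return self.levels.shape[1]


@dataclass(frozen=True)
class SpectralFeature:
    """Per-level DFT magnitudes; row h, columns k = 0..K."""

    coeffs: np.ndarray  # shape (n_levels, K+1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "coeffs", np.asarray(self.coeffs, dtype=float))

    @property
    def n_levels(self) -> int:
        return self.coeffs.shape[0]

    @property
    def max_coeff(self) -> int:
        return self.coeffs.shape[1] - 1


@dataclass(frozen=True)
class ASDFeature:
    """Per-scale angle sequences, normalized to [0, 1) by dividing by 2*pi."""

    angles: np.ndarray  # shape (n_scales, Np)
    scales: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles", np.asarray(self.angles, dtype=float))
        object.__setattr__(self, "scales", tuple(int(s) for s in self.scales))


def global_centroid(contour: SampledContour) -> np.ndarray:
    """Arithmetic mean of the contour's sample points."""
    return contour.points.mean(axis=0)


def _unnormalized_ccd(contour: SampledContour) -> np.ndarray:
    return np.linalg.norm(contour.points - global_centroid(contour), axis=1)


def ccd(contour: SampledContour) -> CCDFeature:
    """Centroid contour distance, normalized to mean 1.

    Raises ``ValueError`` "degenerate contour" when all points coincide.
    """
    d = _unnormalized_ccd(contour)
    total = d.sum()
    if total <= 0.0:
        raise ValueError("degenerate contour: all points coincide")
    return CCDFeature(values=d * len(d) / total)


def dynamic_centroids(contour: SampledContour, h: int) -> np.ndarray:
    """Windowed centroids: point i averages the 2^(t0-h)+1 neighbors
    i - 2^(t0-h-1) .. i + 2^(t0-h-1), indices modulo Np.

    At h = 0 the window covers every index exactly once, so every dynamic
    centroid equals the global centroid.
    """
    if not 0 <= h <= contour.t0 - 1:
        raise ValueError(f"invalid level: h={h} requires 0 <= h <= t0-1={contour.t0 - 1}")
    n = contour.n_points
    half = 2 ** (contour.t0 - h - 1)
    offsets = np.arange(-half, half + 1)
    idx = (np.arange(n)[:, None] + offsets[None, :]) % n
    return contour.points[idx].mean(axis=1)


def msccd(contour: SampledContour, H: int) -> MSCCDFeature:
    """Multiscale CCD: rows h = 0..H of normalized dynamic-centroid distances.

    All rows are divided by the same global sum of centroid distances, so row
    h = 0 equals the CCD feature exactly.  H = 0 is accepted (single-level
    degenerate case used by the FCCD reduction).
    """
    max_h = min(contour.t0 - 1, MAX_LEVEL)
    if not 0 <= H <= max_h:
        raise ValueError(f"invalid H: {H} (need 0 <= H <= {max_h})")
    n = contour.n_points
    d_uc = _unnormalized_ccd(contour)
    total = d_uc.sum()
    if total <= 0.0:
        raise ValueError("degenerate contour: all points coincide")
    rows = np.empty((H + 1, n))
    rows[0] = d_uc * n / total  # h=0 window spans all points: identical to CCD
    for h in range(1, H + 1):
        dc = dynamic_centroids(contour, h)
        rows[h] = np.linalg.norm(contour.points - dc, axis=1) * n / total
    return MSCCDFeature(levels=rows, t0=contour.t0)


def dft_magnitude(seq: np.ndarray) -> np.ndarray:
    """Normalized DFT magnitude: out(k) = |sum_i seq(i) e^{-j2pi ik/N}| / N."""
    seq = np.asarray(seq, dtype=float)
    if seq.size == 0:
        raise ValueError("empty sequence")
    return np.abs(np.fft.fft(seq)) / len(seq)


def _check_k(K: int, n_points: int) -> None:
    if not 0 <= K <= n_points - 1:
        raise ValueError(f"invalid K: {K} (need 0 <= K <= {n_points - 1})")


def fccd(feature: CCDFeature, K: int) -> SpectralFeature:
    """Single-level spectrum of a CCD feature, coefficients k = 0..K."""
    _check_k(K, feature.n_points)
    return SpectralFeature(coeffs=dft_magnitude(feature.values)[None, : K + 1])


def fmsccd(feature: MSCCDFeature, K: int) -> SpectralFeature:
    """Per-level spectra of an MSCCD feature, coefficients k = 0..K."""
    _check_k(K, feature.n_points)
    coeffs = np.vstack([dft_magnitude(row)[: K + 1] for row in feature.levels])
    return SpectralFeature(coeffs=coeffs)


def default_asd_scales(t0: int, H: int) -> tuple[int, ...]:
    """Scale set {2^(t0-h-1) : h = 1..H}, mirroring the multiscale windows."""
    return tuple(2 ** (t0 - h - 1) for h in range(1, H + 1))


def asd(contour: SampledContour, scales: Sequence[int]) -> ASDFeature:
    """Angle-scale descriptor.

    For each interval scale s, the angle at point i is the signed angle from
    the vector to the fore neighbor p_{i+s} to the vector to the aft neighbor
    p_{i-s} (atan2 of cross and dot), wrapped to [0, 2*pi) and divided by
    2*pi.  With counterclockwise orientation a square corner gives 0.25.
    """
    n = contour.n_points
    max_scale = (n - 1) // 2
    scales = tuple(int(s) for s in scales)
    for s in scales:
        if not 1 <= s <= max_scale:
            raise ValueError(f"invalid ASD scale: {s} (need 1 <= s <= {max_scale})")
    pts = contour.points
    rows = np.empty((len(scales), n))
    idx = np.arange(n)
    for r, s in enumerate(scales):
        fore = pts[(idx + s) % n] - pts
        aft = pts[(idx - s) % n] - pts
        cross = fore[:, 0] * aft[:, 1] - fore[:, 1] * aft[:, 0]
        dot = np.einsum("ij,ij->i", fore, aft)
        ang = np.arctan2(cross, dot)
        rows[r] = np.mod(ang, 2.0 * np.pi) / (2.0 * np.pi)
    return ASDFeature(angles=rows, scales=scales)


def fasd(feature: ASDFeature, K: int) -> SpectralFeature:
    """Per-scale spectra of an ASD feature, coefficients k = 0..K."""
    _check_k(K, feature.angles.shape[1])
    coeffs = np.vstack([dft_magnitude(row)[: K + 1] for row in feature.angles])
    return SpectralFeature(coeffs=coeffs)
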