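"""Pairwise dissimilarities and their configuration.

Spatial features are compared by an exhaustive cyclic-shift L2 distance (the
minimum over all Np starting-point offsets, computed exactly via FFT circular
cross-correlation).  Spectral features use a level-weighted city-block
distance.  Distances are symmetric, nonnegative and zero on identical inputs
but are not claimed to satisfy the triangle inequality.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from fmsccd.descriptors import (
    CCDFeature,
    MAX_LEVEL,
    MSCCDFeature,
    SpectralFeature,
    default_asd_scales,
)

__all__ = [
    "MatchConfig",
    "DistanceMatrix",
    "level_weights",
    "dist_ccd_exhaustive",
    "dist_msccd_exhaustive",
    "dist_spectral",
    "combined_distance",
]


def level_weights(H: int, ew: float) -> np.ndarray:
    """Normalized level weights w_h = alpha_h / sum(alpha), alpha_h = (1 - 0.1h)^ew.

    The exponent is a true power: a multiplicative factor would cancel in the
    normalization and make the weights independent of ew.  Weights sum to 1
    and decrease strictly in h for every ew > 0 and H <= 9.
    """
    if not 0 <= H <= MAX_LEVEL:
        raise ValueError(f"invalid H: {H} (levels h >= 10 are never used)")
    if ew <= 0:
        raise ValueError(f"invalid ew: {ew} (need ew > 0)")
    alpha = (1.0 - 0.1 * np.arange(H + 1)) ** ew
    return alpha / alpha.sum()


@dataclass(frozen=True)
class MatchConfig:
    """Operating point for feature extraction and matching.

    Defaults are the chosen operating point used without fine tuning:
    t0=9 (Np=513), H=6, ew=5, K=50, w_fmc=4/6.
    """

    t0: int = 9
    H: int = 6
    K: int = 50
    ew: float = 5.0
    w_fmc: float = 4.0 / 6.0
    asd_scales: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.t0 < 1:
            raise ValueError(f"invalid t0: {self.t0}")
        if not 0 <= self.H <= min(self.t0 - 1, MAX_LEVEL):
            raise ValueError(f"invalid H: {self.H}")
        if not 0 <= self.K <= 2**self.t0:
            raise ValueError(f"invalid K: {self.K}")
        if self.ew <= 0:
            raise ValueError(f"invalid ew: {self.ew}")
        if not 0.0 < self.w_fmc < 1.0:
            raise ValueError(f"invalid w_fmc: {self.w_fmc} (need 0 < w_fmc < 1)")
        if self.asd_scales is not None:
            object.__setattr__(self, "asd_scales", tuple(int(s) for s in self.asd_scales))

    @property
    def n_points(self) -> int:
        return 2**self.t0 + 1

    @property
    def w_levels(self) -> np.ndarray:
        return level_weights(self.H, self.ew)

    def effective_asd_scales(self) -> tuple[int, ...]:
        if self.asd_scales is not None:
            return self.asd_scales
        return default_asd_scales(self.t0, max(self.H, 1))


def _circular_crosscorr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """c(n) = sum_i a(i) * b(i + n mod N), for n = 0..N-1."""
    n = len(a)
    return np.fft.irfft(np.conj(np.fft.rfft(a)) * np.fft.rfft(b), n=n)


def dist_ccd_exhaustive(a: CCDFeature, b: CCDFeature) -> float:
    """Min over all cyclic shifts n of ||a - shift_n(b)||_2 (exact search)."""
    va, vb = a.values, b.values
    if va.shape != vb.shape:
        raise ValueError(
            f"incompatible features: lengths {va.shape[0]} vs {vb.shape[0]}"
        )
    sq = va @ va + vb @ vb - 2.0 * _circular_crosscorr(va, vb)
    # the quadratic expansion suffers cancellation near zero; recompute the
    # distance directly at the best shift for full precision
    n_best = int(np.argmin(sq))
    return float(np.linalg.norm(va - np.roll(vb, -n_best)))


def dist_msccd_exhaustive(a: MSCCDFeature, b: MSCCDFeature, cfg: MatchConfig) -> float:
    """Min over shifts n of sqrt(sum_h w_h sum_i (a(h,i) - b(h,n+i))^2).

    One common shift is applied to every level (a single starting-point
    offset describes one contour).
    """
    if a.levels.shape != b.levels.shape:
        raise ValueError(
            f"incompatible features: shapes {a.levels.shape} vs {b.levels.shape}"
        )
    w = level_weights(a.max_level, cfg.ew)
    total = np.zeros(a.n_points)
    for h in range(a.max_level + 1):
        ra, rb = a.levels[h], b.levels[h]
        total += w[h] * (ra @ ra + rb @ rb - 2.0 * _circular_crosscorr(ra, rb))
    # direct recomputation at the best common shift avoids cancellation noise
    n_best = int(np.argmin(total))
    shifted = np.roll(b.levels, -n_best, axis=1)
    return float(np.sqrt(np.sum(w[:, None] * (a.levels - shifted) ** 2)))


def dist_spectral(a: SpectralFeature, b: SpectralFeature, cfg: MatchConfig) -> float:
    """Level-weighted city-block distance: sum_h w_h sum_{k=0..K} |a - b|.

    With a single level this reduces to the plain city-block spectral
    distance (weight 1).  Weights follow the level-weight law on the
    feature's own row count, so FMSCCD features are weighted per their level
    h and FASD features per their scale index.
    """
    if a.coeffs.shape != b.coeffs.shape:
        raise ValueError(
            f"incompatible features: shapes {a.coeffs.shape} vs {b.coeffs.shape}"
        )
    w = level_weights(a.n_levels - 1, cfg.ew)
    return float(w @ np.abs(a.coeffs - b.coeffs).sum(axis=1))


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs dissimilarities with shape ids and class labels."""

    values: np.ndarray
    ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        ids = tuple(str(i) for i in self.ids)
        labels = tuple(str(l) for l in self.labels)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"distance matrix must be square, got {v.shape}")
        if v.shape[0] < 2:
            raise ValueError("distance matrix needs at least 2 shapes")
        if len(ids) != v.shape[0] or len(labels) != v.shape[0]:
            raise ValueError("ids/labels length must match matrix size")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric (tol 1e-9)")
        if np.abs(np.diag(v)).max() > 1e-9:
            raise ValueError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=list(self.ids))
        df.insert(0, "id", list(self.ids))
        df.insert(1, "label", list(self.labels))
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path)
        if df.columns[:2].tolist() != ["id", "label"]:
            raise ValueError("distance matrix CSV must start with id,label columns")
        ids = [str(i) for i in df["id"]]
        labels = [str(l) for l in df["label"]]
        vals = df[df.columns[2:]].to_numpy(dtype=float)
        return cls(values=vals, ids=tuple(ids), labels=tuple(labels))


def combined_distance(d1: DistanceMatrix, d2: DistanceMatrix, w_fmc: float) -> DistanceMatrix:
    """Convex combination of two distance matrices, each normalized by the
    sum of all its Nd^2 entries (diagonal included, both orderings).
    """
    if d1.ids != d2.ids or d1.labels != d2.labels:
        raise ValueError("incompatible matrices: ids/labels differ")
    if not 0.0 < w_fmc < 1.0:
        raise ValueError(f"invalid w_fmc: {w_fmc}")
    s1 = d1.values.sum()
    s2 = d2.values.sum()
    if s1 <= 0 or s2 <= 0:
        raise ValueError("cannot normalize an all-zero distance matrix")
    out = w_fmc * d1.values / s1 + (1.0 - w_fmc) * d2.values / s2
    return DistanceMatrix(values=out, ids=d1.ids, labels=d1.labels)
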