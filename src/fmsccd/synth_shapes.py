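"""Seeded parametric shape generator.

Every test input is generated here: parametric families (circle, ellipse,
regular polygon, star, superformula) expressed as radial curves r(theta),
optionally roughened with seeded low-frequency harmonic noise, densely
polygonized and uniformly resampled.  Databases add per-instance rotation,
scale and start-index augmentation applied to the *sampled* points, so at
zero noise all instances of a class are exact similarity copies of each
other up to a cyclic start shift.

Seeding: each shape draws from ``numpy.random.SeedSequence([seed, class,
instance])`` so databases are stable under partial regeneration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import shapely

from fmsccd.contour_io import RawContour, SampledContour, resample_uniform

__all__ = [
    "ShapeSpec",
    "make_shape",
    "perturb_local",
    "make_database",
    "make_fine_detail_pair",
]

_DENSE_N = 2048  # vertices of the dense polygon before resampling


@dataclass(frozen=True)
class ShapeSpec:
    """Parametric family + parameters + seeded noise amplitude."""

    family: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    noise: float = 0.0


def _radius_profile(family: str, params: dict[str, Any], theta: np.ndarray) -> np.ndarray:
    if family == "circle":
        return np.full_like(theta, float(params.get("radius", 1.0)))
    if family == "ellipse":
        a = float(params.get("a", 1.0))
        b = float(params.get("b", 0.5))
        return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    if family == "regular_polygon":
        n = int(params.get("sides", 5))
        if n < 3:
            raise ValueError("invalid spec: regular_polygon needs >= 3 sides")
        R = float(params.get("radius", 1.0))
        return R * np.cos(np.pi / n) / np.cos(np.mod(theta, 2 * np.pi / n) - np.pi / n)
    if family == "star":
        R = float(params.get("radius", 1.0))
        k = int(params.get("spikes", 5))
        amp = float(params.get("spikiness", 0.25))
        if not 0 <= amp < 1:
            raise ValueError("invalid spec: star spikiness must be in [0, 1)")
        return R * (1.0 + amp * np.cos(k * theta))
    if family == "superformula":
        # Gielis curve; leaf-like outlines for m in {1, 2}
        m = float(params.get("m", 2.0))
        n1 = float(params.get("n1", 1.0))
        n2 = float(params.get("n2", 1.0))
        n3 = float(params.get("n3", 1.0))
        a = float(params.get("a", 1.0))
        b = float(params.get("b", 1.0))
        t = np.abs(np.cos(m * theta / 4.0) / a) ** n2 + np.abs(np.sin(m * theta / 4.0) / b) ** n3
        with np.errstate(divide="ignore"):
            r = t ** (-1.0 / n1)
        if not np.all(np.isfinite(r)):
            raise ValueError("invalid spec: superformula radius diverges")
        return r * float(params.get("radius", 1.0))
    raise ValueError(f"invalid spec: unknown family {family!r}")


def _harmonic_noise(rng: np.random.Generator, theta: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth periodic perturbation: random harmonics m = 2..8, RMS ~ amplitude."""
    if amplitude == 0.0:
        return np.zeros_like(theta)
    modes = np.arange(2, 9)
    coeff = rng.normal(size=modes.size)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=modes.size)
    wave = np.sum(coeff[:, None] * np.cos(modes[:, None] * theta[None, :] + phase[:, None]), axis=0)
    return amplitude * wave / np.sqrt(modes.size / 2.0)


def make_shape(spec: ShapeSpec, t0: int) -> SampledContour:
    """Deterministic contour for a spec: radial profile + seeded noise, resampled."""
    theta = np.linspace(0.0, 2.0 * np.pi, _DENSE_N, endpoint=False)
    r = _radius_profile(spec.family, spec.params, theta)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed) & 0xFFFFFFFF]))
    r = r * (1.0 + _harmonic_noise(rng, theta, spec.noise))
    if np.any(r <= 0):
        raise ValueError("invalid spec: radius profile is not strictly positive")
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return resample_uniform(RawContour(points=pts), t0)


def perturb_local(
    contour: SampledContour,
    center_idx: int,
    width: int,
    amplitude: float,
    cycles: int = 0,
) -> SampledContour:
    """Radial perturbation confined to indices within ``width`` of ``center_idx``.

    With ``cycles=0`` (default) the profile is a raised-cosine bump on the
    cyclic index distance, displacing points radially away from the contour
    centroid by a relative factor up to ``amplitude``.  With ``cycles > 0``
    the bump envelope modulates a cosine carrier with that many oscillations
    across the window — a fine-scale local difference whose spatial
    frequency can exceed any spectral truncation.  Points outside the window
    are untouched; the result is resampled back to Np points.  Raises
    "invalid perturbation" when the displaced curve self-intersects.
    """
    n = contour.n_points
    if width >= n / 4:
        raise ValueError(f"invalid perturbation: width {width} >= Np/4 = {n / 4:g}")
    idx = np.arange(n)
    d = np.abs(idx - center_idx)
    d = np.minimum(d, n - d)  # cyclic index distance
    envelope = np.where(d <= width, np.cos(np.pi * d / (2.0 * width)) ** 2, 0.0)
    if cycles:
        # squared envelope decays faster spectrally; signed carrier keeps the
        # perturbation near zero-mean so global structure is preserved
        envelope = envelope**2 * np.cos(2.0 * np.pi * cycles * (idx - center_idx) / width)
    profile = amplitude * envelope
    factor = 1.0 + profile
    if np.any(factor <= 0):
        raise ValueError("invalid perturbation: curve collapses through the centroid")
    c = contour.points.mean(axis=0)
    moved = c + (contour.points - c) * factor[:, None]
    if not shapely.LinearRing(moved).is_simple:
        raise ValueError("invalid perturbation: curve self-intersects")
    return resample_uniform(RawContour(points=moved), contour.t0)


def make_fine_detail_pair(seed: int, t0: int = 9) -> tuple[SampledContour, SampledContour]:
    """Seeded pair of globally identical contours differing only in fine,
    high-frequency local detail.

    A square carries two antipodal mid-edge oscillatory perturbations whose
    carrier frequency lies above the usual K=50 spectral truncation; the
    coarse descriptor levels barely see the difference while the fine
    dynamic-centroid levels demodulate it.  Used by the multiscale
    sensitivity checks.
    """
    rng = np.random.default_rng(seed)
    clean = make_shape(ShapeSpec("regular_polygon", {"sides": 4}), t0)
    n = clean.n_points
    center = (n // 8 + int(rng.integers(-8, 9))) % n  # mid-edge +/- jitter
    width = int(rng.integers(26, 33))
    amplitude = float(rng.uniform(0.006, 0.012))
    cycles = int(rng.integers(4, 6))
    bumped = perturb_local(clean, center, width, amplitude, cycles=cycles)
    bumped = perturb_local(bumped, (center + n // 2) % n, width, amplitude, cycles=cycles)
    return clean, bumped


# one base family per class index, cycled; parameters drawn per class
_CLASS_FAMILIES = ("ellipse", "star", "regular_polygon", "superformula", "star")


def _class_spec(class_idx: int, db_seed: int) -> ShapeSpec:
    rng = np.random.default_rng(np.random.SeedSequence([int(db_seed) & 0xFFFFFFFF, class_idx]))
    family = _CLASS_FAMILIES[class_idx % len(_CLASS_FAMILIES)]
    cycle = class_idx // len(_CLASS_FAMILIES)
    if family == "ellipse":
        params = {"a": 1.0, "b": float(rng.uniform(0.30, 0.45) / (1 + cycle))}
    elif family == "regular_polygon":
        params = {"sides": 3 + cycle, "radius": 1.0}
    elif family == "superformula":
        params = {"m": 2.0, "n1": 0.7, "n2": 1.4 + 0.3 * cycle, "n3": 1.4 + 0.3 * cycle}
    else:  # star; vary spike count across cycles
        spikes = 5 + 3 * cycle + (class_idx % len(_CLASS_FAMILIES) == 4) * 2
        params = {"spikes": int(spikes), "spikiness": float(rng.uniform(0.18, 0.28))}
    return ShapeSpec(family=family, params=params, seed=int(db_seed) + class_idx)


def make_database(
    n_classes: int,
    n_per_class: int,
    noise: float = 0.0,
    seed: int = 0,
    t0: int = 9,
) -> list[tuple[SampledContour, str]]:
    """Seeded class database: base family per class, per-instance noise,
    random rotation, scale in [0.5, 2] and start-index shift.

    Rotation/scale/shift act on the sampled points, so zero-noise instances
    of a class are exact similarity + cyclic-shift copies of one another.
    """
    if n_classes < 2 or n_per_class < 2:
        raise ValueError("database needs n_classes >= 2 and n_per_class >= 2")
    shapes: list[tuple[SampledContour, str]] = []
    for c in range(n_classes):
        base = _class_spec(c, seed)
        label = f"class{c}"
        for i in range(n_per_class):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed) & 0xFFFFFFFF, c, i])
            )
            spec = ShapeSpec(
                family=base.family,
                params=base.params,
                seed=int(rng.integers(0, 2**31 - 1)),
                noise=noise,
            )
            contour = make_shape(spec, t0)
            angle = rng.uniform(0.0, 2.0 * np.pi)
            scale = rng.uniform(0.5, 2.0)
            shift = int(rng.integers(0, contour.n_points))
            rot = np.array(
                [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
            )
            pts = (contour.points @ rot.T) * scale + rng.uniform(-5.0, 5.0, size=2)
            pts = np.roll(pts, shift, axis=0)
            shapes.append((SampledContour(points=pts, t0=t0), label))
    return shapes
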