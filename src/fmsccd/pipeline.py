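"""Feature extraction and all-pairs distance matrices for each descriptor choice.

Descriptor names accepted everywhere: ``ccd``, ``fccd``, ``msccd``,
``fmsccd``, ``asd``, ``fasd`` and the combination ``fmsccd+fasd`` (convex
combination of the two normalized distance matrices).
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from fmsccd.contour_io import SampledContour
from fmsccd.descriptors import asd, ccd, fasd, fccd, fmsccd, msccd
from fmsccd.matching import (
    DistanceMatrix,
    MatchConfig,
    combined_distance,
    dist_ccd_exhaustive,
    dist_msccd_exhaustive,
    dist_spectral,
)

__all__ = ["DESCRIPTORS", "extract_features", "descriptor_distance_matrix"]

DESCRIPTORS = ("ccd", "fccd", "msccd", "fmsccd", "asd", "fasd", "fmsccd+fasd")


def extract_features(contour: SampledContour, descriptor: str, cfg: MatchConfig):
    """Compute the named feature for one contour (no combination descriptors)."""
    if descriptor == "ccd":
        return ccd(contour)
    if descriptor == "fccd":
        return fccd(ccd(contour), cfg.K)
    if descriptor == "msccd":
        return msccd(contour, cfg.H)
    if descriptor == "fmsccd":
        return fmsccd(msccd(contour, cfg.H), cfg.K)
    if descriptor == "asd":
        return asd(contour, cfg.effective_asd_scales())
    if descriptor == "fasd":
        return fasd(asd(contour, cfg.effective_asd_scales()), cfg.K)
    raise ValueError(f"unknown descriptor {descriptor!r} (choose from {DESCRIPTORS})")


def _pairwise(features, dist) -> np.ndarray:
    n = len(features)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = dist(features[i], features[j])
    return out


def descriptor_distance_matrix(
    contours: Sequence[SampledContour],
    labels: Sequence[str],
    descriptor: str,
    cfg: MatchConfig,
    ids: Sequence[str] | None = None,
) -> DistanceMatrix:
    """All-pairs dissimilarity matrix for a database of contours."""
    if ids is None:
        ids = [f"shape{i:04d}" for i in range(len(contours))]
    if descriptor == "fmsccd+fasd":
        d1 = descriptor_distance_matrix(contours, labels, "fmsccd", cfg, ids)
        d2 = descriptor_distance_matrix(contours, labels, "fasd", cfg, ids)
        return combined_distance(d1, d2, cfg.w_fmc)
    feats = [extract_features(c, descriptor, cfg) for c in contours]
    if descriptor == "ccd":
        values = _pairwise(feats, dist_ccd_exhaustive)
    elif descriptor == "msccd":
        values = _pairwise(feats, lambda a, b: dist_msccd_exhaustive(a, b, cfg))
    elif descriptor in ("fccd", "fmsccd", "fasd"):
        values = _pairwise(feats, lambda a, b: dist_spectral(a, b, cfg))
    elif descriptor == "asd":
        # spatial ASD matched like MSCCD rows: exhaustive common-shift L2
        from fmsccd.descriptors import MSCCDFeature

        as_ms = [
            MSCCDFeature(levels=f.angles, t0=contours[i].t0) for i, f in enumerate(feats)
        ]
        values = _pairwise(as_ms, lambda a, b: dist_msccd_exhaustive(a, b, cfg))
    else:
        raise ValueError(f"unknown descriptor {descriptor!r} (choose from {DESCRIPTORS})")
    return DistanceMatrix(values=values, ids=tuple(ids), labels=tuple(labels))
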