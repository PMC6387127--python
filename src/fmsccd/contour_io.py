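"""Binary-mask contour tracing, uniform arc-length resampling, and table I/O.

Coordinate convention: 0-based pixel centers, x rightward (columns), y
downward (rows).  Contours are closed polygons stored without a repeated
end vertex; orientation is normalized so the shoelace signed area is
positive.  Descriptors only consume the ordered point sequence, so a single
fixed convention suffices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "BinaryMask",
    "RawContour",
    "SampledContour",
    "signed_area",
    "trace_contour",
    "resample_uniform",
    "read_mask",
    "read_contour_table",
    "write_contour_table",
]


@dataclass(frozen=True)
class BinaryMask:
    """2-D integer grid; 0 is background, any nonzero value is foreground."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2-D, got {px.ndim}-D")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class RawContour:
    """Ordered closed polygon of (x, y) points, no repeated end vertex."""

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("contour points must be an (N, 2) array")
        if len(pts) < 3:
            raise ValueError("contour too small: need at least 3 points")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class SampledContour:
    """Closed contour resampled to exactly Np = 2^t0 + 1 equally spaced points."""

    points: np.ndarray
    t0: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("contour points must be an (N, 2) array")
        if self.t0 < 1:
            raise ValueError(f"invalid t0: {self.t0}")
        if len(pts) != 2**self.t0 + 1:
            raise ValueError(
                f"expected 2^{self.t0}+1 = {2**self.t0 + 1} points, got {len(pts)}"
            )
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return len(self.points)


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon (no repeated end vertex)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _dedupe_consecutive(points: np.ndarray) -> np.ndarray:
    keep = np.any(points != np.roll(points, 1, axis=0), axis=1)
    if not keep.any():
        return points[:1]
    return points[keep]


def trace_contour(mask: BinaryMask) -> RawContour:
    """Trace the outer boundary of the largest 8-connected foreground component.

    Returns an ordered closed polygon with positive signed area
    (counterclockwise under the image convention fixed by this module).
    Raises ``ValueError`` "no foreground" for an empty mask and
    "contour too small" for degenerate components.
    """
    fg = mask.pixels != 0
    if not fg.any():
        raise ValueError("no foreground")
    labeled = measure.label(fg, connectivity=2)
    sizes = np.bincount(labeled.ravel())
    sizes[0] = 0
    comp = labeled == int(np.argmax(sizes))
    if comp.sum() < 2:
        raise ValueError("contour too small: single-pixel component")

    # Pad so boundary components touching the frame still produce closed loops.
    padded = np.pad(comp, 1).astype(float)
    loops = measure.find_contours(padded, 0.5)
    if not loops:
        raise ValueError("contour too small: no traceable boundary")

    def perimeter(rc: np.ndarray) -> float:
        return float(np.linalg.norm(np.diff(rc, axis=0), axis=1).sum())

    outer = max(loops, key=perimeter)  # outer boundary dominates inner holes
    if np.allclose(outer[0], outer[-1]):
        outer = outer[:-1]
    # (row, col) -> (x, y), undo the 1-pixel pad
    pts = np.column_stack([outer[:, 1] - 1.0, outer[:, 0] - 1.0])
    pts = _dedupe_consecutive(pts)
    if len(pts) < 3:
        raise ValueError("contour too small")
    if signed_area(pts) < 0:
        pts = pts[::-1].copy()
    return RawContour(points=pts)


def resample_uniform(contour: RawContour, t0: int) -> SampledContour:
    """Resample a closed contour to 2^t0 + 1 points at equal arc-length spacing.

    Linear interpolation on cumulative chord length; the first output point is
    the contour's first point (the start position is arbitrary — every
    descriptor downstream tolerates it via shift-minimizing or DFT-magnitude
    matching).
    """
    if t0 < 1:
        raise ValueError(f"invalid t0: {t0}")
    pts = contour.points
    ring = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(ring, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = cum[-1]
    if perimeter <= 0.0:
        raise ValueError("degenerate contour: zero perimeter")
    n = 2**t0 + 1
    targets = perimeter * np.arange(n) / n
    x = np.interp(targets, cum, ring[:, 0])
    y = np.interp(targets, cum, ring[:, 1])
    return SampledContour(points=np.column_stack([x, y]), t0=t0)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a PNG/PGM/TIFF image as a binary mask (nonzero = foreground)."""
    try:
        img = np.asarray(iio.imread(Path(path)))
    except OSError as exc:
        raise ValueError(f"unreadable mask file {path}: {exc}") from exc
    if img.ndim == 3:  # collapse channel axis; any nonzero channel is foreground
        img = img.max(axis=2)
    if img.ndim != 2:
        raise ValueError(f"mask image must be 2-D, got shape {img.shape}")
    mask = BinaryMask(pixels=(img != 0).astype(np.uint8))
    if not mask.pixels.any():
        raise ValueError("no foreground")
    return mask


def read_contour_table(path: str | Path) -> RawContour:
    """Read a 2-column delimited table (header ``x,y``) as a closed contour."""
    try:
        with open(path) as fh:
            first = fh.readline()
        sep = "\t" if "\t" in first else ","
        # round_trip float parsing: pandas' default parser loses the last ulp
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"unreadable contour table {path}: {exc}") from exc
    if df.shape[1] != 2:
        raise ValueError(
            f"contour table must have exactly 2 columns (x, y), got {df.shape[1]}"
        )
    cols = [c.strip().lower() for c in df.columns]
    if cols != ["x", "y"]:
        raise ValueError(f"contour table header must be x,y, got {list(df.columns)}")
    return RawContour(points=df.to_numpy(dtype=float))


def write_contour_table(contour: RawContour | SampledContour, path: str | Path) -> None:
    """Write contour points as CSV at full float precision (lossless round-trip)."""
    df = pd.DataFrame(contour.points, columns=["x", "y"])
    df.to_csv(path, index=False, float_format="%.17g")
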