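import numpy as np
import pytest

from fmsccd.contour_io import RawContour, SampledContour, resample_uniform


def sampled_from_points(points: np.ndarray, t0: int) -> SampledContour:
    """Wrap an explicit (2^t0+1, 2) point array without resampling."""
    return SampledContour(points=np.asarray(points, dtype=float), t0=t0)


def circle_contour(t0: int, radius: float = 1.0, center=(0.0, 0.0)) -> SampledContour:
    """Exact uniform samples of a circle (analytic, not resampled)."""
    n = 2**t0 + 1
    theta = 2.0 * np.pi * np.arange(n) / n
    pts = np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )
    return sampled_from_points(pts, t0)


def square_contour(t0: int, side: float = 1.0) -> SampledContour:
    """Uniform resampling of a unit-side square starting at a corner."""
    raw = RawContour(
        points=np.array([[0.0, 0.0], [side, 0.0], [side, side], [0.0, side]])
    )
    return resample_uniform(raw, t0)


def random_simple_contour(rng: np.random.Generator, t0: int) -> SampledContour:
    """Random star-shaped (hence simple) closed contour, resampled."""
    n_dense = 400
    theta = 2.0 * np.pi * np.arange(n_dense) / n_dense
    r = 1.0 + 0.4 * np.sum(
        rng.normal(size=(4, 1))
        * np.cos(np.arange(2, 6)[:, None] * theta + rng.uniform(0, 2 * np.pi, (4, 1))),
        axis=0,
    ) / 4.0
    r = np.clip(r, 0.2, None)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return resample_uniform(RawContour(points=pts), t0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
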