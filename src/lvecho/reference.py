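"""Manual reference delineation: 20 boundary landmarks → closed spline → mask.

The expert reference border is defined by 20 points picked on the
endocardial border, joined by a periodic cubic spline (chord-length
parameterization) and rasterized with the even-odd pixel-center rule.
Observer landmark ordering (clockwise or counter-clockwise) is accepted
either way and normalized internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy import interpolate
from shapely.geometry import LineString, Polygon
from skimage import measure

N_LANDMARKS = 20


class InvalidReferenceError(ValueError):
    """The spline (or landmark polygon) self-intersects."""


@dataclass(frozen=True)
class LandmarkSet:
    """Exactly 20 ordered (row, col) boundary points forming a simple closed polygon."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.shape != (N_LANDMARKS, 2):
            raise ValueError(f"expected {N_LANDMARKS} (row, col) points, got {pts.shape}")
        if np.any(np.all(pts == np.roll(pts, -1, axis=0), axis=1)):
            raise ValueError("consecutive landmarks must be distinct")
        ring = Polygon(pts[:, ::-1])  # shapely expects (x, y) = (col, row)
        if not ring.is_valid:
            raise InvalidReferenceError("landmark polygon self-intersects")

    def counterclockwise(self) -> np.ndarray:
        """Points reordered to counter-clockwise orientation in (col, row) axes."""
        if Polygon(self.points[:, ::-1]).exterior.is_ccw:
            return self.points
        return self.points[::-1]


def spline_close(
    landmarks: LandmarkSet, samples_per_segment: int = 20
) -> np.ndarray:
    """Periodic cubic interpolating spline through the landmarks.

    Returns a dense closed curve of 20·samples_per_segment (row, col) points
    (the first landmark is not repeated at the end). The curve passes through
    every landmark exactly.
    """
    if samples_per_segment < 1:
        raise ValueError("samples_per_segment must be >= 1")
    pts = landmarks.counterclockwise()
    # splprep(per=True) treats the last input point as the period closure,
    # so the first landmark is appended explicitly
    closed = np.vstack([pts, pts[:1]])
    (tck, u) = interpolate.splprep([closed[:, 0], closed[:, 1]], per=True, s=0, k=3)
    dense_u = []
    for a, b in zip(u[:-1], u[1:]):
        dense_u.append(np.linspace(a, b, samples_per_segment, endpoint=False))
    dense_u = np.concatenate(dense_u)
    rows, cols = interpolate.splev(dense_u, tck)
    curve = np.column_stack([rows, cols])
    if not LineString(np.vstack([curve, curve[:1]])[:, ::-1]).is_simple:
        raise InvalidReferenceError("interpolated reference curve self-intersects")
    return curve


def rasterize(curve: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Mask of pixels whose centers lie strictly inside the closed curve
    (even-odd rule, 0-based pixel-center coordinates); deterministic and
    invariant to the curve's start point and orientation."""
    curve = np.asarray(curve, dtype=float)
    poly = Polygon(curve[:, ::-1])
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    inside = shapely.contains_xy(poly, cols.ravel(), rows.ravel())
    return inside.reshape(shape)


def landmarks_to_mask(
    landmarks: LandmarkSet, shape: tuple[int, int], samples_per_segment: int = 20
) -> np.ndarray:
    return rasterize(spline_close(landmarks, samples_per_segment), shape)


def sample_landmarks(
    mask: np.ndarray,
    n: int = N_LANDMARKS,
    jitter_sd: float = 0.0,
    rng=None,
) -> LandmarkSet:
    """Headless observer surrogate: ``n`` arc-length-equispaced points on the
    boundary of a truth mask, optionally perturbed by Gaussian jitter.

    Jittered candidates are redrawn (up to 10 times) if they self-intersect.
    """
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no boundary contour")
    contour = max(contours, key=len)
    seglen = np.sqrt((np.diff(contour, axis=0) ** 2).sum(axis=1))
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    targets = np.linspace(0.0, arclen[-1], n, endpoint=False)
    idx = np.searchsorted(arclen, targets)
    base = contour[np.minimum(idx, len(contour) - 1)]
    if jitter_sd <= 0:
        return LandmarkSet(base)
    rng = np.random.default_rng(rng)
    for _ in range(10):
        try:
            return LandmarkSet(base + rng.normal(0.0, jitter_sd, size=base.shape))
        except InvalidReferenceError:
            continue
    return LandmarkSet(base)


def read_landmarks_csv(path) -> LandmarkSet:
    """CSV of 20 rows "row,col"; a header line is optional."""
    import pandas as pd

    try:
        df = pd.read_csv(path, header=None, names=["row", "col"], dtype=float)
    except ValueError:
        df = pd.read_csv(path)
        df.columns = ["row", "col"]
    return LandmarkSet(df[["row", "col"]].to_numpy())


def write_landmarks_csv(landmarks: LandmarkSet, path) -> None:
    import pandas as pd

    pd.DataFrame(landmarks.points, columns=["row", "col"]).to_csv(path, index=False)
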