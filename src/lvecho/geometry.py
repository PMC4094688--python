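"""Shared raster-geometry helpers (pixel-center, row-major, 0-based convention)."""

from __future__ import annotations

import numpy as np

Point = tuple[float, float]  # (row, col)


def pixel_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Row/col coordinate arrays for pixel centers of a raster of the given shape."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    return rows.astype(float), cols.astype(float)


def ellipse_mask(
    shape: tuple[int, int],
    center: Point,
    semi_row: float,
    semi_col: float,
) -> np.ndarray:
    """Boolean mask of pixel centers inside an axis-aligned ellipse."""
    if semi_row <= 0 or semi_col <= 0:
        raise ValueError("ellipse semi-axes must be positive")
    rows, cols = pixel_grid(shape)
    return ((rows - center[0]) / semi_row) ** 2 + (
        (cols - center[1]) / semi_col
    ) ** 2 < 1.0


def half_plane_side(
    shape: tuple[int, int], p0: Point, p1: Point, reference: Point
) -> np.ndarray:
    """Boolean mask of the closed half-plane through p0-p1 NOT containing ``reference``.

    Pixels exactly on the line belong to the returned (far) side, so the
    complementary (near) side is strictly open.
    """
    rows, cols = pixel_grid(shape)
    d = _signed_side(rows, cols, p0, p1)
    d_ref = _signed_side(np.array(reference[0]), np.array(reference[1]), p0, p1)
    if d_ref == 0:
        raise ValueError("reference point lies on the dividing line")
    # far side: opposite sign to the reference, line included
    return d * np.sign(d_ref) <= 0


def _signed_side(rows, cols, p0: Point, p1: Point):
    (r0, c0), (r1, c1) = p0, p1
    return (c1 - c0) * (rows - r0) - (r1 - r0) * (cols - c0)
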