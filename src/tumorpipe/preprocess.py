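"""Histogram equalization: global, entropy diagnostics, and contrast-limited
adaptive (tile-wise) equalization.

Images are plain 2-D integer numpy arrays with values in ``[0, L-1]``
(``L`` = 256 for 8-bit input); histograms are 1-D count arrays of length
``L``.  The adaptive path divides the image into a grid of tiles, builds a
clip-limited equalization look-up table per tile, and blends the tables with
bilinear interpolation between tile centers so tile seams stay invisible.

Clipping caps every histogram bin at a ceiling and redistributes the excess
mass uniformly over all bins, which bounds the slope of the transfer
function and hence the local contrast amplification (and noise
amplification) the equalization can produce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    InfeasibleClipError,
    OutOfRangeError,
)

__all__ = [
    "ClipSpec",
    "as_gray_image",
    "compute_histogram",
    "equalization_map",
    "apply_map",
    "image_entropy",
    "clip_and_redistribute",
    "ahcn_equalize",
]


def as_gray_image(pixels: np.ndarray, levels: int = 256) -> np.ndarray:
    """Validate and return a 2-D integer gray image with values in [0, levels-1]."""
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.size == 0:
        raise DegenerateInputError(
            f"expected a non-empty 2-D gray image, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise OutOfRangeError(f"gray image must have integer dtype, got {arr.dtype}")
    if arr.min() < 0 or arr.max() >= levels:
        raise OutOfRangeError(
            f"pixel values must lie in [0, {levels - 1}], "
            f"got range [{arr.min()}, {arr.max()}]"
        )
    return arr


def compute_histogram(values: np.ndarray, n: int = 256) -> np.ndarray:
    """Count pixels per gray level.

    Parameters
    ----------
    values
        Integer pixel values, any shape (a 2-D image or a 1-D selection of
        pixels, e.g. those inside a mask).
    n
        Number of gray levels; every value must be < ``n``.

    Returns
    -------
    counts : ``(n,)`` int array with ``counts.sum() == values.size``.
    """
    arr = np.asarray(values)
    if n < 2:
        raise ConfigurationError(f"need at least 2 gray levels, got n={n}")
    if arr.size == 0:
        raise DegenerateInputError("cannot build a histogram from zero pixels")
    if not np.issubdtype(arr.dtype, np.integer):
        raise OutOfRangeError(f"histogram input must be integer, got {arr.dtype}")
    if arr.min() < 0 or arr.max() >= n:
        raise OutOfRangeError(
            f"pixel {int(arr.max() if arr.max() >= n else arr.min())} outside [0, {n - 1}]"
        )
    return np.bincount(arr.ravel(), minlength=n).astype(np.int64)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round rounds half to even; the LUT contract fixes half-up instead.
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def equalization_map(counts: np.ndarray, n_out: int | None = None) -> np.ndarray:
    """Build the monotone gray-level transfer table from a histogram.

    ``lut[i] = round_half_up((n_out - 1) * CDF(i))`` where the CDF is the
    cumulative fraction of pixels at levels ``<= i``.  The table is monotone
    non-decreasing by construction and maps the top occupied level to
    ``n_out - 1``.
    """
    c = np.asarray(counts, dtype=np.float64)
    total = c.sum()
    if total <= 0:
        raise DegenerateInputError("equalization map needs a histogram with mass")
    if n_out is None:
        n_out = c.size
    cdf = np.cumsum(c) / total
    lut = _round_half_up((n_out - 1) * cdf).astype(np.int64)
    return np.clip(lut, 0, n_out - 1)


def apply_map(img: np.ndarray, lut: np.ndarray) -> np.ndarray:
    """Remap every pixel through the look-up table; shape is preserved."""
    arr = np.asarray(img)
    lut = np.asarray(lut)
    if arr.size and arr.max() >= lut.size:
        raise OutOfRangeError(
            f"pixel {int(arr.max())} exceeds LUT domain [0, {lut.size - 1}]"
        )
    return lut[arr]


def image_entropy(counts: np.ndarray) -> float:
    """Shannon entropy of the gray-level distribution, in bits.

    ``E = -sum p_i log2 p_i`` over occupied levels (``0 * log 0 := 0``);
    maximal, ``log2 n``, exactly when the histogram is uniform.
    """
    c = np.asarray(counts, dtype=np.float64)
    total = c.sum()
    if total <= 0:
        raise DegenerateInputError("entropy of an empty histogram is undefined")
    p = c[c > 0] / total
    return float(-np.sum(p * np.log2(p)))


@dataclass
class ClipSpec:
    """Clip-limit bookkeeping for one tile.

    ``n_avg`` is the tile's mean pixel count per gray level
    (``tile_rows * tile_cols / n_gray``); ``ceiling`` is the actual per-bin
    clip limit; ``excess`` records the total clipped mass after
    :func:`clip_and_redistribute` has run.
    """

    tile_rows: int
    tile_cols: int
    n_gray: int
    clip_norm: float | None
    n_avg: float = 0.0
    ceiling: int = 0
    excess: int = 0
    n_avggray: float = 0.0

    def __post_init__(self) -> None:
        if self.tile_rows < 1 or self.tile_cols < 1 or self.n_gray < 2:
            raise ConfigurationError("tile must be >=1 px per side with >=2 levels")
        if self.clip_norm is not None and not 0.0 <= self.clip_norm <= 1.0:
            raise ConfigurationError(
                f"clip_norm must be in [0, 1] or None, got {self.clip_norm}"
            )
        self.n_avg = self.tile_rows * self.tile_cols / self.n_gray
        if self.ceiling == 0:
            self.ceiling = self._default_ceiling()

    def _default_ceiling(self) -> int:
        n_pixels = self.tile_rows * self.tile_cols
        if self.clip_norm is None:
            return n_pixels  # no bin can exceed the tile's pixel count
        # clip_norm scales the tile pixel count; the floor ceil(n_avg) keeps
        # the redistribution feasible (mass always fits under the ceiling).
        return max(math.ceil(self.clip_norm * n_pixels), math.ceil(self.n_avg), 1)


def clip_and_redistribute(
    counts: np.ndarray, spec: ClipSpec | int
) -> np.ndarray:
    """Cap every bin at the clip ceiling and redistribute the excess.

    The clipped mass is spread uniformly: ``floor(excess / n)`` to every bin,
    the remainder one count per bin starting at bin 0, then the histogram is
    re-clipped; this repeats until the clipped excess stops decreasing, and
    any final residual is dropped one count at a time into bins strictly
    below the ceiling.  Total mass is conserved exactly and every output bin
    is <= the ceiling.  Deterministic, order-fixed.

    ``spec`` may be a :class:`ClipSpec` (its ``excess`` field is updated with
    the total clipped mass of the first pass) or a bare integer ceiling.
    """
    h = np.asarray(counts, dtype=np.int64).copy()
    n = h.size
    if isinstance(spec, ClipSpec):
        if spec.n_gray != n:
            raise ConfigurationError(
                f"spec has {spec.n_gray} levels but histogram has {n}"
            )
        ceiling = spec.ceiling
    else:
        ceiling = int(spec)
    if ceiling < 1:
        raise ConfigurationError(f"clip ceiling must be >= 1, got {ceiling}")
    total = int(h.sum())
    if ceiling * n < total:
        raise InfeasibleClipError(
            f"mass {total} cannot fit under ceiling {ceiling} x {n} bins"
        )

    excess = int(np.maximum(h - ceiling, 0).sum())
    first_excess = excess
    np.minimum(h, ceiling, out=h)
    prev = None
    while excess > 0 and (prev is None or excess < prev):
        prev = excess
        h += excess // n
        rem = excess % n
        h[:rem] += 1
        excess = int(np.maximum(h - ceiling, 0).sum())
        np.minimum(h, ceiling, out=h)
    # residual that the uniform scheme cannot place without re-creating excess
    while excess > 0:
        room = np.flatnonzero(h < ceiling)
        take = room[:excess]
        h[take] += 1
        excess -= take.size
    if isinstance(spec, ClipSpec):
        spec.excess = first_excess
        spec.n_avggray = first_excess / n
    return h


def _tile_edges(size: int, n_tiles: int) -> np.ndarray:
    """Pixel boundaries of ``n_tiles`` tiles along one axis; the last tile
    absorbs any remainder when ``size`` is not divisible."""
    step = size // n_tiles
    if step < 1:
        raise ConfigurationError(
            f"grid of {n_tiles} tiles needs at least {n_tiles} pixels, got {size}"
        )
    edges = np.arange(n_tiles + 1, dtype=np.int64) * step
    edges[-1] = size
    return edges


def _axis_blend(size: int, centers: np.ndarray):
    """Per-pixel neighbour tile indices and interpolation weight along one axis."""
    pos = np.arange(size, dtype=np.float64)
    idx = np.searchsorted(centers, pos, side="right")
    i1 = np.clip(idx, 0, centers.size - 1)
    i0 = np.clip(idx - 1, 0, centers.size - 1)
    span = centers[i1] - centers[i0]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(span > 0, (pos - centers[i0]) / np.where(span > 0, span, 1), 0.0)
    return i0, i1, t


def ahcn_equalize(
    img: np.ndarray,
    grid_rows: int = 8,
    grid_cols: int = 8,
    clip_norm: float | None = 0.03,
    n_levels: int = 256,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The image is divided into ``grid_rows x grid_cols`` tiles; each tile's
    histogram is clipped (ceiling ``max(ceil(clip_norm * tile_pixels),
    ceil(n_avg))``; ``clip_norm=None`` disables clipping), the excess
    redistributed, and an equalization LUT built from the redistributed
    histogram.  Each output pixel is the bilinear blend of the LUTs of the
    (up to) four nearest tile centers, evaluated at the pixel's input level
    and rounded half-up; pixels outside the outermost tile centers use the
    nearest available one or two maps.

    With a 1x1 grid and ``clip_norm=None`` this reduces bit-for-bit to
    global equalization (map + apply).
    """
    arr = as_gray_image(img, levels=n_levels)
    if grid_rows < 1 or grid_cols < 1:
        raise ConfigurationError("tile grid counts must be >= 1")
    rows, cols = arr.shape
    r_edges = _tile_edges(rows, grid_rows)
    c_edges = _tile_edges(cols, grid_cols)

    luts = np.empty((grid_rows, grid_cols, n_levels), dtype=np.int64)
    for i in range(grid_rows):
        for j in range(grid_cols):
            tile = arr[r_edges[i]: r_edges[i + 1], c_edges[j]: c_edges[j + 1]]
            hist = compute_histogram(tile, n=n_levels)
            spec = ClipSpec(
                tile_rows=tile.shape[0],
                tile_cols=tile.shape[1],
                n_gray=n_levels,
                clip_norm=clip_norm,
            )
            hist = clip_and_redistribute(hist, spec)
            luts[i, j] = equalization_map(hist, n_out=n_levels)

    r_centers = (r_edges[:-1] + r_edges[1:] - 1) / 2.0
    c_centers = (c_edges[:-1] + c_edges[1:] - 1) / 2.0
    i0, i1, tr = _axis_blend(rows, r_centers)
    j0, j1, tc = _axis_blend(cols, c_centers)

    pix = arr
    v00 = luts[i0[:, None], j0[None, :], pix].astype(np.float64)
    v01 = luts[i0[:, None], j1[None, :], pix]
    v10 = luts[i1[:, None], j0[None, :], pix]
    v11 = luts[i1[:, None], j1[None, :], pix]
    tr2 = tr[:, None]
    tc2 = tc[None, :]
    blended = (1 - tr2) * ((1 - tc2) * v00 + tc2 * v01) + tr2 * (
        (1 - tc2) * v10 + tc2 * v11
    )
    out = np.clip(_round_half_up(blended), 0, n_levels - 1)
    return out.astype(arr.dtype)
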