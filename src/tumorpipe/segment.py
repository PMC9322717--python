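"""Otsu threshold selection and tumor-candidate region extraction.

The threshold is chosen by exhaustive search over all gray levels for the
split that maximizes the between-class variance

    sigma_b^2(t) = omega0(t) * omega1(t) * (mu0(t) - mu1(t))^2

of the two pixel classes it induces (class 0: levels <= t, class 1:
levels > t) — equivalently, the split that minimizes the within-class
variance, since sigma_total^2 = sigma_w^2(t) + sigma_b^2(t) at every t.
Ties go to the smallest threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import ConfigurationError, NoValidSplitError, OutOfRangeError, SchemaError

__all__ = [
    "OtsuStats",
    "RegionCandidate",
    "otsu_threshold",
    "within_class_variance",
    "apply_threshold",
    "binary_opening",
    "extract_tumor_candidate",
]


@dataclass(frozen=True)
class OtsuStats:
    """Full statistics of the selected Otsu split.

    ``moment0``/``moment1`` are the unnormalized first moments
    ``sum_{i in class} p_i * i`` (the class means are these divided by the
    class probabilities); exposed as diagnostics only.
    """

    threshold: int
    omega0: float
    omega1: float
    mu0: float
    mu1: float
    sigma_total2: float
    sigma_within2: float
    sigma_between2: float
    moment0: float
    moment1: float


def _class_moments(counts: np.ndarray):
    p = np.asarray(counts, dtype=np.float64)
    total = p.sum()
    if total <= 0:
        raise NoValidSplitError("histogram carries no mass")
    p /= total
    x = np.arange(p.size, dtype=np.float64)
    w0 = np.cumsum(p)
    m0 = np.cumsum(p * x)
    return p, x, w0, m0


def otsu_threshold(counts: np.ndarray) -> OtsuStats:
    """Exhaustive Otsu threshold over a gray-level histogram.

    Raises :class:`NoValidSplitError` when fewer than two levels are
    occupied (no split puts mass on both sides).
    """
    p, x, w0, m0 = _class_moments(counts)
    if np.count_nonzero(p) < 2:
        raise NoValidSplitError("need >= 2 occupied gray levels to split")
    mu_t = m0[-1]
    w0c = w0[:-1]  # candidate thresholds t = 0 .. n-2
    m0c = m0[:-1]
    cmass = np.cumsum(np.asarray(counts, dtype=np.int64))[:-1]
    valid = (cmass > 0) & (cmass < cmass[-1] + counts[-1])  # both classes occupied
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma_b = (mu_t * w0c - m0c) ** 2 / (w0c * (1.0 - w0c))
    sigma_b[~valid] = -np.inf
    t = int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer

    omega0 = float(w0c[t])
    omega1 = 1.0 - omega0
    mom0 = float(m0c[t])
    mom1 = float(mu_t - m0c[t])
    mu0 = mom0 / omega0
    mu1 = mom1 / omega1
    sigma_total2 = float(np.sum(p * (x - mu_t) ** 2))
    sigma_between2 = float(sigma_b[t])
    sigma_within2 = within_class_variance(counts, t)
    return OtsuStats(
        threshold=t,
        omega0=omega0,
        omega1=omega1,
        mu0=mu0,
        mu1=mu1,
        sigma_total2=sigma_total2,
        sigma_within2=sigma_within2,
        sigma_between2=sigma_between2,
        moment0=mom0,
        moment1=mom1,
    )


def within_class_variance(counts: np.ndarray, t: int) -> float:
    """Probability-weighted sum of the two class variances at split ``t``."""
    p, x, w0, m0 = _class_moments(counts)
    if not 0 <= t <= p.size - 2:
        raise NoValidSplitError(f"threshold {t} outside candidate range [0, {p.size - 2}]")
    c = np.asarray(counts, dtype=np.int64)
    if c[: t + 1].sum() == 0 or c[t + 1:].sum() == 0:
        raise NoValidSplitError(f"split at t={t} leaves an empty class")
    omega0 = w0[t]
    omega1 = 1.0 - omega0
    mu0 = m0[t] / omega0
    mu1 = (m0[-1] - m0[t]) / omega1
    lo = slice(0, t + 1)
    hi = slice(t + 1, p.size)
    var0 = np.sum(p[lo] * (x[lo] - mu0) ** 2) / omega0
    var1 = np.sum(p[hi] * (x[hi] - mu1) ** 2) / omega1
    return float(omega0 * var0 + omega1 * var1)


def apply_threshold(img: np.ndarray, t: int, polarity: str = "above") -> np.ndarray:
    """Binarize an image at threshold ``t``.

    ``polarity="above"`` marks pixels strictly greater than ``t`` (the
    default: tumors are assumed hyperintense); ``"below"`` marks pixels
    strictly smaller.
    """
    arr = np.asarray(img)
    if t < 0:
        raise OutOfRangeError(f"threshold must be >= 0, got {t}")
    if polarity == "above":
        mask = arr > t
    elif polarity == "below":
        mask = arr < t
    else:
        raise ConfigurationError(f"polarity must be 'above' or 'below', got {polarity!r}")
    return mask.astype(np.uint8)


def binary_opening(mask: np.ndarray) -> np.ndarray:
    """3x3 binary opening; optional speckle cleanup for thresholded masks."""
    return ndimage.binary_opening(
        np.asarray(mask, dtype=bool), structure=np.ones((3, 3), dtype=bool)
    ).astype(np.uint8)


@dataclass(frozen=True)
class RegionCandidate:
    """A single 8-connected foreground component proposed as the tumor."""

    mask: np.ndarray  # full-size 0/1 array containing exactly this component
    area: int
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) half-open


def extract_tumor_candidate(mask: np.ndarray, min_area: int = 25) -> RegionCandidate | None:
    """Largest 8-connected component with area >= ``min_area``, or ``None``.

    Absence of a qualifying component is a value (the image simply has no
    candidate), never an error.
    """
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise SchemaError(f"mask must be 2-D, got shape {arr.shape}")
    labels = measure.label(arr > 0, connectivity=2)
    if labels.max() == 0:
        return None
    regions = measure.regionprops(labels)
    best = max(regions, key=lambda r: (r.area, -r.label))
    if best.area < min_area:
        return None
    component = (labels == best.label).astype(np.uint8)
    return RegionCandidate(mask=component, area=int(best.area), bbox=tuple(best.bbox))
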