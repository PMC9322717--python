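"""Seeded synthetic brain phantoms and feature-space cluster datasets.

A phantom is an axial-slice stand-in: a bright elliptical "brain" on a dark
background, its tissue intensities compressed into a narrow contrast window
(simulating poor acquisition contrast), corrupted by a smooth low-order
polynomial bias field and additive Gaussian noise, optionally carrying a
compact hyperintense elliptical tumor with a ground-truth mask.  Everything
is driven by one integer seed, with no hidden global random state, so
cohorts regenerate bit-identically.

The cluster generator produces truncated-Gaussian class clouds on the unit
hypercube for exercising the classifier in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateInputError, PhantomSpecError

__all__ = [
    "TumorSpec",
    "PhantomSpec",
    "PhantomSample",
    "make_phantom",
    "make_cohort",
    "make_cluster_dataset",
]

TUMOR = "tumor"
NO_TUMOR = "no-tumor"


@dataclass(frozen=True)
class TumorSpec:
    center: tuple[float, float]  # (row, col) in pixels
    semi_axes: tuple[float, float]  # (row, col) in pixels
    intensity_delta: float = 80.0


@dataclass(frozen=True)
class PhantomSpec:
    """All knobs of one phantom; defaults are the package's study conditions."""

    shape: tuple[int, int] = (128, 128)
    brain_center: tuple[float, float] | None = None  # default: image center
    brain_axes: tuple[float, float] | None = None  # default: 42%/36% of extent
    contrast_window: tuple[float, float] = (100.0, 140.0)
    bias_amplitude: float = 10.0
    noise_sigma: float = 5.0
    tumor: TumorSpec | None = None
    seed: int = 0

    def resolved_brain(self):
        rows, cols = self.shape
        center = self.brain_center or ((rows - 1) / 2.0, (cols - 1) / 2.0)
        axes = self.brain_axes or (0.42 * rows, 0.36 * cols)
        return center, axes


@dataclass(frozen=True)
class PhantomSample:
    image: np.ndarray  # uint8 gray image
    mask: np.ndarray  # uint8 0/1 ground-truth tumor mask
    label: str  # TUMOR iff mask is non-empty


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    rr, cc = np.mgrid[0: shape[0], 0: shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _smooth_field(shape, rng: np.random.Generator) -> np.ndarray:
    """Smooth random field in [0, 1]: a seeded quadratic polynomial plus two
    low-frequency cosine components, rescaled to the unit interval."""
    rows, cols = shape
    u = np.linspace(-1.0, 1.0, rows)[:, None]
    v = np.linspace(-1.0, 1.0, cols)[None, :]
    c = rng.uniform(-1.0, 1.0, size=6)
    f = c[0] + c[1] * u + c[2] * v + c[3] * u * v + c[4] * u**2 + c[5] * v**2
    ph = rng.uniform(0, 2 * np.pi, size=2)
    f = f + 0.5 * np.cos(np.pi * u + ph[0]) + 0.5 * np.cos(np.pi * v + ph[1])
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return np.full(shape, 0.5)
    return (f - lo) / (hi - lo)


def make_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom deterministically from its spec and seed."""
    rows, cols = spec.shape
    if rows < 8 or cols < 8:
        raise PhantomSpecError(f"phantom shape {spec.shape} is too small")
    lo, hi = spec.contrast_window
    if not 0 <= lo < hi <= 255:
        raise PhantomSpecError(f"contrast window {spec.contrast_window} invalid")
    rng = np.random.default_rng(spec.seed)
    center, axes = spec.resolved_brain()
    brain = _ellipse_mask(spec.shape, center, axes)

    # tissue texture lives inside the contrast window; bias and noise on top
    texture = lo + (hi - lo) * _smooth_field(spec.shape, rng)
    bias = spec.bias_amplitude * (2.0 * _smooth_field(spec.shape, rng) - 1.0)
    img = np.zeros(spec.shape, dtype=np.float64)
    img[brain] = texture[brain] + bias[brain]

    mask = np.zeros(spec.shape, dtype=np.uint8)
    if spec.tumor is not None:
        tmask = _ellipse_mask(spec.shape, spec.tumor.center, spec.tumor.semi_axes)
        if not tmask.any():
            raise PhantomSpecError("tumor ellipse rasterizes to zero pixels")
        if np.any(tmask & ~brain):
            raise PhantomSpecError("tumor must lie entirely inside the brain ellipse")
        img[tmask] += spec.tumor.intensity_delta
        mask[tmask] = 1

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    label = TUMOR if mask.any() else NO_TUMOR
    return PhantomSample(image=image, mask=mask, label=label)


def make_cohort(
    n: int,
    tumor_fraction: float,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list[PhantomSample]:
    """Generate ``round(n * tumor_fraction)`` tumor phantoms (jittered tumor
    geometry) followed by tumor-free ones, all seeded from ``seed``."""
    if n < 1:
        raise DegenerateInputError("cohort size must be >= 1")
    if not 0.0 <= tumor_fraction <= 1.0:
        raise PhantomSpecError(f"tumor_fraction must be in [0, 1], got {tumor_fraction}")
    base = base_spec or PhantomSpec()
    n_tumor = round(n * tumor_fraction)
    rng = np.random.default_rng(seed)
    center, axes = base.resolved_brain()
    delta = base.tumor.intensity_delta if base.tumor is not None else 80.0

    samples = []
    for i in range(n):
        child_seed = int(rng.integers(0, 2**31 - 1))
        if i < n_tumor:
            # place the tumor well inside the brain ellipse
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.0, 0.45)
            t_center = (
                center[0] + rad * axes[0] * np.sin(ang),
                center[1] + rad * axes[1] * np.cos(ang),
            )
            t_axes = (rng.uniform(5.0, 9.0), rng.uniform(5.0, 9.0))
            tumor = TumorSpec(center=t_center, semi_axes=t_axes, intensity_delta=delta)
        else:
            tumor = None
        spec = replace(base, tumor=tumor, seed=child_seed)
        samples.append(make_phantom(spec))
    return samples


def make_cluster_dataset(
    k: int,
    d: int,
    n_per_class: int,
    separation: float,
    sigma: float = 0.05,
    seed: int = 0,
):
    """Truncated-Gaussian class clouds on [0, 1]^d.

    Class centers are rejection-sampled in the interior of the hypercube
    until every pair is at least ``separation * sigma`` apart; samples are
    ``N(center, sigma^2 I)`` clamped to [0, 1].

    Returns ``(X, y)`` with ``X`` of shape ``(k * n_per_class, d)`` and
    string labels ``"c0" .. "c{k-1}"``.
    """
    if k < 2 or d < 1 or n_per_class < 1:
        raise DegenerateInputError("need k >= 2, d >= 1, n_per_class >= 1")
    if separation <= 0 or sigma <= 0:
        raise PhantomSpecError("separation and sigma must be > 0")
    rng = np.random.default_rng(seed)
    min_dist = separation * sigma
    margin = min(0.25, 2 * sigma)
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < k:
        cand = rng.uniform(margin, 1.0 - margin, size=d)
        if all(np.linalg.norm(cand - c) >= min_dist for c in centers):
            centers.append(cand)
        tries += 1
        if tries > 20000:
            raise PhantomSpecError(
                f"cannot place {k} centers {min_dist:.3f} apart in [0,1]^{d}"
            )
    X = np.concatenate(
        [
            np.clip(rng.normal(c, sigma, size=(n_per_class, d)), 0.0, 1.0)
            for c in centers
        ]
    )
    y = np.repeat([f"c{i}" for i in range(k)], n_per_class)
    return X, y
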