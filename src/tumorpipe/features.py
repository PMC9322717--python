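"""Region features and min-max normalization for the classifier.

A detected region is summarized by a fixed 8-feature vector covering shape
(area, perimeter, circularity, eccentricity), position (centroid as a
fraction of the image extent) and intensity (mean, standard deviation
inside the region).  Features are min-max normalized to [0, 1] against
ranges fitted on a training set, because the classifier's max-min
similarity is only contractually bounded on the unit hypercube.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .errors import DegenerateInputError, SchemaError
from .segment import RegionCandidate

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "FeatureRanges",
    "extract_region_features",
    "fit_ranges",
    "normalize",
]

FEATURE_NAMES: tuple[str, ...] = (
    "area",
    "perimeter",
    "circularity",
    "eccentricity",
    "centroid_row_frac",
    "centroid_col_frac",
    "mean_intensity",
    "std_intensity",
)


@dataclass(frozen=True)
class FeatureVector:
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 1 or vals.size != len(self.names):
            raise SchemaError(
                f"{len(self.names)} names but value shape {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise SchemaError("feature values must be finite")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class FeatureRanges:
    """Per-feature (min, max) learned from training vectors."""

    names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "mins": [float(v) for v in self.mins],
            "maxs": [float(v) for v in self.maxs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureRanges":
        return cls(
            names=tuple(d["names"]),
            mins=np.asarray(d["mins"], dtype=np.float64),
            maxs=np.asarray(d["maxs"], dtype=np.float64),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def extract_region_features(img: np.ndarray, region: RegionCandidate) -> FeatureVector:
    """Measure the 8-feature descriptor of one region on its source image.

    Circularity is ``4 * pi * area / perimeter**2`` (1 for an ideal disc);
    the perimeter is the Crofton-weighted boundary length of
    ``skimage.measure.regionprops``, which is unbiased for smooth blobs.  A
    single-pixel region (perimeter 0) gets circularity 1 by convention.
    """
    arr = np.asarray(img)
    comp = np.asarray(region.mask)
    if comp.shape != arr.shape:
        raise SchemaError(f"region shape {comp.shape} != image shape {arr.shape}")
    if region.area < 1 or not comp.any():
        raise DegenerateInputError("cannot extract features from an empty region")

    props = measure.regionprops(comp.astype(np.int32))[0]
    area = float(props.area)
    perimeter = float(props.perimeter)
    circularity = 4.0 * math.pi * area / perimeter**2 if perimeter > 0 else 1.0
    rows, cols = arr.shape
    cr, cc = props.centroid
    inside = arr[comp > 0].astype(np.float64)
    values = np.array(
        [
            area,
            perimeter,
            circularity,
            float(props.eccentricity),
            cr / max(rows - 1, 1),
            cc / max(cols - 1, 1),
            float(inside.mean()),
            float(inside.std()),
        ]
    )
    return FeatureVector(names=FEATURE_NAMES, values=values)


def fit_ranges(vectors: list[FeatureVector]) -> FeatureRanges:
    """Per-feature min/max over a training set of vectors."""
    if not vectors:
        raise DegenerateInputError("need at least one vector to fit ranges")
    names = vectors[0].names
    for fv in vectors:
        if fv.names != names:
            raise SchemaError(f"feature names differ: {fv.names} vs {names}")
    stacked = np.stack([fv.values for fv in vectors])
    return FeatureRanges(names=names, mins=stacked.min(axis=0), maxs=stacked.max(axis=0))


def normalize(fv: FeatureVector, ranges: FeatureRanges) -> FeatureVector:
    """Min-max scale into [0, 1], clamping out-of-range values.

    A degenerate feature (max == min in training) maps to 0.5.
    """
    if fv.names != ranges.names:
        raise SchemaError(f"feature names {fv.names} do not match ranges {ranges.names}")
    span = ranges.maxs - ranges.mins
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (fv.values - ranges.mins) / np.where(span > 0, span, 1.0)
    scaled = np.where(span > 0, np.clip(scaled, 0.0, 1.0), 0.5)
    return FeatureVector(names=fv.names, values=scaled)
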