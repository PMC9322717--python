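"""End-to-end pipeline: enhance, segment, detect, featurize, classify.

Per image the stages are: contrast-limited adaptive equalization; Otsu
segmentation; largest-component tumor-candidate extraction; region feature
extraction and normalization; max-min LVQ classification.  An image with no
surviving candidate is predicted tumor-free directly (with similarity 0) —
absence of a candidate is a first-class prediction, never an exception.

Segmentation is iterated Otsu: a whole-head image is dominated by the
background/tissue bimodality and a small tumor is a tiny minority class
Otsu's balanced-split objective will not pick, so the threshold is re-run
on the current foreground until the foreground occupies at most
``segment.max_region_fraction`` of the image (default 0.2) or no further
valid split exists.  Setting the fraction to 1.0 reduces to a single global
Otsu.

The thresholds are computed on the *original* intensities by default
(``segment.source: original``): adaptive equalization is a local-contrast
transform that deliberately discards the global intensity ranking a
threshold depends on (each tile's brightest content maps toward the top of
the range), so thresholding its output cannot isolate a globally
hyperintense minority blob.  The enhanced image is still what the region's
intensity features are measured on, which is where contrast normalization
pays off.  ``segment.source: enhanced`` thresholds the equalized image
instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import evaluation, features, lvq, preprocess, segment
from .errors import ConfigurationError, NoValidSplitError
from .segment import RegionCandidate
from .synthetic import NO_TUMOR, TUMOR, PhantomSample

__all__ = [
    "ImageRecord",
    "PipelineResult",
    "segment_image",
    "build_feature_table",
    "train_codebook",
    "run_pipeline",
]


@dataclass
class ImageRecord:
    """Per-image outcome of one pipeline run."""

    index: int
    label: str
    similarity: float
    candidate: RegionCandidate | None
    feature_values: np.ndarray | None
    dice: float | None = None  # only for images whose truth label is tumor


@dataclass
class PipelineResult:
    records: list[ImageRecord]
    report: evaluation.EvalReport | None = None
    counts: evaluation.ConfusionCounts | None = None


def segment_image(img: np.ndarray, cfg: dict):
    """Enhance one image and extract its tumor candidate.

    Returns ``(enhanced, mask, candidate)``; ``candidate`` is ``None`` when
    no component survives the minimum-area filter or the image admits no
    valid intensity split.
    """
    pp = cfg["preprocess"]
    sg = cfg["segment"]
    enhanced = preprocess.ahcn_equalize(
        img,
        grid_rows=pp["grid_rows"],
        grid_cols=pp["grid_cols"],
        clip_norm=pp["clip_norm"],
        n_levels=pp["n_levels"],
    )
    n = pp["n_levels"]
    source = enhanced if sg.get("source", "original") == "enhanced" else np.asarray(img)
    max_frac = sg.get("max_region_fraction", 0.2)
    budget = max_frac * source.size
    mask = None
    current = np.ones_like(source, dtype=bool)
    for _ in range(8):  # each split strictly shrinks the foreground
        try:
            stats = segment.otsu_threshold(
                preprocess.compute_histogram(source[current], n=n)
            )
        except NoValidSplitError:
            break
        fg = (segment.apply_threshold(source, stats.threshold, sg["polarity"]) > 0) & current
        if not fg.any():
            break
        mask = fg
        if fg.sum() <= budget:
            break
        current = fg
    if mask is None:
        return enhanced, np.zeros_like(img, dtype=np.uint8), None
    mask = mask.astype(np.uint8)
    if sg["opening"]:
        mask = segment.binary_opening(mask)
    candidate = segment.extract_tumor_candidate(mask, min_area=sg["min_area"])
    return enhanced, mask, candidate


def build_feature_table(samples: list[PhantomSample], cfg: dict):
    """Run enhancement + segmentation over labeled samples and collect the
    feature vectors of every image that yields a candidate.

    Returns ``(vectors, labels)``; images without a candidate contribute no
    row (there is no region to describe).
    """
    vectors, labels = [], []
    for sample in samples:
        enhanced, _, candidate = segment_image(sample.image, cfg)
        if candidate is None:
            continue
        vectors.append(features.extract_region_features(enhanced, candidate))
        labels.append(sample.label)
    return vectors, labels


def train_codebook(samples: list[PhantomSample], cfg: dict) -> lvq.Codebook:
    """Fit feature ranges and an LVQ codebook from a labeled cohort."""
    vectors, labels = build_feature_table(samples, cfg)
    if not vectors:
        raise ConfigurationError("no image in the training cohort yields a candidate")
    ranges = features.fit_ranges(vectors)
    X = np.stack([features.normalize(v, ranges).values for v in vectors])
    tc = cfg["lnq"]
    codebook = lvq.train(
        X,
        np.asarray(labels),
        lvq.TrainConfig(
            seed=cfg["seed"],
            learning_rate=tc["learning_rate"],
            epochs=tc["epochs"],
            clusters_per_class=tc["clusters_per_class"],
        ),
    )
    codebook.ranges = ranges
    if tc["beta"] is not None:
        codebook, _ = lvq.quantize_codebook(codebook, lvq.QuantizationSpec(tc["beta"]))
    return codebook


def run_pipeline(
    samples: list[PhantomSample],
    cfg: dict,
    codebook: lvq.Codebook,
    with_truth: bool = True,
) -> PipelineResult:
    """Classify every sample; when truth is available, score the cohort.

    The predicted mask used for Dice is the candidate component when the
    predicted label is tumor, else empty; Dice is reported for images whose
    ground-truth label is tumor.
    """
    if codebook.ranges is None:
        raise ConfigurationError("codebook carries no feature ranges")
    if tuple(codebook.ranges.names) != features.FEATURE_NAMES:
        raise ConfigurationError(
            "codebook feature schema does not match the extractor"
        )
    records: list[ImageRecord] = []
    for i, sample in enumerate(samples):
        enhanced, _, candidate = segment_image(sample.image, cfg)
        if candidate is None:
            rec = ImageRecord(
                index=i, label=NO_TUMOR, similarity=0.0,
                candidate=None, feature_values=None,
            )
        else:
            fv = features.extract_region_features(enhanced, candidate)
            norm = features.normalize(fv, codebook.ranges)
            res = lvq.classify(norm.values, codebook)
            rec = ImageRecord(
                index=i, label=res.label, similarity=res.similarity,
                candidate=candidate, feature_values=fv.values,
            )
        if with_truth and sample.label == TUMOR:
            pred_mask = (
                rec.candidate.mask
                if (rec.label == TUMOR and rec.candidate is not None)
                else np.zeros_like(sample.mask)
            )
            rec.dice = evaluation.dice(pred_mask, sample.mask)
        records.append(rec)

    result = PipelineResult(records=records)
    if with_truth:
        y_true = [s.label for s in samples]
        y_pred = [r.label for r in records]
        counts = evaluation.ConfusionCounts.from_labels(y_true, y_pred, positive=TUMOR)
        dices = [r.dice for r in records if r.dice is not None]
        result.counts = counts
        result.report = evaluation.EvalReport(
            accuracy=evaluation.accuracy(counts),
            precision=(
                evaluation.precision(counts) if counts.tp + counts.fp > 0 else None
            ),
            specificity=(
                evaluation.specificity(counts) if counts.tn + counts.fp > 0 else None
            ),
            dice=float(np.mean(dices)) if dices else None,
        )
    return result
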