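"""Learning-vector-quantization classifier with a max-min similarity, plus
bit-width weight quantization and SQNR accounting.

The classifier keeps, per class, a small set of reference ("codebook")
vectors on the unit hypercube.  A query is matched to a reference by the
fuzzy max-min ratio

    S(x, w) = sum_i min(x_i, w_i) / sum_i max(x_i, w_i)

which lies in [0, 1], is symmetric, and equals 1 exactly when x == w.  The
predicted class is the one whose best reference attains the global maximum
similarity.  Training is LVQ1: the winning reference moves toward a sample
of its own class and away from a sample of another class, with a linearly
decaying learning rate, clamped to [0, 1] so the similarity contract stays
valid.

Reference weights can be quantized to beta bits with a uniform mid-rise
quantizer on [0, 1]; the resulting signal-to-quantization-noise ratio grows
close to linearly in beta (about 6 dB per bit for uniformly distributed
weights), and the slope kappa is estimated by a straight-line fit rather
than assumed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigurationError,
    DataError,
    SchemaError,
    UndefinedSimilarityError,
)
from .features import FeatureRanges

__all__ = [
    "Codebook",
    "TrainConfig",
    "QuantizationSpec",
    "QuantizationReport",
    "ClassificationResult",
    "maxmin_similarity",
    "classify",
    "train",
    "quantize_weights",
    "quantize_codebook",
    "measure_sqnr",
    "sqnr_vs_beta",
]


@dataclass
class Codebook:
    """Per-class clusters of reference vectors on [0, 1]^d."""

    classes: tuple[str, ...]
    clusters: dict[str, np.ndarray]  # class -> (n_clusters, d)
    d: int
    ranges: FeatureRanges | None = None
    beta: int | None = None  # bit-width the weights were quantized to, if any

    def __post_init__(self) -> None:
        if not self.classes:
            raise ConfigurationError("codebook needs at least one class")
        for cls in self.classes:
            w = np.asarray(self.clusters[cls], dtype=np.float64)
            if w.ndim != 2 or w.shape[1] != self.d or w.shape[0] < 1:
                raise ConfigurationError(
                    f"class {cls!r} clusters must be (k, {self.d}), got {w.shape}"
                )
            if w.min() < 0 or w.max() > 1:
                raise ConfigurationError("reference values must lie in [0, 1]")
            self.clusters[cls] = w

    def stacked(self):
        """All references as one array plus a parallel class-label array."""
        refs = np.concatenate([self.clusters[c] for c in self.classes])
        labels = np.concatenate(
            [np.repeat(c, len(self.clusters[c])) for c in self.classes]
        )
        return refs, labels

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "d": self.d,
            "clusters": {c: self.clusters[c].tolist() for c in self.classes},
            "ranges": self.ranges.to_dict() if self.ranges is not None else None,
            "quantization": {"beta": self.beta},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "Codebook":
        ranges = d.get("ranges")
        return cls(
            classes=tuple(d["classes"]),
            clusters={
                c: np.asarray(v, dtype=np.float64) for c, v in d["clusters"].items()
            },
            d=int(d["d"]),
            ranges=FeatureRanges.from_dict(ranges) if ranges else None,
            beta=(d.get("quantization") or {}).get("beta"),
        )

    @classmethod
    def from_json(cls, text: str) -> "Codebook":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class TrainConfig:
    seed: int
    learning_rate: float = 0.1
    epochs: int = 50
    clusters_per_class: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.learning_rate < 1.0:
            raise ConfigurationError(
                f"learning_rate must be in (0, 1), got {self.learning_rate}"
            )
        if self.epochs < 0 or self.clusters_per_class < 1:
            raise ConfigurationError("epochs must be >= 0 and clusters_per_class >= 1")


@dataclass(frozen=True)
class QuantizationSpec:
    beta: int
    domain: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ConfigurationError(f"bit-width beta must be >= 1, got {self.beta}")


@dataclass(frozen=True)
class QuantizationReport:
    """SQNR bookkeeping for one or several bit-widths.

    ``kappa`` is the fitted dB-per-bit efficiency: the least-squares slope
    of SQNR against beta when several bit-widths were measured, else the
    single-point ratio SQNR / beta.
    """

    betas: tuple[int, ...]
    sqnr_db: tuple[float, ...]
    noise_power: tuple[float, ...]
    signal_power: float
    kappa: float
    noise: np.ndarray | None = field(default=None, repr=False)  # w_tilde - w at betas[-1]


@dataclass(frozen=True)
class ClassificationResult:
    label: str
    similarity: float
    per_class: dict[str, float]


def maxmin_similarity(x: np.ndarray, w: np.ndarray) -> float:
    """Fuzzy max-min similarity sum(min)/sum(max) on [0, 1]^d."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if x.shape != w.shape or x.ndim != 1 or x.size < 1:
        raise SchemaError(f"vector shapes differ: {x.shape} vs {w.shape}")
    if x.min() < 0 or w.min() < 0 or x.max() > 1 or w.max() > 1:
        raise SchemaError("similarity requires components in [0, 1]")
    denom = np.maximum(x, w).sum()
    if denom == 0.0:
        raise UndefinedSimilarityError("similarity of two all-zero vectors is undefined")
    return float(np.minimum(x, w).sum() / denom)


def _similarity_to_refs(x: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """Vectorized sum(min)/sum(max) of one query against many references.

    Two identical all-zero vectors score 1.0 here (they are equal); the
    public :func:`maxmin_similarity` treats that case as an error instead.
    """
    num = np.minimum(x[None, :], refs).sum(axis=1)
    den = np.maximum(x[None, :], refs).sum(axis=1)
    return np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)


def classify(values: np.ndarray, cb: Codebook) -> ClassificationResult:
    """Predict the class whose best reference is most similar to the query.

    Per class the similarity is the maximum over that class's cluster
    vectors; the returned label attains the global maximum, ties broken by
    codebook class order.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1 or x.size != cb.d:
        raise SchemaError(f"query has shape {x.shape}, codebook expects d={cb.d}")
    if x.min() < 0 or x.max() > 1:
        raise SchemaError("query must be normalized to [0, 1]")
    per_class: dict[str, float] = {}
    for cls in cb.classes:
        per_class[cls] = float(_similarity_to_refs(x, cb.clusters[cls]).max())
    best = max(cb.classes, key=lambda c: per_class[c])  # max is stable: first wins ties
    return ClassificationResult(label=best, similarity=per_class[best], per_class=per_class)


def train(
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    history: list[float] | None = None,
) -> Codebook:
    """LVQ1 training on normalized feature vectors.

    The codebook is initialized from class-stratified samples drawn with the
    config seed.  Each epoch visits the samples in a fresh seeded shuffle;
    the globally most similar reference moves toward the sample when its
    class matches (``w += alpha * (x - w)``) and away otherwise, with
    ``alpha = learning_rate * (1 - epoch / epochs)``, then is clamped to
    [0, 1].  Same data + same seed => identical codebook.

    When ``history`` is a list, the tracked loss ``1 - mean(best similarity
    to the true class)`` is appended after every epoch.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0] or X.shape[0] < 1:
        raise SchemaError(f"X {X.shape} and y {y.shape} do not align")
    if X.min() < 0 or X.max() > 1:
        raise SchemaError("training vectors must be normalized to [0, 1]")
    classes = tuple(dict.fromkeys(str(c) for c in y))  # order of first appearance
    rng = np.random.default_rng(cfg.seed)

    clusters: dict[str, np.ndarray] = {}
    for cls in classes:
        idx = np.flatnonzero(y.astype(str) == cls)
        if idx.size == 0:
            raise DataError(f"class {cls!r} has no training samples")
        pick = rng.choice(idx, size=cfg.clusters_per_class, replace=idx.size < cfg.clusters_per_class)
        clusters[cls] = X[pick].copy()

    refs = np.concatenate([clusters[c] for c in classes])
    ref_class = np.concatenate(
        [np.repeat(c, cfg.clusters_per_class) for c in classes]
    )
    y_str = y.astype(str)
    for epoch in range(cfg.epochs):
        alpha = cfg.learning_rate * (1.0 - epoch / cfg.epochs)
        if alpha <= 0:
            break
        for i in rng.permutation(X.shape[0]):
            x = X[i]
            sims = _similarity_to_refs(x, refs)
            win = int(np.argmax(sims))
            sign = 1.0 if ref_class[win] == y_str[i] else -1.0
            refs[win] += sign * alpha * (x - refs[win])
            np.clip(refs[win], 0.0, 1.0, out=refs[win])
        if history is not None:
            s_correct = [
                _similarity_to_refs(X[i], refs[ref_class == y_str[i]]).max()
                for i in range(X.shape[0])
            ]
            history.append(float(1.0 - np.mean(s_correct)))

    k = cfg.clusters_per_class
    out = {cls: refs[j * k: (j + 1) * k].copy() for j, cls in enumerate(classes)}
    return Codebook(classes=classes, clusters=out, d=X.shape[1])


def quantize_weights(w: np.ndarray, beta: int) -> np.ndarray:
    """Uniform mid-rise quantizer with 2**beta levels on [0, 1].

    Reconstruction points are ``(k + 0.5) / 2**beta``; a weight already on a
    reconstruction point is returned unchanged.
    """
    if beta < 1:
        raise ConfigurationError(f"bit-width beta must be >= 1, got {beta}")
    w = np.asarray(w, dtype=np.float64)
    scale = float(2**beta)
    # cell index clipped into [0, 2^beta - 1] so w = 1 lands in the top cell
    k = np.clip(np.floor(w * scale), 0, scale - 1)
    return (k + 0.5) / scale


def quantize_codebook(cb: Codebook, spec: QuantizationSpec):
    """Quantize every reference weight; returns the new codebook and a report.

    The report records the per-weight error ``n_w = w_tilde - w`` and the
    signal/noise powers whose ratio (in dB) is the SQNR.
    """
    refs, _ = cb.stacked()
    flat = refs.ravel()
    qflat = quantize_weights(flat, spec.beta)
    noise = qflat - flat
    signal_power = float(np.mean(flat**2))
    noise_power = float(np.mean(noise**2))
    sqnr = measure_sqnr(flat, qflat)
    new_clusters = {
        cls: quantize_weights(cb.clusters[cls], spec.beta) for cls in cb.classes
    }
    qcb = Codebook(
        classes=cb.classes,
        clusters=new_clusters,
        d=cb.d,
        ranges=cb.ranges,
        beta=spec.beta,
    )
    report = QuantizationReport(
        betas=(spec.beta,),
        sqnr_db=(sqnr,),
        noise_power=(noise_power,),
        signal_power=signal_power,
        kappa=sqnr / spec.beta if np.isfinite(sqnr) else float("inf"),
        noise=noise,
    )
    return qcb, report


def measure_sqnr(weights: np.ndarray, quantized: np.ndarray) -> float:
    """Signal-to-quantization-noise ratio in dB.

    ``10 * log10(mean(w^2) / mean((w_tilde - w)^2))``; zero noise power is
    reported as ``inf`` (a signal, not an exception).
    """
    w = np.asarray(weights, dtype=np.float64)
    q = np.asarray(quantized, dtype=np.float64)
    if w.shape != q.shape or w.size < 1:
        raise SchemaError(f"shapes differ: {w.shape} vs {q.shape}")
    noise_power = float(np.mean((q - w) ** 2))
    if noise_power == 0.0:
        return float("inf")
    return float(10.0 * np.log10(np.mean(w**2) / noise_power))


def sqnr_vs_beta(weights: np.ndarray, betas) -> QuantizationReport:
    """Measure SQNR across bit-widths and fit the dB-per-bit slope kappa."""
    w = np.asarray(weights, dtype=np.float64).ravel()
    betas = tuple(int(b) for b in betas)
    if len(betas) < 1:
        raise ConfigurationError("need at least one bit-width")
    sqnrs, powers = [], []
    noise = None
    for b in betas:
        q = quantize_weights(w, b)
        noise = q - w
        powers.append(float(np.mean(noise**2)))
        sqnrs.append(measure_sqnr(w, q))
    if len(betas) >= 2:
        kappa = float(np.polyfit(betas, sqnrs, 1)[0])
    else:
        kappa = sqnrs[0] / betas[0]
    return QuantizationReport(
        betas=betas,
        sqnr_db=tuple(sqnrs),
        noise_power=tuple(powers),
        signal_power=float(np.mean(w**2)),
        kappa=kappa,
        noise=noise,
    )
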