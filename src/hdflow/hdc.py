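"""Binary hyperdimensional computing: encoding, bundling, Hamming classification.

A sample is represented by a binary hypervector of dimension ``D``.  Each
class prototype is the bitwise majority vote over the hypervectors of its
training samples (bundling); a query is assigned to the class whose
prototype lies at minimum Hamming distance.  Training is a single pass with
no iterative optimisation, so a model is a pure function of the training
set, the encoder configuration and the tie-break seed.

Encoding here is structural rather than arithmetic: the feature vector
produced by the event-frame preprocessing is already binary (presence or
absence of events per region), so the encoder either passes it through
unchanged (``identity``) or selects a fixed seeded subset of ``D`` of its
positions (``subsample``), e.g. D = 10,000 out of a 640x480x2 feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .events import FeatureVector
from .exceptions import (
    ArgumentError,
    ConfigError,
    DimensionError,
    TrainingError,
)


@dataclass(frozen=True)
class EncoderConfig:
    """How a flat binary feature maps to a hypervector.

    ``identity`` requires ``D`` to equal the feature length; ``subsample``
    keeps the feature bits at the first ``D`` positions of a seeded
    permutation of the indices, fixed for the life of a model.
    """

    D: int
    mode: str = "identity"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ConfigError("hypervector dimension D must be positive")
        if self.mode not in ("identity", "subsample"):
            raise ConfigError(f"unknown encoder mode {self.mode!r}")


@dataclass
class Hypervector:
    """A binary vector of fixed dimension D (stored as uint8 bits)."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.ascontiguousarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1:
            raise ArgumentError("hypervector bits must be one-dimensional")
        if self.bits.size and self.bits.max() > 1:
            raise ArgumentError("hypervector bits must be 0 or 1")

    @property
    def dim(self) -> int:
        return int(self.bits.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypervector):
            return NotImplemented
        return np.array_equal(self.bits, other.bits)


@dataclass
class ClassPrototype:
    """Majority-bundled hypervector for one class plus its sample count."""

    label: str
    hv: Hypervector
    n_samples: int


@dataclass
class ClassifierModel:
    """Encoder configuration plus one prototype per class."""

    encoder: EncoderConfig
    prototypes: list[ClassPrototype]
    tie_seed: int = 0

    def __post_init__(self) -> None:
        labels = [p.label for p in self.prototypes]
        if len(set(labels)) != len(labels):
            raise ConfigError("prototype labels must be unique")
        dims = {p.hv.dim for p in self.prototypes}
        if len(dims) > 1:
            raise DimensionError("prototypes must share dimension D")

    @property
    def labels(self) -> list[str]:
        return sorted(p.label for p in self.prototypes)

    @property
    def D(self) -> int:
        return self.encoder.D


@lru_cache(maxsize=64)
def _subsample_indices(D: int, seed: int, feature_length: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.permutation(feature_length)[:D]


def _tie_vector(D: int, tie_seed: int) -> np.ndarray:
    """The single tie-break hypervector, drawn once from ``tie_seed``."""
    return np.random.default_rng(tie_seed).integers(0, 2, size=D, dtype=np.uint8)


def _encode_matrix(X: np.ndarray, cfg: EncoderConfig) -> np.ndarray:
    if cfg.mode == "identity":
        if cfg.D != X.shape[1]:
            raise ConfigError(
                f"identity encoder needs D == feature length ({X.shape[1]}), got D={cfg.D}"
            )
        return X
    if cfg.D > X.shape[1]:
        raise ConfigError(
            f"subsample encoder needs D <= feature length ({X.shape[1]}), got D={cfg.D}"
        )
    idx = _subsample_indices(cfg.D, cfg.seed, X.shape[1])
    return X[:, idx]


def encode(feature: FeatureVector, cfg: EncoderConfig) -> Hypervector:
    """Map a binary feature vector to a hypervector per ``cfg``."""
    out = _encode_matrix(feature.bits[None, :], cfg)[0]
    return Hypervector(out.copy())


def bundle_majority(hvs: Sequence[Hypervector], tie_seed: int = 0) -> Hypervector:
    """Bitwise majority vote over a non-empty list of hypervectors.

    A position with an exact tie (even list length) takes its bit from a
    tie-break vector generated once from ``tie_seed``, keeping bundling
    deterministic and independent of list order.
    """
    if len(hvs) == 0:
        raise ArgumentError("cannot bundle an empty list of hypervectors")
    dims = {hv.dim for hv in hvs}
    if len(dims) != 1:
        raise DimensionError(f"ragged hypervector dimensions: {sorted(dims)}")
    M = np.stack([hv.bits for hv in hvs])
    return Hypervector(_majority_from_counts(M.sum(axis=0, dtype=np.int64), M.shape[0], tie_seed))


def _majority_from_counts(ones: np.ndarray, n: int, tie_seed: int) -> np.ndarray:
    out = (2 * ones > n).astype(np.uint8)
    ties = 2 * ones == n
    if ties.any():
        out[ties] = _tie_vector(ones.size, tie_seed)[ties]
    return out


def hamming(a: Hypervector, b: Hypervector) -> int:
    """Number of positions at which two hypervectors differ."""
    if a.dim != b.dim:
        raise DimensionError(f"dimension mismatch: {a.dim} vs {b.dim}")
    return int(np.count_nonzero(a.bits != b.bits))


def train_matrix(
    X: np.ndarray,
    labels: Sequence[str],
    cfg: EncoderConfig,
    tie_seed: int = 0,
    classes: Iterable[str] | None = None,
) -> ClassifierModel:
    """Vectorised single-pass training from a (n_samples, length) bit matrix."""
    X = np.ascontiguousarray(X, dtype=np.uint8)
    labels = np.asarray(labels)
    if X.shape[0] != labels.size:
        raise ArgumentError("feature matrix and label list disagree in length")
    if X.shape[0] == 0:
        raise TrainingError("cannot train on an empty sample list")
    declared = sorted(set(labels)) if classes is None else sorted(classes)
    Xe = _encode_matrix(X, cfg)
    prototypes = []
    for lab in declared:
        rows = Xe[labels == lab]
        if rows.shape[0] == 0:
            raise TrainingError(f"class {lab!r} has zero training samples")
        bits = _majority_from_counts(rows.sum(axis=0, dtype=np.int64), rows.shape[0], tie_seed)
        prototypes.append(ClassPrototype(str(lab), Hypervector(bits), rows.shape[0]))
    return ClassifierModel(cfg, prototypes, tie_seed)


def train(
    samples: Sequence[tuple[FeatureVector, str]],
    cfg: EncoderConfig,
    tie_seed: int = 0,
    classes: Iterable[str] | None = None,
) -> ClassifierModel:
    """Train one majority-vote prototype per class in a single pass."""
    if len(samples) == 0:
        raise TrainingError("cannot train on an empty sample list")
    lengths = {len(f) for f, _ in samples}
    if len(lengths) != 1:
        raise DimensionError(f"features have ragged lengths: {sorted(lengths)}")
    X = np.stack([f.bits for f, _ in samples])
    labels = [lab for _, lab in samples]
    return train_matrix(X, labels, cfg, tie_seed, classes)


def classify_matrix(model: ClassifierModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classify a (n, length) bit matrix; returns (predicted labels, distances).

    Distance columns follow ``model.labels`` (sorted); ties go to the
    lexicographically smallest label.
    """
    Xe = _encode_matrix(np.ascontiguousarray(X, dtype=np.uint8), model.encoder)
    labs = model.labels
    protos = {p.label: p.hv.bits for p in model.prototypes}
    dists = np.empty((Xe.shape[0], len(labs)), dtype=np.int64)
    for j, lab in enumerate(labs):
        dists[:, j] = np.count_nonzero(Xe != protos[lab][None, :], axis=1)
    pred_idx = np.argmin(dists, axis=1)  # first minimum == smallest label
    preds = np.asarray(labs, dtype=object)[pred_idx]
    return preds, dists


def classify(model: ClassifierModel, feature: FeatureVector) -> tuple[str, dict[str, int]]:
    """Assign ``feature`` to the nearest prototype by Hamming distance."""
    preds, dists = classify_matrix(model, feature.bits[None, :])
    table = {lab: int(d) for lab, d in zip(model.labels, dists[0])}
    return str(preds[0]), table


# ---------------------------------------------------------------------------
# Model persistence (packed-bit container)
# ---------------------------------------------------------------------------


def save_model(model: ClassifierModel, path) -> None:
    """Serialise a model to an ``.npz`` container with bit-packed prototypes."""
    bits = np.stack([p.hv.bits for p in model.prototypes])
    np.savez_compressed(
        Path(path),
        D=model.encoder.D,
        mode=model.encoder.mode,
        encoder_seed=model.encoder.seed,
        tie_seed=model.tie_seed,
        labels=np.asarray([p.label for p in model.prototypes], dtype="U64"),
        n_samples=np.asarray([p.n_samples for p in model.prototypes], dtype=np.int64),
        packed=np.packbits(bits, axis=1),
    )


def load_model(path) -> ClassifierModel:
    """Inverse of :func:`save_model`."""
    with np.load(Path(path), allow_pickle=False) as f:
        D = int(f["D"])
        cfg = EncoderConfig(D=D, mode=str(f["mode"]), seed=int(f["encoder_seed"]))
        tie_seed = int(f["tie_seed"])
        labels = [str(s) for s in f["labels"]]
        n_samples = f["n_samples"]
        bits = np.unpackbits(f["packed"], axis=1, count=D)
    prototypes = [
        ClassPrototype(lab, Hypervector(bits[i]), int(n_samples[i]))
        for i, lab in enumerate(labels)
    ]
    return ClassifierModel(cfg, prototypes, tie_seed)
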