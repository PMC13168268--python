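"""Session-aware evaluation: splits, confusion matrices, ablations, sweeps.

Flow-cytometry acquisitions drift between measurement sessions (source
intensity, beam alignment, refractive-index changes).  When every class is
recorded in its own session, that drift is correlated with the labels and a
classifier can exploit it -- measurement bias.  The two protocols here make
the distinction explicit:

* ``single_session``: train and test within one session of each class
  (optimistic; shares any session signature between train and test);
* ``intertwined``: train on some sessions and test on disjoint held-out
  sessions, so the session signature cannot leak into the test labels.

Samples are stored as binarized polarity maps at sensor resolution; the
down-sampling factor and polarity handling are a :class:`FeatureConfig`, so
ablations and feature-dimension sweeps re-derive features from the same
dataset without re-simulating or re-reading events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from . import events as ev
from . import hdc
from .exceptions import ArgumentError, EvaluationError, SplitError


@dataclass
class Sample:
    """One labelled transit: binary polarity maps plus provenance tags."""

    label: str
    session: int
    sample_id: int
    pos: np.ndarray
    neg: np.ndarray


@dataclass
class SessionDataset:
    """Labelled samples tagged with (class, session, sample) identity."""

    samples: list[Sample]
    sensor_width: int
    sensor_height: int

    def __post_init__(self) -> None:
        keys = [(s.label, s.session, s.sample_id) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ArgumentError("(class, session, sample) triples must be unique")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def classes(self) -> list[str]:
        return sorted({s.label for s in self.samples})

    @property
    def sessions_per_class(self) -> dict[str, set[int]]:
        out: dict[str, set[int]] = {}
        for s in self.samples:
            out.setdefault(s.label, set()).add(s.session)
        return out

    @property
    def sessions(self) -> list[int]:
        """Sessions present for every class (usable for session-aware splits)."""
        per = self.sessions_per_class
        common = set.intersection(*per.values()) if per else set()
        return sorted(common)


@dataclass(frozen=True)
class SplitSpec:
    """How to divide a :class:`SessionDataset` into train and test sets."""

    mode: str  # "single_session" | "intertwined"
    session: int | None = None
    train_fraction: float = 5 / 6
    train_sessions: frozenset[int] | None = None
    test_sessions: frozenset[int] | None = None
    seed: int = 0


@dataclass(frozen=True)
class FeatureConfig:
    """Feature recipe: down-sampling block, polarity handling, pooling mode."""

    block: tuple[int, int] = (1, 1)
    polarity_mode: str = "split"
    pool: str = "block"


@dataclass
class ConfusionMatrix:
    """counts[i][j] = number of samples of true class i predicted as j."""

    labels: list[str]
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


def split_single_session(
    ds: SessionDataset, spec: SplitSpec
) -> tuple[list[Sample], list[Sample]]:
    """Per class, shuffle the named session's samples and cut at train_fraction."""
    if spec.mode != "single_session":
        raise SplitError(f"spec mode {spec.mode!r} is not 'single_session'")
    if spec.session is None:
        raise SplitError("single_session split needs a session id")
    if not 0 < spec.train_fraction < 1:
        raise SplitError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(spec.seed)
    train: list[Sample] = []
    test: list[Sample] = []
    for lab in ds.classes:
        pool = [
            s for s in ds.samples if s.label == lab and s.session == spec.session
        ]
        if not pool:
            raise SplitError(f"class {lab!r} has no samples in session {spec.session}")
        order = rng.permutation(len(pool))
        cut = int(np.floor(spec.train_fraction * len(pool)))
        train.extend(pool[i] for i in order[:cut])
        test.extend(pool[i] for i in order[cut:])
    return train, test


def split_intertwined(
    ds: SessionDataset, spec: SplitSpec
) -> tuple[list[Sample], list[Sample]]:
    """Train on one session set, test on a disjoint session set."""
    if spec.mode != "intertwined":
        raise SplitError(f"spec mode {spec.mode!r} is not 'intertwined'")
    tr, te = spec.train_sessions, spec.test_sessions
    if not tr or not te:
        raise SplitError("intertwined split needs non-empty train and test session sets")
    if set(tr) & set(te):
        raise SplitError(f"train/test session sets overlap: {sorted(set(tr) & set(te))}")
    per = ds.sessions_per_class
    for lab in ds.classes:
        missing = (set(tr) | set(te)) - per[lab]
        if missing:
            raise SplitError(f"class {lab!r} is missing sessions {sorted(missing)}")
    train = [s for s in ds.samples if s.session in tr]
    test = [s for s in ds.samples if s.session in te]
    return train, test


def split(ds: SessionDataset, spec: SplitSpec) -> tuple[list[Sample], list[Sample]]:
    if spec.mode == "single_session":
        return split_single_session(ds, spec)
    if spec.mode == "intertwined":
        return split_intertwined(ds, spec)
    raise SplitError(f"unknown split mode {spec.mode!r}")


# ---------------------------------------------------------------------------
# Feature extraction (batch) and train/evaluate
# ---------------------------------------------------------------------------


def feature_matrix(
    samples: Sequence[Sample], fc: FeatureConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into a (n, length) uint8 bit matrix plus label array."""
    if len(samples) == 0:
        raise ArgumentError("no samples to featurise")
    pos = np.stack([s.pos for s in samples])
    neg = np.stack([s.neg for s in samples])
    if fc.pool == "block":
        pos = ev._downsample_or_batch(pos, fc.block)
        neg = ev._downsample_or_batch(neg, fc.block)
    else:
        bh, bw = fc.block
        pos = pos[:, ::bh, ::bw]
        neg = neg[:, ::bh, ::bw]
    n = pos.shape[0]
    if fc.polarity_mode == "split":
        X = np.concatenate([pos.reshape(n, -1), neg.reshape(n, -1)], axis=1)
    elif fc.polarity_mode == "merged":
        X = (pos | neg).reshape(n, -1)
    else:
        raise ArgumentError(f"unknown polarity_mode {fc.polarity_mode!r}")
    labels = np.asarray([s.label for s in samples], dtype=object)
    return X.astype(np.uint8), labels


def feature_of(sample: Sample, fc: FeatureConfig) -> ev.FeatureVector:
    """Single-sample feature via the same path as :func:`feature_matrix`."""
    X, _ = feature_matrix([sample], fc)
    return ev.FeatureVector(X[0], fc.polarity_mode)


def fit(
    train_samples: Sequence[Sample],
    fc: FeatureConfig,
    tie_seed: int = 0,
    encoder: hdc.EncoderConfig | None = None,
) -> hdc.ClassifierModel:
    """Train a majority-vote prototype model on the given samples."""
    X, labels = feature_matrix(train_samples, fc)
    cfg = encoder if encoder is not None else hdc.EncoderConfig(D=X.shape[1])
    return hdc.train_matrix(X, labels, cfg, tie_seed)


def evaluate(
    model: hdc.ClassifierModel, test_samples: Sequence[Sample], fc: FeatureConfig
) -> ConfusionMatrix:
    """Classify every test sample and tabulate the confusion matrix."""
    X, labels = feature_matrix(test_samples, fc)
    unknown = sorted(set(labels) - set(model.labels))
    if unknown:
        raise EvaluationError(f"test set contains unknown classes {unknown}")
    preds, _ = hdc.classify_matrix(model, X)
    counts = _sk_confusion(labels.astype(str), preds.astype(str), labels=model.labels)
    return ConfusionMatrix(list(model.labels), counts.astype(np.int64))


def accuracy(cm: ConfusionMatrix) -> float:
    """Micro-averaged accuracy: trace over total count."""
    if cm.total == 0:
        raise ArgumentError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def train_test_accuracy(
    train_samples: Sequence[Sample],
    test_samples: Sequence[Sample],
    fc: FeatureConfig,
    tie_seed: int = 0,
    encoder: hdc.EncoderConfig | None = None,
) -> tuple[ConfusionMatrix, float]:
    model = fit(train_samples, fc, tie_seed, encoder)
    cm = evaluate(model, test_samples, fc)
    return cm, accuracy(cm)


# ---------------------------------------------------------------------------
# Protocol-level runs
# ---------------------------------------------------------------------------


def leave_one_session_out(
    ds: SessionDataset,
    fc: FeatureConfig,
    tie_seed: int = 0,
    encoder: hdc.EncoderConfig | None = None,
) -> tuple[float, pd.DataFrame]:
    """Intertwined protocol: hold out each session in turn, average accuracy."""
    sessions = ds.sessions
    if len(sessions) < 2:
        raise SplitError("leave-one-session-out needs at least two common sessions")
    rows = []
    for held in sessions:
        spec = SplitSpec(
            mode="intertwined",
            train_sessions=frozenset(s for s in sessions if s != held),
            test_sessions=frozenset({held}),
        )
        tr, te = split_intertwined(ds, spec)
        _, acc = train_test_accuracy(tr, te, fc, tie_seed, encoder)
        rows.append({"held_out_session": held, "accuracy": acc})
    table = pd.DataFrame(rows)
    return float(table["accuracy"].mean()), table


def single_session_accuracy(
    ds: SessionDataset,
    fc: FeatureConfig,
    train_fraction: float = 5 / 6,
    tie_seed: int = 0,
    seed: int = 0,
    sessions: Iterable[int] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Single-session protocol, averaged over the requested sessions."""
    use = sorted(sessions) if sessions is not None else ds.sessions
    rows = []
    for sess in use:
        spec = SplitSpec(
            mode="single_session",
            session=sess,
            train_fraction=train_fraction,
            seed=seed + sess,
        )
        tr, te = split_single_session(ds, spec)
        _, acc = train_test_accuracy(tr, te, fc, tie_seed)
        rows.append({"session": sess, "accuracy": acc})
    table = pd.DataFrame(rows)
    return float(table["accuracy"].mean()), table


def run_polarity_ablation(
    ds: SessionDataset,
    spec: SplitSpec,
    fc: FeatureConfig = FeatureConfig(),
    tie_seed: int = 0,
) -> tuple[float, float]:
    """Accuracy with polarity maps concatenated vs merged, same split/seeds."""
    tr, te = split(ds, spec)
    _, acc_split = train_test_accuracy(
        tr, te, replace(fc, polarity_mode="split"), tie_seed
    )
    _, acc_merged = train_test_accuracy(
        tr, te, replace(fc, polarity_mode="merged"), tie_seed
    )
    return acc_split, acc_merged


def sweep_feature_dims(
    ds: SessionDataset,
    block_sizes: Sequence[tuple[int, int]],
    spec: SplitSpec,
    fc: FeatureConfig = FeatureConfig(),
    tie_seed: int = 0,
) -> pd.DataFrame:
    """Re-run the identical pipeline at several down-sampling factors.

    Returns one row per block size with the resulting map shape, feature
    length and accuracy.  The split is computed once and shared across rows
    so only the feature resolution varies.
    """
    for bh, bw in block_sizes:
        if bh < 1 or bw < 1:
            raise ArgumentError(f"invalid block ({bh}, {bw})")
    tr, te = split(ds, spec)
    rows = []
    for bh, bw in block_sizes:
        fci = replace(fc, block=(bh, bw))
        X, _ = feature_matrix(te[:1], fci)
        hp = -(-ds.sensor_height // bh)
        wp = -(-ds.sensor_width // bw)
        _, acc = train_test_accuracy(tr, te, fci, tie_seed)
        rows.append(
            {
                "block_h": bh,
                "block_w": bw,
                "map_width": wp,
                "map_height": hp,
                "n_features": int(X.shape[1]),
                "accuracy": acc,
            }
        )
    return pd.DataFrame(rows)
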