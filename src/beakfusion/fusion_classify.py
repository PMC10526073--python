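"""Vector-stacking feature fusion and multi-class RBF-SVM classification.

Fusion is plain concatenation, ``y = [x_shallow, x_deep]``: the fused
texture+deep vector is 59 + 2048 = 2107 long and the fused morphology+deep
vector (32-pixel cells) is 1764 + 2048 = 3812 long.  Classification uses a
radial-basis-function support vector machine with penalty ``C = 10``
decomposed one-vs-rest into one binary machine per class; features are
standardized (location/scale estimated on the training set only) before the
kernel, which matters when histogram-scale and activation-scale coordinates
are concatenated.  The margin quadratic program is delegated to
scikit-learn's libsvm wrapper; the contract here is the fusion/classification
pipeline, not a bespoke solver.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from beakfusion.errors import DegenerateLabelError, PairingError, ParameterError, ShapeError

TAGS = ("lbp", "hog", "deep", "fused")


@dataclass
class FeatureVector:
    """A fixed-length real descriptor with provenance."""

    values: np.ndarray
    tag: str
    source_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size == 0:
            raise ParameterError("feature vector must be non-empty")
        if not np.all(np.isfinite(v)):
            raise ParameterError(f"non-finite entries in feature {self.source_id!r}")
        if self.tag not in TAGS:
            raise ParameterError(f"tag must be one of {TAGS}, got {self.tag!r}")
        self.values = v

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SVMConfig:
    kernel: str = "rbf"
    C_penalty: float = 10.0
    decomposition: str = "one-vs-rest"
    gamma: float | str = "scale"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kernel != "rbf":
            raise ParameterError(f"only the rbf kernel is supported, got {self.kernel!r}")
        if self.C_penalty <= 0:
            raise ParameterError(f"C_penalty must be > 0, got {self.C_penalty}")
        if self.decomposition != "one-vs-rest":
            raise ParameterError("only one-vs-rest decomposition is supported")


def fuse(a: FeatureVector, b: FeatureVector) -> FeatureVector:
    """Stack two descriptors of the same image: ``[a.values, b.values]``."""
    if a.source_id != b.source_id:
        raise PairingError(
            f"cannot fuse features of different images: {a.source_id!r} vs {b.source_id!r}"
        )
    return FeatureVector(
        values=np.concatenate([a.values, b.values]), tag="fused", source_id=a.source_id
    )


class TrainedClassifier:
    """A fitted one-vs-rest SVM with its preprocessing and provenance."""

    def __init__(self, model: Pipeline | OneVsRestClassifier, classes: list[str], dim: int,
                 config: SVMConfig, tag: str):
        self.model = model
        self.classes = classes
        self.dim = dim
        self.config = config
        self.tag = tag

    @property
    def n_machines(self) -> int:
        ovr = self.model[-1] if isinstance(self.model, Pipeline) else self.model
        return len(ovr.estimators_)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        joblib.dump(self.model, path)
        meta = {
            "format_version": 1,
            "feature_tag": self.tag,
            "dim": self.dim,
            "classes": self.classes,
            "config": {
                "kernel": self.config.kernel,
                "C_penalty": self.config.C_penalty,
                "decomposition": self.config.decomposition,
                "gamma": self.config.gamma,
                "standardize": self.config.standardize,
            },
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        if meta.get("format_version") != 1:
            raise ParameterError(f"unsupported classifier format in {path}")
        model = joblib.load(path)
        cfg = SVMConfig(**meta["config"])
        return cls(model, meta["classes"], meta["dim"], cfg, meta["feature_tag"])


def _as_matrix(features: Sequence[FeatureVector | np.ndarray]) -> tuple[np.ndarray, str]:
    rows = []
    tag = "fused"
    for f in features:
        if isinstance(f, FeatureVector):
            rows.append(f.values)
            tag = f.tag
        else:
            rows.append(np.asarray(f, dtype=float).ravel())
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ShapeError(f"feature lengths differ: {sorted(lengths)}")
    x = np.vstack(rows)
    if not np.all(np.isfinite(x)):
        raise ParameterError("features contain non-finite values")
    return x, tag


def fit_classifier(
    features: Sequence[FeatureVector | np.ndarray],
    labels: Sequence[str],
    config: SVMConfig = SVMConfig(),
    seed: int = 0,
) -> TrainedClassifier:
    """Fit a one-vs-rest RBF-SVM (one binary machine per class).

    Ties between per-class decision values are broken by the lowest class
    index in sorted label order.  Deterministic given ``seed``.
    """
    if len(features) != len(labels):
        raise ShapeError("features and labels must have equal length")
    if len(features) == 0:
        raise DegenerateLabelError("cannot fit a classifier on an empty set")
    x, tag = _as_matrix(features)
    y = np.asarray([str(l) for l in labels])
    classes = sorted(set(y))
    if len(classes) < 2:
        raise DegenerateLabelError(f"need at least two classes, got {classes}")
    svc = SVC(
        kernel=config.kernel,
        C=config.C_penalty,
        gamma=config.gamma,
        random_state=seed,
    )
    ovr = OneVsRestClassifier(svc)
    if config.standardize:
        model: Pipeline | OneVsRestClassifier = Pipeline(
            [("scale", StandardScaler()), ("svm", ovr)]
        )
    else:
        model = ovr
    model.fit(x, y)
    return TrainedClassifier(model, classes, x.shape[1], config, tag)


def predict(clf: TrainedClassifier, features: Sequence[FeatureVector | np.ndarray]) -> list[str]:
    """Predict labels; every output belongs to the training label set."""
    if len(features) == 0:
        return []
    x, _ = _as_matrix(features)
    if x.shape[1] != clf.dim:
        raise ShapeError(f"feature length {x.shape[1]} != training length {clf.dim}")
    return [str(l) for l in clf.model.predict(x)]
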