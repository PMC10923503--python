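"""Time-series classifier zoo under a single train/evaluate contract.

Six architectures are available: five neural networks (``mlp``, ``cnn``,
``resnet``, ``fcn``, ``mcdcnn``) and a non-neural fallback
(``knn_fallback``, 1-nearest-neighbour on Euclidean distance between raw
segments).  The fallback is first-class: any model able to classify groups
of time series can stand in for the networks, and the 1-NN makes the full
pipeline deterministic, desk-scale and hardware-free.

``mlp`` is implemented but excluded from the default zoo, being consistently
weaker than the convolutional models on this task.  Registry order is also
the documented tie-break order for best-model selection.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from sklearn.neighbors import KNeighborsClassifier

from ..errors import ConfigurationError, DataError, LabelError
from .architectures import BUILDERS

#: all registered architectures, in tie-break order
REGISTRY_ORDER = ("fcn", "resnet", "cnn", "mcdcnn", "mlp", "knn_fallback")

#: the default zoo (mlp excluded)
DEFAULT_MODELS = ("fcn", "resnet", "cnn", "mcdcnn")

#: default training epochs per trainable architecture: the simple CNN needs
#: hundreds of epochs to saturate, the others saturate within tens.
DEFAULT_EPOCHS = {"cnn": 200, "resnet": 20, "fcn": 20, "mcdcnn": 20, "mlp": 20}


@dataclass(frozen=True)
class ModelSpec:
    """Recipe for one classifier.

    ``hyperparams`` overrides architecture defaults (layer widths, kernel
    sizes, learning rate ``lr``, ``batch_size``); unknown architectures are
    rejected at construction.
    """

    architecture: str
    input_length: int
    epochs: int | None = None
    seed: int = 0
    hyperparams: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.architecture not in REGISTRY_ORDER:
            raise ConfigurationError(
                f"architecture: unknown {self.architecture!r}; "
                f"choose from {REGISTRY_ORDER}"
            )
        if self.trainable and self.effective_epochs < 1:
            raise ConfigurationError("epochs: must be >= 1 for trainable models")

    @property
    def trainable(self) -> bool:
        return self.architecture != "knn_fallback"

    @property
    def effective_epochs(self) -> int:
        if self.epochs is not None:
            return self.epochs
        return DEFAULT_EPOCHS.get(self.architecture, 0)

    def with_seed(self, seed: int) -> "ModelSpec":
        return ModelSpec(
            self.architecture, self.input_length, self.epochs, seed, dict(self.hyperparams)
        )


def default_specs(
    input_length: int,
    models: tuple[str, ...] = DEFAULT_MODELS,
    seed: int = 0,
    hyperparams: dict[str, dict] | None = None,
) -> list[ModelSpec]:
    """Build one spec per requested architecture, in registry order."""
    hyperparams = hyperparams or {}
    ordered = [m for m in REGISTRY_ORDER if m in models]
    unknown = set(models) - set(REGISTRY_ORDER)
    if unknown:
        raise ConfigurationError(f"architecture: unknown {sorted(unknown)}")
    return [
        ModelSpec(m, input_length, seed=seed, hyperparams=hyperparams.get(m, {}))
        for m in ordered
    ]


@dataclass
class TrainedModel:
    """A fitted classifier plus the ordered class labels it was trained on."""

    spec: ModelSpec
    classes: tuple[str, str]
    _impl: Any

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Class indices (0 = classes[0]) for a batch of segments."""
        return np.asarray(self._impl.predict(x))

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        return path

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


class _SpectrumKNN:
    """1-NN on log band-averaged periodogram features.

    The summary-feature variant of the fallback: each segment is mapped to
    ``n_bands`` log-power bands of its periodogram before the Euclidean
    nearest-neighbour rule.  Far more sensitive than raw-segment distance to
    small spectral composition changes, at the price of discarding phase.
    """

    def __init__(self, n_neighbors: int = 1, n_bands: int = 48) -> None:
        self.knn = KNeighborsClassifier(n_neighbors=n_neighbors)
        self.n_bands = n_bands

    def _features(self, x: np.ndarray) -> np.ndarray:
        p = np.abs(np.fft.rfft(x, axis=1)) ** 2
        p = p[:, 1:]  # drop DC
        usable = p.shape[1] // self.n_bands * self.n_bands
        bands = p[:, :usable].reshape(x.shape[0], self.n_bands, -1).mean(axis=2)
        return np.log1p(bands)

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_SpectrumKNN":
        self.knn.fit(self._features(x), y)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.knn.predict(self._features(x))


def build_model(spec: ModelSpec) -> Any:
    """Instantiate an untrained model for a spec (parameters seeded)."""
    if spec.architecture == "knn_fallback":
        if spec.hyperparams.get("features", "raw") == "spectrum":
            return _SpectrumKNN(
                n_neighbors=spec.hyperparams.get("n_neighbors", 1),
                n_bands=spec.hyperparams.get("n_bands", 48),
            )
        return KNeighborsClassifier(n_neighbors=spec.hyperparams.get("n_neighbors", 1))
    net = BUILDERS[spec.architecture](spec.input_length, spec.hyperparams)
    net.init(spec.seed)
    return net


def train(
    model: Any,
    x: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    classes: tuple[str, str],
) -> TrainedModel:
    """Fit a model on a balanced training half.

    ``x`` is (n_segments, L), ``y`` integer class indices.  The 1-NN fallback
    is exactly deterministic; networks are deterministic given the seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.shape[0] == 0:
        raise DataError("empty training set")
    if x.shape[1] != spec.input_length:
        raise DataError(
            f"segment length {x.shape[1]} != spec.input_length {spec.input_length}"
        )
    if len(np.unique(y)) < 2:
        raise DataError("training set must contain both classes")
    if spec.architecture == "knn_fallback":
        model.fit(x, y)
    else:
        model.fit(
            x,
            y,
            epochs=spec.effective_epochs,
            batch_size=spec.hyperparams.get("batch_size", 16),
            lr=spec.hyperparams.get("lr", 1e-3),
        )
    return TrainedModel(spec=spec, classes=classes, _impl=model)


def evaluate(model: TrainedModel, x: np.ndarray, y: np.ndarray) -> float:
    """Accuracy: the fraction of correctly classified segments.

    On the perfectly balanced datasets this pipeline produces, accuracy is a
    sufficient score; no complementary metric is computed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.shape[0] == 0:
        raise DataError("empty test set")
    if np.any((y < 0) | (y >= len(model.classes))):
        raise LabelError("test set contains a label the model was not trained on")
    pred = model.predict(x)
    return float(np.mean(pred == y))


def fit_and_score(
    spec: ModelSpec,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    classes: tuple[str, str] = ("a", "b"),
) -> float:
    """Convenience: build, train and evaluate in one call."""
    model = build_model(spec)
    trained = train(model, x_train, y_train, spec, classes)
    return evaluate(trained, x_test, y_test)
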