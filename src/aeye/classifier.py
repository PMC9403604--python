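"""Per-filtered-image binary classification (nystagmus / no-nystagmus).

Each filtered image inherits the label of the video it came from and is
classified independently; the voting module turns the resulting
per-image probability vector into a video-level decision. This is what
makes a small video corpus trainable: V videos of T frames supply
V × (T − 1) labeled training images under non-sliding filtering.

Backbones are small scikit-learn estimators behind a registry, trained
on area-pooled, [0, 1]-scaled filtered images. The default is a compact
multilayer perceptron that trains in minutes on one CPU; a linear
logistic backbone is available as a second, architecturally distinct
model for ensembling. The registry is open: any estimator factory with
a ``predict_proba`` can be registered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import joblib
import numpy as np

from .filtered_image import FilteredImageStack
from .voting import PerImageScores

__all__ = [
    "BackboneSpec",
    "ImageClassifier",
    "train_classifier",
    "predict_stack",
    "register_backbone",
    "available_backbones",
]

_BACKBONES: dict[str, Callable] = {}


def register_backbone(name: str, factory: Callable) -> None:
    """Register an estimator factory: (spec: BackboneSpec) → estimator."""
    _BACKBONES[name] = factory


def available_backbones() -> tuple[str, ...]:
    return tuple(sorted(_BACKBONES))


@dataclass(frozen=True)
class BackboneSpec:
    """Backbone choice plus training configuration.

    input_size
        (H, W) the filtered images are area-pooled to before
        classification; pooling doubles as the model's fixed input
        contract, so stacks at any resolution are accepted.
    epochs
        Fixed optimisation budget; early stopping is off for
        reproducibility.
    """

    name: str = "tiny_mlp"
    input_size: tuple[int, int] = (12, 16)
    epochs: int = 60
    batch_size: int = 256
    learning_rate: float = 1e-3
    hidden: tuple[int, ...] = (32,)
    seed: int = 0

    def make_estimator(self):
        if self.name not in _BACKBONES:
            raise ValueError(
                f"unknown backbone {self.name!r}; available: {available_backbones()}"
            )
        return _BACKBONES[self.name](self)


def _mlp_factory(spec: BackboneSpec):
    from sklearn.neural_network import MLPClassifier

    return MLPClassifier(
        hidden_layer_sizes=spec.hidden,
        batch_size=spec.batch_size,
        learning_rate_init=spec.learning_rate,
        max_iter=spec.epochs,
        solver="adam",
        early_stopping=False,
        n_iter_no_change=spec.epochs,  # run the full fixed budget
        random_state=spec.seed,
    )


def _logistic_factory(spec: BackboneSpec):
    from sklearn.linear_model import LogisticRegression

    return LogisticRegression(max_iter=1000, random_state=spec.seed)


register_backbone("tiny_mlp", _mlp_factory)
register_backbone("logistic", _logistic_factory)


def pool_images(images: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Area-pool a (N, H, W) image stack to (N, h, w).

    Exact block means when H, W are multiples of the target; otherwise
    an anti-aliased resize.
    """
    n, H, W = images.shape
    h, w = size
    if (H, W) == (h, w):
        return images.astype(np.float64)
    if H % h == 0 and W % w == 0:
        return (
            images.reshape(n, h, H // h, w, W // w).mean(axis=(2, 4)).astype(np.float64)
        )
    from skimage.transform import resize

    return np.stack(
        [
            resize(img, (h, w), order=1, anti_aliasing=H > h, preserve_range=True)
            for img in images.astype(np.float64)
        ]
    )


@dataclass
class ImageClassifier:
    """Trained per-image model: filtered image → nystagmus probability."""

    spec: BackboneSpec
    estimator: object
    training_log: list = field(default_factory=list)

    def featurize(self, images: np.ndarray) -> np.ndarray:
        pooled = pool_images(np.asarray(images, dtype=np.float64), self.spec.input_size)
        return pooled.reshape(pooled.shape[0], -1) / 255.0

    def predict_images(self, images: np.ndarray) -> np.ndarray:
        """Nystagmus probability for each image in a (N, H, W) stack."""
        if images.shape[0] == 0:
            raise ValueError("empty image stack")
        proba = self.estimator.predict_proba(self.featurize(images))
        positive = list(self.estimator.classes_).index(1)
        return np.clip(proba[:, positive], 0.0, 1.0)

    def save(self, path: str | Path) -> None:
        """Checkpoint (estimator + spec + log) via joblib."""
        joblib.dump(
            {"spec": self.spec, "estimator": self.estimator, "log": self.training_log},
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ImageClassifier":
        blob = joblib.load(path)
        return cls(spec=blob["spec"], estimator=blob["estimator"], training_log=blob["log"])


def train_classifier(
    stacks: Sequence[FilteredImageStack],
    backbone: Optional[BackboneSpec] = None,
) -> ImageClassifier:
    """Fit a per-image classifier on labeled filtered-image stacks.

    Every image inherits its stack's video label; both classes must be
    represented. Training is fully seeded through the backbone spec.
    """
    backbone = backbone or BackboneSpec()
    X_parts, y_parts = [], []
    model = ImageClassifier(spec=backbone, estimator=backbone.make_estimator())
    for stack in stacks:
        if stack.label is None:
            raise ValueError("all training stacks must carry a label")
        X_parts.append(model.featurize(stack.images))
        y_parts.append(np.full(len(stack), int(stack.label)))
    if not X_parts:
        raise ValueError("no training stacks given")
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    model.estimator.fit(X, y)

    train_acc = float(model.estimator.score(X, y))
    losses = getattr(model.estimator, "loss_curve_", None)
    if losses is not None:
        model.training_log = [
            {"epoch": i + 1, "train_loss": float(l), "train_acc": None}
            for i, l in enumerate(losses)
        ]
        model.training_log[-1]["train_acc"] = train_acc
    else:
        model.training_log = [{"epoch": 1, "train_loss": float("nan"), "train_acc": train_acc}]
    return model


def predict_stack(model: ImageClassifier, stack: FilteredImageStack, video_id: str = "") -> PerImageScores:
    """One probability per filtered image, order-aligned with t_index."""
    if len(stack) == 0:
        raise ValueError("empty filtered-image stack")
    probs = model.predict_images(stack.images)
    return PerImageScores(probs=probs, t_index=stack.t_index, video_id=video_id)
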