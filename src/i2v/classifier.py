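"""Model construction and training with cross-entropy or adaptive cross-entropy.

The adaptive cross-entropy (ACE) loss up-weights currently misclassified
samples: with per-sample cross-entropy ceᵢ and the correctness indicator
cᵢ = [argmax p̂ᵢ == yᵢ],

    L_ACE = (1/N) Σᵢ (1 + α·(1 − cᵢ)) · ceᵢ

so α = 0 recovers plain cross-entropy and a batch of all-wrong predictions
gives (1 + α) times the plain loss.  The indicator is recomputed from the
current forward pass every step and treated as a constant (no gradient).

Training follows a fixed recipe: mini-batch SGD with momentum, constant
learning rate, and per-image random horizontal flips at load time.  The
offline-trainable backbone is the package's own ``TinyCNN``; the classical
ImageNet backbone names are registered so that requesting one produces an
actionable error rather than a silent fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import DatasetManifest, load_image
from .nn import TinyCNN, softmax

PROB_EPS = 1e-12

#: backbone registry; only ``tiny`` is constructible offline
BACKBONES = ("vgg19", "resnet18", "mobilenetv2", "inceptionv3",
             "efficientnet", "densenet121", "tiny")


@dataclass
class LossConfig:
    """kind='ce' for plain cross-entropy; 'ace' adds the α-weighted
    misclassified-sample term (kind='ce' equals kind='ace' with α=0)."""

    kind: str = "ce"
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("ce", "ace"):
            raise ValueError("loss kind must be 'ce' or 'ace'")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    @property
    def effective_alpha(self) -> float:
        return self.alpha if self.kind == "ace" else 0.0


@dataclass
class TrainConfig:
    """Optimizer schedule and augmentation switches for one training run."""

    num_classes: int = 2
    backbone: str = "tiny"
    pretrained: bool = False
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 64
    epochs: int = 20
    hflip_prob: float = 0.5
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ValueError("hflip_prob must be in [0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def build_model(backbone: str, num_classes: int, pretrained: bool = False,
                seed: int = 0):
    """Instantiate a backbone with a classification head of ``num_classes`` logits.

    Only the self-contained ``tiny`` CNN can be built here; the ImageNet
    backbone names require an external deep-learning runtime and published
    weights, so requesting them raises with guidance.
    """
    if backbone not in BACKBONES:
        raise ValueError(
            f"unknown backbone {backbone!r}; registry: {', '.join(BACKBONES)}"
        )
    if backbone != "tiny":
        raise RuntimeError(
            f"backbone {backbone!r} needs a deep-learning runtime and "
            "published pretrained weights, neither of which this package "
            "bundles; use backbone='tiny' (pretrained=False) for a "
            "self-contained model"
        )
    if pretrained:
        raise RuntimeError(
            "no pretrained weights exist for the 'tiny' backbone; "
            "pass pretrained=False"
        )
    return TinyCNN(num_classes=num_classes, seed=seed)


# ---------------------------------------------------------------------- #
# losses (defined on predicted probabilities)
# ---------------------------------------------------------------------- #
def _check_batch(probs: np.ndarray, labels: np.ndarray):
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    if probs.ndim != 2 or probs.shape[0] != labels.shape[0]:
        raise ValueError("probs must be (N, C) with one label per row")
    if np.any(probs < 0) or np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("each probability row must be non-negative and sum to 1")
    if np.any(labels < 0) or np.any(labels >= probs.shape[1]):
        raise ValueError("labels out of range")
    return probs, labels


def per_sample_cross_entropy(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    probs, labels = _check_batch(probs, labels)
    p_true = probs[np.arange(len(labels)), labels]
    return -np.log(np.maximum(p_true, PROB_EPS))


def cross_entropy_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true classes."""
    return float(per_sample_cross_entropy(probs, labels).mean())


def ace_loss(probs: np.ndarray, labels: np.ndarray, alpha: float = 1.0) -> float:
    """Adaptive cross-entropy: CE plus α times the mean CE of misclassified rows.

    Argmax ties break toward the lowest class index.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    probs, labels = _check_batch(probs, labels)
    ce = per_sample_cross_entropy(probs, labels)
    correct = probs.argmax(axis=1) == labels
    return float(ce.mean() + alpha * (ce * ~correct).mean())


# ---------------------------------------------------------------------- #
# training
# ---------------------------------------------------------------------- #
def _to_batch_tensor(images: np.ndarray) -> np.ndarray:
    """uint8 (N, H, W, 3) -> float32 (N, 3, H, W) scaled to [0, 1]."""
    x = np.asarray(images)
    if x.ndim != 4 or x.shape[-1] != 3:
        raise ValueError("expected images of shape (N, H, W, 3)")
    return np.ascontiguousarray(
        x.transpose(0, 3, 1, 2).astype(np.float32) / 255.0)


def fit_arrays(model: TinyCNN, images: np.ndarray, labels: np.ndarray,
               config: TrainConfig) -> pd.DataFrame:
    """SGD training loop over in-memory images; returns the per-epoch history.

    Horizontal flips are drawn per image per epoch from the run's seeded
    generator, so identical config + seed reproduces the history exactly.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.min() < 0 or labels.max() >= config.num_classes:
        raise ValueError("labels out of range for num_classes")
    n = len(labels)
    if images.shape[0] != n:
        raise ValueError("images and labels length mismatch")
    rng = np.random.default_rng(config.seed)
    alpha = config.loss.effective_alpha
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        flip = rng.random(n) < config.hflip_prob
        total_loss = 0.0
        total_correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = images[idx]
            fmask = flip[idx]
            if fmask.any():
                batch = batch.copy()
                batch[fmask] = batch[fmask, :, ::-1]
            x = _to_batch_tensor(batch)
            yb = labels[idx]
            logits = model.forward(x)
            probs = softmax(logits)
            ce = -np.log(np.maximum(probs[np.arange(len(yb)), yb], PROB_EPS))
            correct = probs.argmax(axis=1) == yb
            weights = 1.0 + alpha * (~correct)
            loss = float((weights * ce).mean())
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(yb)), yb] = 1.0
            dlogits = (weights[:, None] * (probs - onehot) / len(yb)
                       ).astype(np.float32)
            model.zero_grad()
            model.backward(dlogits)
            model.sgd_step(config.learning_rate, config.momentum)
            total_loss += loss * len(yb)
            total_correct += int(correct.sum())
        history.append({"epoch": epoch + 1,
                        "loss": total_loss / n,
                        "accuracy": total_correct / n})
    return pd.DataFrame(history)


def predict_proba_arrays(model: TinyCNN, images: np.ndarray,
                         batch_size: int = 64) -> np.ndarray:
    out = []
    for start in range(0, len(images), batch_size):
        x = _to_batch_tensor(images[start:start + batch_size])
        out.append(softmax(model.forward(x)))
    return np.concatenate(out, axis=0)


def load_manifest_images(manifest: DatasetManifest, split: str | None = None,
                         size: tuple[int, int] | None = None):
    """Stack a manifest (or one split) into (images, accession labels, records)."""
    records = [r for r in manifest.records
               if split is None or r.split == split]
    if not records:
        raise ValueError(f"no records in split {split!r}")
    imgs = np.stack([load_image(r.path, size=size) for r in records])
    labels = [r.accession for r in records]
    return imgs, labels, records


class CNNClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style image classifier over the package's CNN backbone.

    Parameters mirror :class:`TrainConfig`; ``fit`` accepts images of shape
    (N, H, W, 3) (uint8 or [0, 255] floats) with arbitrary hashable labels.

    Attributes
    ----------
    classes_ : ndarray of sorted unique labels seen in ``fit``.
    model_ : the trained :class:`TinyCNN`.
    history_ : per-epoch DataFrame with ``loss`` and ``accuracy`` columns.
    """

    def __init__(self, backbone: str = "tiny", pretrained: bool = False,
                 learning_rate: float = 0.01, momentum: float = 0.9,
                 batch_size: int = 64, epochs: int = 20,
                 hflip_prob: float = 0.5, loss_kind: str = "ce",
                 alpha: float = 1.0, seed: int = 0):
        self.backbone = backbone
        self.pretrained = pretrained
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.batch_size = batch_size
        self.epochs = epochs
        self.hflip_prob = hflip_prob
        self.loss_kind = loss_kind
        self.alpha = alpha
        self.seed = seed

    def _config(self, num_classes: int) -> TrainConfig:
        return TrainConfig(
            num_classes=num_classes, backbone=self.backbone,
            pretrained=self.pretrained, learning_rate=self.learning_rate,
            momentum=self.momentum, batch_size=self.batch_size,
            epochs=self.epochs, hflip_prob=self.hflip_prob, seed=self.seed,
            loss=LossConfig(kind=self.loss_kind, alpha=self.alpha),
        )

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError("X must have shape (N, H, W, 3)")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        config = self._config(len(self.classes_))
        self.model_ = build_model(config.backbone, config.num_classes,
                                  config.pretrained, seed=config.seed)
        self.history_ = fit_arrays(self.model_, X.astype(np.uint8),
                                   y_idx, config)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return predict_proba_arrays(self.model_, np.asarray(X).astype(np.uint8),
                                    self.batch_size)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


def train(model: TinyCNN, manifest: DatasetManifest, config: TrainConfig,
          classes: list[str] | None = None):
    """Train ``model`` on a manifest's train split; returns (model, history).

    ``classes`` fixes the label encoding (sorted accession list); an accession
    in the manifest that is missing from it is an error before training starts.
    """
    images, labels, _ = load_manifest_images(manifest, split="train")
    if classes is None:
        classes = sorted(set(labels))
    index = {c: i for i, c in enumerate(classes)}
    missing = sorted(set(labels) - set(index))
    if missing:
        raise ValueError(f"accessions absent from label encoder: {missing[:5]}")
    if len(classes) != config.num_classes:
        raise ValueError(
            f"config.num_classes={config.num_classes} but {len(classes)} classes"
        )
    y = np.array([index[l] for l in labels], dtype=np.int64)
    history = fit_arrays(model, images, y, config)
    return model, history
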