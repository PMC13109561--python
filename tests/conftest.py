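"""Shared fixtures: synthetic datasets and (expensive) trained models.

The full-size pipeline fixture (10 accessions x 5 dates x 2 views, seed 42)
and the two trained models (plain and adaptive cross-entropy) are built once
per session because training is the dominant cost of the suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from i2v import SynthConfig, generate_synthetic_dataset, run_gmma, split_dataset
from i2v.classifier import (
    LossConfig,
    TrainConfig,
    build_model,
    fit_arrays,
    load_manifest_images,
    predict_proba_arrays,
)

PIPELINE_SEED = 42


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(n_accessions=3, n_dates=4, image_size=(48, 64), seed=7)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("small_synth")
    return generate_synthetic_dataset(small_config, out), small_config


@pytest.fixture(scope="session")
def pipeline_config() -> SynthConfig:
    return SynthConfig(n_accessions=10, n_dates=5, image_size=(96, 128),
                       seed=PIPELINE_SEED)


@pytest.fixture(scope="session")
def pipeline_manifest(tmp_path_factory, pipeline_config):
    """Split 10x5x2 fixture manifest (80/20 stratified, seed 42)."""
    out = tmp_path_factory.mktemp("pipeline_synth")
    manifest = generate_synthetic_dataset(pipeline_config, out)
    return split_dataset(manifest, test_fraction=0.2, seed=PIPELINE_SEED)


@pytest.fixture(scope="session")
def augmented_manifest(tmp_path_factory, pipeline_manifest):
    out = tmp_path_factory.mktemp("pipeline_mixed")
    augmented, report = run_gmma(pipeline_manifest, out, lam=0.5)
    return augmented, report


@pytest.fixture(scope="session")
def trained_models(augmented_manifest):
    """CE- and ACE-trained TinyCNN on the augmented fixture, plus eval arrays."""
    augmented, _ = augmented_manifest
    x_train, l_train, _ = load_manifest_images(augmented, "train")
    x_test, l_test, test_records = load_manifest_images(augmented, "test")
    classes = sorted(set(l_train))
    index = {c: i for i, c in enumerate(classes)}
    y_train = np.array([index[l] for l in l_train])
    y_test = np.array([index[l] for l in l_test])
    out = {"classes": classes, "x_test": x_test, "y_test": y_test,
           "test_records": test_records}
    for kind in ("ce", "ace"):
        config = TrainConfig(num_classes=len(classes), epochs=20,
                             seed=PIPELINE_SEED,
                             loss=LossConfig(kind=kind, alpha=1.0))
        model = build_model("tiny", len(classes), seed=PIPELINE_SEED)
        history = fit_arrays(model, x_train, y_train, config)
        train_preds = predict_proba_arrays(model, x_train).argmax(axis=1)
        test_preds = predict_proba_arrays(model, x_test).argmax(axis=1)
        out[kind] = {
            "model": model,
            "history": history,
            "train_accuracy": float((train_preds == y_train).mean()),
            "test_accuracy": float((test_preds == y_test).mean()),
            "test_preds": test_preds,
        }
    return out


def random_prediction_batch(rng: np.random.Generator, n: int, c: int):
    """Random (probs, labels) with valid simplex rows."""
    raw = rng.gamma(1.0, 1.0, size=(n, c))
    probs = raw / raw.sum(axis=1, keepdims=True)
    labels = rng.integers(0, c, size=n)
    return probs, labels
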