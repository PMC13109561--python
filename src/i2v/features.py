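"""Handcrafted image descriptors and the classical classifier baselines.

Each image is summarized by four complementary descriptor families:

* 7 Hu invariant moments of the grayscale image, signed-log transformed
  (sign(h)·log10(|h| + ε)) to tame their dynamic range;
* GLCM (Haralick) contrast at every (distance, orientation) pair of a
  configurable grid, computed on a 32-level quantized, symmetric, normalized
  co-occurrence matrix;
* a 26-bin normalized histogram of uniform local binary patterns with
  radius 3 and 24 sampling points (P + 2 bins);
* mean hue, saturation and value in HSV space (H in [0, 1)).

Features are z-scored with train-split statistics (sample sd, n−1) and fed to
Naive Bayes, decision-tree, SVM and k-NN classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color
from skimage.feature import graycomatrix, graycoprops, local_binary_pattern
from skimage.measure import moments_central, moments_hu, moments_normalized
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluation import EvalReport, compute_metrics

HU_EPS = 1e-30
LBP_RADIUS = 3
LBP_POINTS = 24
LBP_BINS = LBP_POINTS + 2
GLCM_LEVELS = 32

DEFAULT_DISTANCES = (1, 2, 3)
DEFAULT_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


@dataclass
class FeatureVector:
    hu: np.ndarray                # (7,)
    haralick_contrast: np.ndarray  # (len(distances) * len(angles),)
    lbp_hist: np.ndarray          # (26,)
    hsv_means: np.ndarray         # (3,)

    @property
    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.hu, self.haralick_contrast,
                               self.lbp_hist, self.hsv_means])


def feature_names(distances=DEFAULT_DISTANCES,
                  angles=DEFAULT_ANGLES) -> list[str]:
    names = [f"hu{i+1}" for i in range(7)]
    for d in distances:
        for a in angles:
            names.append(f"glcm_contrast_d{d}_a{int(round(np.degrees(a)))}")
    names += [f"lbp_{i}" for i in range(LBP_BINS)]
    names += ["mean_h", "mean_s", "mean_v"]
    return names


def _signed_log(values: np.ndarray) -> np.ndarray:
    return np.sign(values) * np.log10(np.abs(values) + HU_EPS)


def extract_features(image: np.ndarray, distances=DEFAULT_DISTANCES,
                     angles=DEFAULT_ANGLES) -> FeatureVector:
    """Deterministic descriptor vector for one RGB image."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("image too small for co-occurrence statistics")
    if not distances or not len(angles):
        raise ValueError("distances and angles must be non-empty")
    gray = color.rgb2gray(arr)  # float in [0, 1]
    # integer gray levels: exact LBP comparisons and stable GLCM binning
    gray_u8 = np.rint(gray * 255.0).astype(np.uint8)

    mu = moments_central(gray)
    hu = _signed_log(moments_hu(moments_normalized(mu)))

    quant = (gray_u8 // (256 // GLCM_LEVELS)).astype(np.uint8)
    glcm = graycomatrix(quant, distances=list(distances), angles=list(angles),
                        levels=GLCM_LEVELS, symmetric=True, normed=True)
    contrast = graycoprops(glcm, "contrast").ravel()  # row-major (d, angle)

    lbp = local_binary_pattern(gray_u8, P=LBP_POINTS, R=LBP_RADIUS,
                               method="uniform")
    hist, _ = np.histogram(lbp, bins=np.arange(LBP_BINS + 1) - 0.5)
    lbp_hist = hist / hist.sum()

    hsv = color.rgb2hsv(arr)
    hsv_means = hsv.reshape(-1, 3).mean(axis=0)

    return FeatureVector(hu=hu, haralick_contrast=contrast,
                         lbp_hist=lbp_hist, hsv_means=hsv_means)


def extract_feature_matrix(images, distances=DEFAULT_DISTANCES,
                           angles=DEFAULT_ANGLES) -> np.ndarray:
    return np.stack([extract_features(im, distances, angles).concatenated
                     for im in images])


def zscore_normalize(train_matrix: np.ndarray, apply_matrix: np.ndarray):
    """Standardize both matrices with train-split mean and sample sd (n−1).

    Constant training columns map to 0 everywhere.  Returns
    (train_z, apply_z, means, sds).
    """
    train = np.asarray(train_matrix, dtype=np.float64)
    other = np.asarray(apply_matrix, dtype=np.float64)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValueError("train_matrix needs >= 2 rows")
    means = train.mean(axis=0)
    sds = train.std(axis=0, ddof=1)
    safe = np.where(sds > 0, sds, 1.0)
    train_z = (train - means) / safe
    other_z = (other - means) / safe
    const = sds == 0
    train_z[:, const] = 0.0
    other_z[:, const] = 0.0
    return train_z, other_z, means, sds


class HandcraftedFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer wrapping descriptor extraction + train-statistic z-scoring."""

    def __init__(self, distances=DEFAULT_DISTANCES, angles=DEFAULT_ANGLES,
                 standardize: bool = True):
        self.distances = distances
        self.angles = angles
        self.standardize = standardize

    def fit(self, X, y=None):
        raw = extract_feature_matrix(X, self.distances, self.angles)
        self.means_ = raw.mean(axis=0)
        self.sds_ = raw.std(axis=0, ddof=1) if len(raw) > 1 \
            else np.zeros(raw.shape[1])
        self.feature_names_ = feature_names(self.distances, self.angles)
        return self

    def transform(self, X):
        raw = extract_feature_matrix(X, self.distances, self.angles)
        if not self.standardize:
            return raw
        safe = np.where(self.sds_ > 0, self.sds_, 1.0)
        z = (raw - self.means_) / safe
        z[:, self.sds_ == 0] = 0.0
        return z


def make_baseline_classifiers(seed: int = 0) -> dict:
    return {
        "naive_bayes": GaussianNB(),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "svm": SVC(random_state=seed),
        "knn": KNeighborsClassifier(),
    }


def fit_baselines(features: np.ndarray, labels, splits,
                  seed: int = 0) -> dict[str, EvalReport]:
    """Fit the four classical classifiers on the train split, score the test split.

    Uses the same train/test partition as the CNN run; features are z-scored
    with train statistics inside this function.
    """
    features = np.asarray(features)
    labels = np.asarray(labels)
    splits = np.asarray(splits)
    train_mask = splits == "train"
    test_mask = splits == "test"
    if not train_mask.any() or not test_mask.any():
        raise ValueError("both train and test splits must be non-empty")
    classes, y = np.unique(labels, return_inverse=True)
    unseen = set(y[test_mask]) - set(y[train_mask])
    if unseen:
        import warnings
        warnings.warn(f"{len(unseen)} test classes unseen in training")
    train_z, test_z, _, _ = zscore_normalize(features[train_mask],
                                             features[test_mask])
    reports = {}
    for name, clf in make_baseline_classifiers(seed).items():
        clf.fit(train_z, y[train_mask])
        preds = clf.predict(test_z)
        reports[name] = compute_metrics(preds, y[test_mask], len(classes),
                                        class_names=list(map(str, classes)))
    return reports
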