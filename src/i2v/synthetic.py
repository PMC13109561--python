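"""Deterministic synthetic plant-image datasets for offline pipeline testing.

Each "plant" is a noisy striped ellipse over a uniform dark background.  The
accession index keys the hue and stripe frequency (the class signature), the
date index drives a monotone growth in projected area, and the side view is a
fixed affine transform (horizontal squeeze + shear) of the front view.  The
generator emulates the structure real whole-plant phenotyping datasets have —
many classes, few images per class, two viewpoints, a growth axis — without
any attempt at photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import color, transform

from .dataset import DatasetManifest, ImageRecord

#: uniform background colour of every generated image (RGB, uint8)
BACKGROUND = np.array([20, 26, 22], dtype=np.uint8)

#: colour-distance threshold separating plant from background
FOREGROUND_THRESHOLD = 30.0


@dataclass
class SynthConfig:
    """Parameters of the synthetic dataset generator.

    class_signal in [0, 1] scales how far accession signatures (hue, stripe
    frequency) are spread apart; 0 makes all accessions identically
    distributed, 1 gives well-separated classes.  noise_sd is the per-pixel
    Gaussian noise scale in [0, 1] intensity units.
    """

    n_accessions: int = 10
    n_dates: int = 5
    viewpoints: tuple[str, ...] = ("front", "side")
    image_size: tuple[int, int] = (96, 128)  # (width, height)
    seed: int = 0
    class_signal: float = 1.0
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.n_accessions < 2:
            raise ValueError("n_accessions must be >= 2")
        if self.n_dates < 1:
            raise ValueError("n_dates must be >= 1")
        if self.image_size[0] < 32 or self.image_size[1] < 32:
            raise ValueError("image_size must be at least 32x32")
        bad = set(self.viewpoints) - {"front", "side"}
        if bad:
            raise ValueError(f"unknown viewpoints: {bad}")

    @property
    def accession_labels(self) -> list[str]:
        return [f"A{i:04d}" for i in range(self.n_accessions)]

    @property
    def date_tokens(self) -> list[str]:
        # days-after-sowing style tokens, weekly cadence
        return [str(42 + 7 * d) for d in range(self.n_dates)]


def _signature(config: SynthConfig, acc_idx: int) -> tuple[float, float]:
    """(hue, stripe frequency) for one accession, spread by class_signal."""
    frac = acc_idx / max(1, config.n_accessions - 1)
    hue = (0.18 + 0.75 * config.class_signal * frac) % 1.0
    freq = 3.0 + 9.0 * config.class_signal * ((acc_idx * 7) % config.n_accessions) \
        / max(1, config.n_accessions - 1)
    return hue, freq


def _render_front(config: SynthConfig, acc_idx: int, date_idx: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Front-view plant as float RGB in [0, 1]."""
    w, h = config.image_size
    hue, freq = _signature(config, acc_idx)
    growth = (date_idx + 1) / config.n_dates  # in (0, 1]

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cx, cy = w / 2.0, h * 0.62
    rx = 0.12 * w + 0.30 * w * growth
    ry = 0.15 * h + 0.32 * h * growth
    d2 = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2
    wobble = 0.12 * np.sin(5.0 * np.arctan2(yy - cy, xx - cx) + acc_idx)
    mask = d2 <= (1.0 + wobble)

    stripes = 0.5 + 0.35 * np.sin(2 * np.pi * freq * yy / h + acc_idx)
    hsv = np.zeros((h, w, 3))
    hsv[..., 0] = hue
    hsv[..., 1] = 0.85
    hsv[..., 2] = 0.35 + 0.5 * stripes
    plant = color.hsv2rgb(hsv)

    img = np.empty((h, w, 3))
    img[:] = BACKGROUND / 255.0
    img[mask] = plant[mask]
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


#: fixed affine mapping front view -> side view (squeeze + mild shear)
_SIDE_AFFINE = dict(scale=(0.72, 1.0), shear=0.12)


def _render_view(config: SynthConfig, acc_idx: int, date_idx: int,
                 viewpoint: str, rng: np.random.Generator) -> np.ndarray:
    front = _render_front(config, acc_idx, date_idx, rng)
    if viewpoint == "front":
        return front
    w, h = config.image_size
    tf = transform.AffineTransform(
        scale=_SIDE_AFFINE["scale"], shear=_SIDE_AFFINE["shear"],
        translation=(w * 0.16, 0.0),
    )
    warped = transform.warp(front, tf.inverse, order=1,
                            cval=0.0, preserve_range=True)
    bg = BACKGROUND / 255.0
    out_of_frame = transform.warp(np.ones((h, w)), tf.inverse, order=0, cval=0.0) < 0.5
    warped[out_of_frame] = bg
    return np.clip(warped, 0.0, 1.0)


def render_image(config: SynthConfig, acc_idx: int, date_idx: int,
                 viewpoint: str) -> np.ndarray:
    """One synthetic plant image as uint8 RGB; deterministic in all arguments."""
    # per-image seed stream so rendering order never matters
    seed = np.random.SeedSequence(
        [config.seed, acc_idx, date_idx, 0 if viewpoint == "front" else 1])
    rng = np.random.default_rng(seed)
    img = _render_view(config, acc_idx, date_idx, viewpoint, rng)
    return (img * 255.0).round().astype(np.uint8)


def generate_synthetic_dataset(config: SynthConfig, out_dir) -> DatasetManifest:
    """Write the full accession x date x viewpoint grid of PNGs and return its manifest.

    Filenames follow the ``accession_tag_date_viewpoint.png`` grammar with the
    tag fixed to ``p1``; the same seed yields byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for a, acc in enumerate(config.accession_labels):
        for d, date in enumerate(config.date_tokens):
            for v in config.viewpoints:
                arr = render_image(config, a, d, v)
                name = f"{acc}_p1_{date}_{v}.png"
                path = out_dir / name
                Image.fromarray(arr).save(path)
                records.append(ImageRecord(
                    path=str(path), accession=acc, tag="p1",
                    date=date, viewpoint=v, stage=date,
                ))
    records.sort(key=lambda r: r.sort_key)
    return DatasetManifest(records)


def foreground_mass(image) -> float:
    """Fraction of pixels whose colour distance from the known background
    exceeds the generator's threshold; in [0, 1]."""
    arr = np.asarray(image, dtype=np.float64)
    dist = np.sqrt(((arr - BACKGROUND.astype(np.float64)) ** 2).sum(axis=-1))
    return float((dist > FOREGROUND_THRESHOLD).mean())


def mean_hsv_features(image) -> np.ndarray:
    """Mean HSV over the plant (foreground) pixels of a generated image.

    The class signature lives in the plant, so the generator's own summary
    feature masks out the known background; an all-background image falls
    back to the whole-frame mean.
    """
    from skimage import color

    arr = np.asarray(image)
    hsv = color.rgb2hsv(arr)
    mask = foreground_mask(arr)
    if not mask.any():
        return hsv.reshape(-1, 3).mean(axis=0)
    return hsv[mask].mean(axis=0)


def foreground_mask(image) -> np.ndarray:
    """Boolean plant mask under the generator's background model."""
    arr = np.asarray(image, dtype=np.float64)
    dist = np.sqrt(((arr - BACKGROUND.astype(np.float64)) ** 2).sum(axis=-1))
    return dist > FOREGROUND_THRESHOLD
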