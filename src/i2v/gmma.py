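"""Growth-stage and multi-view mixed augmentation (GMMA).

Training images of one accession are convexly interpolated along three axes,
with mixing weight λ (default 0.5) and the label kept hard:

* temporal    — same viewpoint, adjacent sampling dates:
                I = λ·I(t) + (1−λ)·I(t+1)
* viewpoint   — same date, front and side views:
                I = λ·I(front) + (1−λ)·I(side)
* view_stage  — front view at date t with side view at the next date t+1:
                I = λ·I(t, front) + (1−λ)·I(t+1, side)

"Adjacent" means immediate successor in the sorted list of dates actually
present for that accession (per viewpoint for temporal mixing), so irregular
sampling schedules are handled.  Only same-accession pairs are ever mixed and
only the training split is augmented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .dataset import DatasetManifest, ImageRecord, date_sort_key, load_image

logger = logging.getLogger(__name__)

MIX_TYPES = ("temporal", "viewpoint", "view_stage")


@dataclass(frozen=True)
class MixJob:
    """One pending interpolation: left contributes λ, right contributes 1−λ."""

    left: ImageRecord
    right: ImageRecord
    mix_type: str
    lam: float = 0.5

    def __post_init__(self) -> None:
        if self.mix_type not in MIX_TYPES:
            raise ValueError(f"mix_type must be one of {MIX_TYPES}")
        if self.left.accession != self.right.accession:
            raise ValueError("GMMA never mixes across accessions")
        if not 0.0 < self.lam < 1.0:
            raise ValueError("lambda must be in (0, 1)")


@dataclass
class MixReport:
    """Counts of original and per-type mixed images for one GMMA run."""

    n_original: int = 0
    n_viewpoint: int = 0
    n_temporal: int = 0
    n_view_stage: int = 0

    @property
    def n_mixed(self) -> int:
        return self.n_viewpoint + self.n_temporal + self.n_view_stage

    @property
    def n_total(self) -> int:
        return self.n_original + self.n_mixed

    def to_dict(self) -> dict:
        return {
            "n_original": self.n_original,
            "n_viewpoint": self.n_viewpoint,
            "n_temporal": self.n_temporal,
            "n_view_stage": self.n_view_stage,
            "n_total": self.n_total,
        }


def mixgen(image_i: np.ndarray, image_j: np.ndarray, lam: float) -> np.ndarray:
    """Per-pixel convex combination λ·Iᵢ + (1−λ)·Iⱼ, rounded and clipped to uint8."""
    a = np.asarray(image_i)
    b = np.asarray(image_j)
    if a.shape != b.shape:
        raise ValueError(
            f"image shapes differ ({a.shape} vs {b.shape}); "
            "preprocess both images to a common size first"
        )
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    mixed = lam * a.astype(np.float64) + (1.0 - lam) * b.astype(np.float64)
    return np.clip(np.rint(mixed), 0, 255).astype(np.uint8)


def _slots(records: list[ImageRecord]) -> dict[tuple, list[ImageRecord]]:
    """Index raw records by (date token, viewpoint), deterministically ordered."""
    out: dict[tuple, list[ImageRecord]] = {}
    for r in sorted(records, key=lambda r: r.sort_key):
        if r.is_mixed:
            continue
        out.setdefault((r.date, r.viewpoint), []).append(r)
    return out


def enumerate_mix_jobs(group: list[ImageRecord], lam: float = 0.5,
                       view_stage_symmetric: bool = False) -> list[MixJob]:
    """All eligible mix jobs for one accession's images, deterministically ordered.

    When a (date, viewpoint) slot holds several images the Cartesian product of
    candidates is enumerated.  Groups of size <= 1 yield no jobs.  With
    ``view_stage_symmetric`` the mirrored side(t) x front(t+1) pairs are also
    emitted.
    """
    raw = [r for r in group if not r.is_mixed]
    if len(raw) <= 1:
        return []
    accessions = {r.accession for r in raw}
    if len(accessions) != 1:
        raise ValueError(f"group spans several accessions: {sorted(accessions)}")
    slots = _slots(raw)
    dates = sorted({d for d, _ in slots}, key=date_sort_key)

    jobs: list[MixJob] = []

    # temporal: per viewpoint, consecutive dates present in that viewpoint
    for view in ("front", "side"):
        vdates = [d for d in dates if (d, view) in slots]
        for t, t1 in zip(vdates, vdates[1:]):
            for left in slots[(t, view)]:
                for right in slots[(t1, view)]:
                    jobs.append(MixJob(left, right, "temporal", lam))

    # viewpoint: front x side at each date holding both views
    for d in dates:
        if (d, "front") in slots and (d, "side") in slots:
            for left in slots[(d, "front")]:
                for right in slots[(d, "side")]:
                    jobs.append(MixJob(left, right, "viewpoint", lam))

    # view_stage: front at t with side at the accession's next date t+1
    for t, t1 in zip(dates, dates[1:]):
        if (t, "front") in slots and (t1, "side") in slots:
            for left in slots[(t, "front")]:
                for right in slots[(t1, "side")]:
                    jobs.append(MixJob(left, right, "view_stage", lam))
        if view_stage_symmetric and (t, "side") in slots and (t1, "front") in slots:
            for left in slots[(t, "side")]:
                for right in slots[(t1, "front")]:
                    jobs.append(MixJob(left, right, "view_stage", lam))

    jobs.sort(key=lambda j: (j.mix_type, j.left.sort_key, j.right.sort_key))
    return jobs


def mixed_filename(job: MixJob) -> str:
    v = {"front": "front", "side": "side"}
    return (f"{job.left.accession}_mix-{job.mix_type}_"
            f"{job.left.date}-{job.right.date}_"
            f"{v[job.left.viewpoint]}{v[job.right.viewpoint]}.png")


def run_gmma(manifest: DatasetManifest, out_dir, lam: float = 0.5,
             view_stage_symmetric: bool = False,
             ) -> tuple[DatasetManifest, MixReport]:
    """Execute every mix job over the manifest's train split.

    Mixed PNGs are written under ``out_dir``; the returned manifest contains
    the original records plus one ``is_mixed=True`` train record per mixed
    image.  The test split is never augmented and accessions are never mixed.
    """
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must be in (0, 1)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    train = [r for r in manifest.records if r.split == "train" and not r.is_mixed]
    report = MixReport(n_original=len(manifest.records))
    new_records: list[ImageRecord] = [replace(r) for r in manifest.records]
    used_names: dict[str, int] = {}

    groups: dict[str, list[ImageRecord]] = {}
    for r in train:
        groups.setdefault(r.accession, []).append(r)

    for acc in sorted(groups):
        for job in enumerate_mix_jobs(groups[acc], lam, view_stage_symmetric):
            try:
                left = load_image(job.left.path)
                right = load_image(job.right.path)
            except OSError as e:
                logger.warning("skipping job %s x %s: %s",
                               job.left.path, job.right.path, e)
                continue
            try:
                mixed = mixgen(left, right, job.lam)
            except ValueError as e:
                logger.warning("skipping job %s x %s: %s",
                               job.left.path, job.right.path, e)
                continue
            name = mixed_filename(job)
            if name in used_names:
                used_names[name] += 1
                stem, ext = name.rsplit(".", 1)
                name = f"{stem}-{used_names[name]}.{ext}"
            else:
                used_names[name] = 0
            path = out_dir / name
            Image.fromarray(mixed).save(path)
            new_records.append(ImageRecord(
                path=str(path), accession=acc,
                tag=f"mix-{job.mix_type}", date=job.left.date,
                viewpoint=job.left.viewpoint, stage=job.left.stage,
                subspecies=job.left.subspecies, split="train", is_mixed=True,
            ))
            if job.mix_type == "temporal":
                report.n_temporal += 1
            elif job.mix_type == "viewpoint":
                report.n_viewpoint += 1
            else:
                report.n_view_stage += 1

    return DatasetManifest(new_records), report
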