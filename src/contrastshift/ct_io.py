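"""Volume I/O, HU preprocessing, and translator-pool curation.

Preprocessing follows the standard contrast-robust CT recipe: attenuation
is clipped to [-200, 300] HU (the window where iodine contrast changes
attenuation most) and then z-scored to zero mean / unit variance over the
full grid.

Curation assembles the two unpaired translator training pools from
automatically scored scans: a scan joins the contrast pool when a
contrast classifier assigns it probability > 0.8, and the non-contrast
pool when the probability is < 0.2 *and* its acquisition noise —
the standard deviation of fat-window voxels — is below 15 HU (low-dose
screening scans are often too noisy to translate cleanly).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

from .grids import HU, NORMALIZED, VolumeGrid

HU_CLIP_RANGE = (-200.0, 300.0)
FAT_WINDOW_HU = (-150.0, -50.0)  # conventional CT fat attenuation range
MIN_FAT_VOXELS = 100


# ---------------------------------------------------------------------------
# NIfTI I/O


def write_volume(grid: VolumeGrid, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag(list(grid.spacing_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(grid.values, dtype=np.float64), affine)
    img.header.set_zooms(grid.spacing_mm)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, intensity_kind: str = HU) -> VolumeGrid:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D NIfTI, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-positive voxel spacing {zooms}")
    return VolumeGrid(np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms), intensity_kind)


# ---------------------------------------------------------------------------
# Preprocessing


def clip_hu(grid: VolumeGrid, lo: float = HU_CLIP_RANGE[0], hi: float = HU_CLIP_RANGE[1]) -> VolumeGrid:
    """Clip attenuation to the iodine-sensitive window [-200, 300] HU."""
    if grid.intensity_kind != HU:
        raise ValueError("clip_hu requires HU input")
    return grid.with_values(np.clip(grid.values, lo, hi))


def normalize_zmuv(grid: VolumeGrid) -> VolumeGrid:
    """Z-score the full grid to zero mean, unit variance."""
    values = grid.values
    sd = values.std()
    if sd == 0:
        raise ValueError("cannot normalize a constant volume (zero variance)")
    return grid.with_values((values - values.mean()) / sd, intensity_kind=NORMALIZED)


def preprocess(grid: VolumeGrid) -> VolumeGrid:
    """clip to [-200, 300] HU then z-score; the segmenter/translator input contract."""
    return normalize_zmuv(clip_hu(grid))


def estimate_fat_noise(grid: VolumeGrid, window: tuple[float, float] = FAT_WINDOW_HU) -> float:
    """Acquisition-noise estimate: sample SD of voxels in the fat HU window."""
    if grid.intensity_kind != HU:
        raise ValueError("estimate_fat_noise requires HU input")
    sel = grid.values[(grid.values >= window[0]) & (grid.values <= window[1])]
    if sel.size < MIN_FAT_VOXELS:
        raise ValueError(f"only {sel.size} voxels in fat window {window}; need >= {MIN_FAT_VOXELS}")
    return float(sel.std(ddof=1))


# ---------------------------------------------------------------------------
# Curation


@dataclass
class CurationRecord:
    scan_id: str
    contrast_probability: float
    fat_noise_sd_hu: float
    accepted_as: str = "pending"  # contrast | noncontrast | rejected


def curate_translator_pools(
    records: list[CurationRecord],
    p_hi: float = 0.8,
    p_lo: float = 0.2,
    noise_max: float = 15.0,
) -> tuple[list[CurationRecord], list[CurationRecord]]:
    """Split scored scans into (contrast pool, non-contrast pool) in place.

    Gates are strict inequalities: probability must exceed ``p_hi`` for the
    contrast pool, and be below ``p_lo`` with fat noise below ``noise_max``
    HU for the non-contrast pool. Everything else is rejected.
    """
    contrast_pool, noncontrast_pool = [], []
    for rec in records:
        if rec.contrast_probability > p_hi:
            rec.accepted_as = "contrast"
            contrast_pool.append(rec)
        elif rec.contrast_probability < p_lo and rec.fat_noise_sd_hu < noise_max:
            rec.accepted_as = "noncontrast"
            noncontrast_pool.append(rec)
        else:
            rec.accepted_as = "rejected"
    if not contrast_pool or not noncontrast_pool:
        raise ValueError(
            f"curation left an empty pool (contrast={len(contrast_pool)}, "
            f"noncontrast={len(noncontrast_pool)}); translator cannot train"
        )
    return contrast_pool, noncontrast_pool


def write_curation_report(records: list[CurationRecord], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["scan_id", "contrast_probability", "fat_noise_sd_hu", "accepted_as"])
        for rec in records:
            w.writerow([rec.scan_id, rec.contrast_probability, rec.fat_noise_sd_hu, rec.accepted_as])
    return path


# ---------------------------------------------------------------------------
# Desk-scale contrast classifier


def _histogram_features(grid: VolumeGrid, bins: int = 16) -> np.ndarray:
    clipped = np.clip(grid.values, *HU_CLIP_RANGE)
    hist, _ = np.histogram(clipped, bins=bins, range=HU_CLIP_RANGE)
    # scale fractions to O(1) so the logistic penalty does not drown the
    # informative (small-mass) high-HU bins
    return bins * hist / clipped.size


class ContrastClassifier(ClassifierMixin, BaseEstimator):
    """Logistic model on a 16-bin HU histogram that scores contrast probability.

    Stands in for a deep image classifier in the curation pipeline; only its
    thresholded probability (>0.8 contrast / <0.2 non-contrast) is consumed
    downstream, so a calibrated histogram model preserves the contract.
    """

    def __init__(self, bins: int = 16, C: float = 100.0):
        self.bins = bins
        self.C = C

    def fit(self, volumes: list[VolumeGrid], labels: list[str] | np.ndarray) -> "ContrastClassifier":
        y = np.asarray([1 if lab == "contrast" else 0 for lab in labels])
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("need both contrast and non-contrast examples")
        for cls in classes:
            if (y == cls).sum() < 10:
                raise ValueError("need >= 10 examples per class")
        X = np.stack([_histogram_features(v, self.bins) for v in volumes])
        self.model_ = LogisticRegression(C=self.C, max_iter=2000).fit(X, y)
        self.classes_ = self.model_.classes_
        return self

    def predict_proba(self, volumes: list[VolumeGrid]) -> np.ndarray:
        X = np.stack([_histogram_features(v, self.bins) for v in volumes])
        return self.model_.predict_proba(X)

    def predict(self, volumes: list[VolumeGrid]) -> np.ndarray:
        return self.model_.predict(
            np.stack([_histogram_features(v, self.bins) for v in volumes])
        )

    def contrast_probability(self, volume: VolumeGrid) -> float:
        return float(self.predict_proba([volume])[0, 1])


def train_contrast_classifier(labeled: list[tuple[VolumeGrid, str]]) -> ContrastClassifier:
    """Fit the desk-scale contrast classifier on (volume, domain-label) pairs."""
    volumes, labels = zip(*labeled)
    return ContrastClassifier().fit(list(volumes), list(labels))
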