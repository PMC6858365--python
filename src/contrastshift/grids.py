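"""In-memory containers for CT-like volumes and organ label masks.

A :class:`VolumeGrid` is a 3D scalar field with voxel spacing and an
intensity-semantics flag: raw Hounsfield units (``"HU"``) or z-scored
intensities (``"normalized"``). The flag is carried through every
transform so that HU-only operations (clipping, fat-noise estimation)
can refuse normalized input.

A :class:`LabelVolume` is a binary organ mask aligned voxel-for-voxel
with its volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

HU = "HU"
NORMALIZED = "normalized"


@dataclass
class VolumeGrid:
    """3D scalar image with spacing and intensity semantics."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    intensity_kind: str = HU
    synthetic: bool = False  # True for GAN-translated volumes

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"VolumeGrid requires 3D data, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("VolumeGrid values must be finite")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        if self.intensity_kind not in (HU, NORMALIZED):
            raise ValueError(f"unknown intensity_kind {self.intensity_kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, intensity_kind: str | None = None) -> "VolumeGrid":
        return VolumeGrid(
            values=values,
            spacing_mm=self.spacing_mm,
            intensity_kind=self.intensity_kind if intensity_kind is None else intensity_kind,
        )

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class LabelVolume:
    """Binary organ mask aligned with a :class:`VolumeGrid`."""

    values: np.ndarray
    organ: str = "organ"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"LabelVolume requires 3D data, got ndim={arr.ndim}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"LabelVolume must be binary, found values {uniq[:10]}")
        self.values = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_count(self) -> int:
        return int(self.values.sum())

    def volume_mm3(self, spacing_mm: tuple[float, float, float]) -> float:
        return self.voxel_count() * float(np.prod(spacing_mm))


def require_aligned(grid: VolumeGrid, mask: LabelVolume) -> None:
    if grid.shape != mask.shape:
        raise ValueError(f"volume shape {grid.shape} != mask shape {mask.shape}")
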