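"""Training-time augmentation regimes.

Three regimes are supported on top of the shared spatial stack
(flip -> 3D rotation up to 30 degrees -> elastic b-spline deformation ->
random crop):

* ``standard`` — the spatial stack only;
* ``histeq``   — a fair coin picks the original or a 64-bin
  histogram-equalized version of the image before the spatial stack;
* ``cyclegan`` — a fair coin picks the original or the precomputed
  GAN-translated (synthetic non-contrast) volume before the spatial
  stack.

Every spatial transform is applied with identical parameters to the
image (trilinear interpolation) and the mask (nearest neighbor, so masks
stay binary), and the parameters are recorded in a ``transform_log``
that can be replayed exactly. Sixteen augmented variants per volume are
precomputed and cached; training then samples uniformly among them. The
per-variant random streams are keyed by (case id, variant index) only,
so different augmentation regimes share identical spatial streams and
differ purely in the intensity branch.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import affine_transform, map_coordinates, zoom as nd_zoom
from scipy.spatial.transform import Rotation

from .grids import LabelVolume, VolumeGrid, require_aligned

CONDITIONS = ("none", "standard", "histeq", "cyclegan")


@dataclass
class AugmentConfig:
    flip_probability: float = 0.5  # per axis
    flip_axes: tuple[int, ...] = (0, 1, 2)
    rotation_max_deg: float = 30.0
    crop_shape: tuple[int, int, int] | None = None  # None = full size
    bspline_control_points: int = 10  # per axis
    bspline_sigma: float = 8.0  # displacement SD, voxels
    swap_probability: float = 0.5  # histeq / domain-swap coin
    cached_variants: int = 16
    seed: int = 0

    def validate(self) -> None:
        for p in (self.flip_probability, self.swap_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.bspline_control_points < 4:
            raise ValueError("need >= 4 b-spline control points per axis")


@dataclass
class AugmentedVariant:
    image: VolumeGrid
    mask: LabelVolume
    transform_log: list[dict] = field(default_factory=list)
    source_domain: str = "original"


# ---------------------------------------------------------------------------
# Deterministic transform primitives (explicit parameters, replayable)


def apply_flip(image: np.ndarray, mask: np.ndarray, axes: tuple[int, ...]):
    for ax in axes:
        image = np.flip(image, axis=ax)
        mask = np.flip(mask, axis=ax)
    return np.ascontiguousarray(image), np.ascontiguousarray(mask)


def apply_rotation(image: np.ndarray, mask: np.ndarray,
                   angles_deg: tuple[float, float, float], fill: float):
    if all(a == 0 for a in angles_deg):
        return image, mask
    rot = Rotation.from_euler("xyz", angles_deg, degrees=True).as_matrix()
    center = (np.asarray(image.shape) - 1) / 2.0
    offset = center - rot @ center
    out_img = affine_transform(image, rot, offset=offset, order=1, cval=fill)
    out_msk = affine_transform(mask.astype(np.uint8), rot, offset=offset, order=0, cval=0)
    return out_img, out_msk


def bspline_displacement_field(control: np.ndarray, grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Upsample (3, cp, cp, cp) control displacements to a dense field by cubic splines."""
    fields = []
    for c in range(3):
        factors = [grid_shape[i] / control.shape[1 + i] for i in range(3)]
        fields.append(nd_zoom(control[c], factors, order=3, mode="nearest"))
    return np.stack(fields)


def apply_elastic(image: np.ndarray, mask: np.ndarray, control: np.ndarray, fill: float):
    if np.all(control == 0):
        return image, mask
    disp = bspline_displacement_field(control, image.shape)
    coords = np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in image.shape],
                                  indexing="ij"))
    coords = coords + disp
    out_img = map_coordinates(image, coords, order=1, cval=fill)
    out_msk = map_coordinates(mask.astype(np.uint8), coords, order=0, cval=0)
    return out_img, out_msk


def apply_crop(image: np.ndarray, mask: np.ndarray, offset, crop_shape):
    sl = tuple(slice(o, o + c) for o, c in zip(offset, crop_shape))
    return image[sl].copy(), mask[sl].copy()


# ---------------------------------------------------------------------------
# Random transforms


def random_flip(image: VolumeGrid, mask: LabelVolume, rng: np.random.Generator,
                axes=(0, 1, 2), p: float = 0.5):
    require_aligned(image, mask)
    chosen = tuple(ax for ax in axes if rng.random() < p)
    img, msk = apply_flip(image.values, mask.values, chosen)
    return image.with_values(img), LabelVolume(msk, mask.organ), {"op": "flip", "axes": chosen}


def random_rotation_3d(image: VolumeGrid, mask: LabelVolume, rng: np.random.Generator,
                       max_deg: float = 30.0, fill: float | None = None):
    require_aligned(image, mask)
    angles = tuple(float(rng.uniform(-max_deg, max_deg)) for _ in range(3))
    fill = float(image.values.min()) if fill is None else fill
    img, msk = apply_rotation(image.values, mask.values, angles, fill)
    return (image.with_values(img), LabelVolume(msk, mask.organ),
            {"op": "rotate", "angles_deg": angles, "fill": fill})


def random_elastic_bspline(image: VolumeGrid, mask: LabelVolume, rng: np.random.Generator,
                           control_points: int = 10, sigma: float = 8.0,
                           fill: float | None = None):
    require_aligned(image, mask)
    if control_points > min(image.shape):
        raise ValueError(
            f"control lattice {control_points}^3 larger than grid {image.shape}"
        )
    control = rng.normal(0.0, sigma, size=(3, control_points, control_points, control_points)) \
        if sigma > 0 else np.zeros((3, control_points, control_points, control_points))
    fill = float(image.values.min()) if fill is None else fill
    img, msk = apply_elastic(image.values, mask.values, control, fill)
    return (image.with_values(img), LabelVolume(msk, mask.organ),
            {"op": "elastic", "control": control, "fill": fill})


# spec-facing alias
elastic_bspline = random_elastic_bspline


def random_crop(image: VolumeGrid, mask: LabelVolume, crop_shape, rng: np.random.Generator):
    require_aligned(image, mask)
    crop_shape = tuple(crop_shape)
    if any(c > n for c, n in zip(crop_shape, image.shape)):
        raise ValueError(f"crop {crop_shape} larger than grid {image.shape}")
    offset = tuple(int(rng.integers(0, n - c + 1)) for c, n in zip(crop_shape, image.shape))
    img, msk = apply_crop(image.values, mask.values, offset, crop_shape)
    return (image.with_values(img), LabelVolume(msk, mask.organ),
            {"op": "crop", "offset": offset, "crop_shape": crop_shape})


# ---------------------------------------------------------------------------
# Histogram equalization


def histeq_augment(image: VolumeGrid, bins: int = 64,
                   target_histogram: np.ndarray | None = None) -> VolumeGrid:
    """Monotone intensity remapping toward a flat (or given) histogram.

    MATLAB ``histeq`` semantics: a 64-bin CDF mapping, rescaled to the
    input intensity range. Rank order of voxel intensities is preserved.
    """
    values = image.values
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        warnings.warn("constant image: histogram equalization is a no-op")
        return image.with_values(values.copy())
    hist, edges = np.histogram(values, bins=bins, range=(vmin, vmax))
    if target_histogram is None:
        cdf = np.cumsum(hist).astype(np.float64)
    else:
        # map input quantiles onto the target distribution's quantiles
        t = np.asarray(target_histogram, dtype=np.float64)
        if t.size != bins:
            raise ValueError("target_histogram must have `bins` entries")
        src_cdf = np.cumsum(hist) / hist.sum()
        tgt_cdf = np.cumsum(t) / t.sum()
        lut = np.interp(src_cdf, tgt_cdf, np.arange(bins) + 1.0)
        cdf = lut
    cdf = cdf / cdf[-1]
    centers = (edges[:-1] + edges[1:]) / 2.0
    mapped = np.interp(values, centers, vmin + cdf * (vmax - vmin))
    return image.with_values(mapped)


def chi2_to_uniform(values: np.ndarray, bins: int = 64) -> float:
    """Chi-squared distance between an intensity histogram and the uniform one."""
    hist, _ = np.histogram(values, bins=bins, range=(float(values.min()), float(values.max())))
    p = hist / hist.sum()
    u = 1.0 / bins
    return float(np.sum((p - u) ** 2 / u))


# ---------------------------------------------------------------------------
# Sample assembly and caching


def _spatial_stack(image: VolumeGrid, mask: LabelVolume, config: AugmentConfig,
                   rng: np.random.Generator):
    log = []
    image, mask, entry = random_flip(image, mask, rng, config.flip_axes, config.flip_probability)
    log.append(entry)
    image, mask, entry = random_rotation_3d(image, mask, rng, config.rotation_max_deg)
    log.append(entry)
    image, mask, entry = random_elastic_bspline(
        image, mask, rng, config.bspline_control_points, config.bspline_sigma
    )
    log.append(entry)
    crop = config.crop_shape if config.crop_shape is not None else image.shape
    image, mask, entry = random_crop(image, mask, crop, rng)
    log.append(entry)
    return image, mask, log


def assemble_training_sample(
    image: VolumeGrid,
    mask: LabelVolume,
    condition: str,
    config: AugmentConfig,
    rng: np.random.Generator,
    translated_volume: VolumeGrid | None = None,
) -> AugmentedVariant:
    """One augmented training sample under the given regime.

    The intensity branch (histeq / domain swap) comes first so that both
    branches pass through identical spatial statistics; the mask always
    derives from the original case.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    require_aligned(image, mask)
    if condition == "none":
        return AugmentedVariant(image=image, mask=mask, transform_log=[], source_domain="original")

    # split the stream so the spatial transforms are identical across
    # conditions for the same (case, variant) key: the intensity coin uses
    # its own substream
    coin_seed, spatial_seed = rng.integers(2**63, size=2)
    coin_rng = np.random.default_rng(coin_seed)
    spatial_rng = np.random.default_rng(spatial_seed)

    source_domain = "original"
    log: list[dict] = []
    work = image
    if condition == "histeq":
        if coin_rng.random() < config.swap_probability:
            work = histeq_augment(work)
            source_domain = "histeq"
        log.append({"op": "intensity_branch", "source_domain": source_domain})
    elif condition == "cyclegan":
        if translated_volume is None:
            raise ValueError("cyclegan condition requires a precomputed translated volume")
        if translated_volume.shape != image.shape:
            raise ValueError("translated volume not aligned with case")
        if coin_rng.random() < config.swap_probability:
            work = translated_volume
            source_domain = "synthetic_noncontrast"
        log.append({"op": "intensity_branch", "source_domain": source_domain})

    work, mask, spatial_log = _spatial_stack(work, mask, config, spatial_rng)
    return AugmentedVariant(
        image=work, mask=mask, transform_log=log + spatial_log, source_domain=source_domain
    )


def replay_spatial_log(image: VolumeGrid, mask: LabelVolume, transform_log: list[dict]):
    """Re-apply logged spatial transforms exactly (oracle for consistency tests)."""
    img, msk = image.values, mask.values
    for entry in transform_log:
        op = entry["op"]
        if op == "flip":
            img, msk = apply_flip(img, msk, entry["axes"])
        elif op == "rotate":
            img, msk = apply_rotation(img, msk, entry["angles_deg"], entry["fill"])
        elif op == "elastic":
            img, msk = apply_elastic(img, msk, entry["control"], entry["fill"])
        elif op == "crop":
            img, msk = apply_crop(img, msk, entry["offset"], entry["crop_shape"])
        elif op == "intensity_branch":
            pass  # intensity only; no spatial effect
        else:
            raise ValueError(f"unknown transform {op!r}")
    return img, msk


def write_variant_cache(variants: list[AugmentedVariant], cache_dir,
                        case_id: str, condition: str) -> list:
    """Persist cached variants as NIfTI plus JSON transform logs.

    Files are keyed by (case_id, condition, variant index); elastic
    control lattices are stored inline in the JSON log.
    """
    import json
    from pathlib import Path

    from . import ct_io

    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, var in enumerate(variants):
        stem = f"{case_id}_{condition}_{i:02d}"
        written.append(ct_io.write_volume(var.image, cache_dir / f"{stem}_img.nii"))
        written.append(ct_io.write_volume(
            var.image.with_values(var.mask.values.astype(np.float64)),
            cache_dir / f"{stem}_mask.nii"))
        log = [{k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in entry.items()} for entry in var.transform_log]
        path = cache_dir / f"{stem}_log.json"
        path.write_text(json.dumps({"source_domain": var.source_domain,
                                    "transform_log": log}))
        written.append(path)
    return written


def variant_rng(seed: int, case_id: str, variant_index: int) -> np.random.Generator:
    """Random stream keyed by (seed, case, variant) — condition-independent."""
    crc = zlib.crc32(case_id.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), crc, int(variant_index)]))


def cache_variants(
    image: VolumeGrid,
    mask: LabelVolume,
    condition: str,
    config: AugmentConfig,
    case_id: str,
    translated_volume: VolumeGrid | None = None,
    k: int | None = None,
) -> list[AugmentedVariant]:
    """Precompute k (default 16) augmented variants of one volume."""
    k = config.cached_variants if k is None else k
    if condition == "none":
        return [AugmentedVariant(image=image, mask=mask, transform_log=[],
                                 source_domain="original")]
    return [
        assemble_training_sample(
            image, mask, condition, config,
            variant_rng(config.seed, case_id, i),
            translated_volume=translated_volume,
        )
        for i in range(k)
    ]
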