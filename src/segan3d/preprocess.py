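"""CT preprocessing: Hounsfield-unit windowing, gray-level mapping and
patch extraction/stitching.

The pipeline converts a raw abdominal CT volume (HU values, NIfTI) into
the gray-level patches the segmentation network consumes:

1. *Truncation* — clip HU into a liver-contrast window, by default
   [-200, +200] HU (liver parenchyma and its neighbours live inside this
   range; air at -1000 HU and bone above +400 HU carry no liver
   information and are flattened to the window edges).
2. *Normalisation* — linear map of the window onto [0, 1]:
   ``(H - HU_min) / (HU_max - HU_min)``.
3. *Gray mapping* — multiply by 255 and truncate to an integer gray
   level in [0, 255].  The network itself consumes these values divided
   back by 255 (see :func:`to_network_input`).

Volumes are indexed ``(x, y, z)`` with ``z`` the slice axis.  Patching
tiles the volume without overlap after zero-padding each axis up to the
next multiple of the patch shape; stitching is its exact inverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class HUVolume:
    """Raw CT volume: values in Hounsfield units plus voxel spacing (mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"HUVolume requires a 3D array, got {self.values.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class WindowParams:
    """HU window [hu_min, hu_max]; default [-200, +200] HU."""

    hu_min: float = -200.0
    hu_max: float = 200.0

    def __post_init__(self):
        if not self.hu_min < self.hu_max:
            raise ValueError(f"hu_min must be < hu_max, got [{self.hu_min}, {self.hu_max}]")


@dataclass
class GrayVolume:
    """Preprocessed volume: integer gray levels in [0, 255]."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("GrayVolume requires a 3D array")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 255):
            raise ValueError("gray values must lie in [0, 255]")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class PatchSet:
    """Non-overlapping tiles of a volume plus the bookkeeping to undo them."""

    patches: list[np.ndarray]
    placements: list[tuple[int, int, int]]
    pad_record: tuple[int, int, int]
    source_shape: tuple[int, int, int]
    patch_shape: tuple[int, int, int] = field(default=None)

    def __post_init__(self):
        if self.patch_shape is None and self.patches:
            self.patch_shape = self.patches[0].shape

    def __len__(self) -> int:
        return len(self.patches)


def read_ct_volume(path) -> HUVolume:
    """Read a 3D NIfTI image; values pass through unmodified (assumed HU)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D from {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return HUVolume(values=data, spacing=spacing)


def write_nifti(values: np.ndarray, spacing, path, dtype=None) -> None:
    """Write a 3D array as NIfTI with a diagonal affine built from spacing."""
    arr = np.asarray(values, dtype=dtype) if dtype else np.asarray(values)
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def truncate_hu(vol: HUVolume, w: WindowParams | None = None) -> HUVolume:
    """Clip every voxel into the HU window (idempotent)."""
    w = w or WindowParams()
    return HUVolume(values=np.clip(vol.values, w.hu_min, w.hu_max),
                    spacing=vol.spacing)


def normalize_hu(vol: HUVolume, w: WindowParams | None = None) -> np.ndarray:
    """Map windowed HU linearly onto [0, 1]; requires pre-truncated input."""
    w = w or WindowParams()
    v = vol.values
    if v.size and (v.min() < w.hu_min or v.max() > w.hu_max):
        raise ValueError("normalize_hu requires values inside the window; "
                         "apply truncate_hu first")
    return (v.astype(np.float64) - w.hu_min) / (w.hu_max - w.hu_min)


def map_to_gray(norm: np.ndarray, spacing, rounding: str = "floor") -> GrayVolume:
    """Multiply [0,1] values by 255 and convert to integer gray levels.

    ``rounding`` selects the integer conversion: "floor" (truncation, the
    default) or "round" (nearest).
    """
    norm = np.asarray(norm)
    if norm.size and (norm.min() < 0 or norm.max() > 1):
        raise ValueError("map_to_gray requires inputs in [0, 1]")
    scaled = norm * 255.0
    if rounding == "floor":
        gray = np.floor(scaled)
    elif rounding == "round":
        gray = np.rint(scaled)
    else:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return GrayVolume(values=np.clip(gray, 0, 255).astype(np.uint8), spacing=spacing)


def hu_to_gray(vol: HUVolume, w: WindowParams | None = None,
               rounding: str = "floor") -> GrayVolume:
    """Full truncate -> normalize -> gray pipeline."""
    w = w or WindowParams()
    return map_to_gray(normalize_hu(truncate_hu(vol, w), w), vol.spacing,
                       rounding=rounding)


def to_network_input(gray: GrayVolume) -> np.ndarray:
    """Gray levels rescaled to the canonical [0, 1] network-input scale."""
    return gray.values.astype(np.float32) / 255.0


def resample_inplane(vol: np.ndarray, target_xy: tuple[int, int],
                     spacing, is_label: bool = False):
    """Rescale the in-plane (x, y) size, keeping the slice axis untouched.

    Trilinear interpolation for images, nearest-neighbour for label masks.
    Returns the resampled array and the adjusted spacing.
    """
    nx, ny, nz = vol.shape
    tx, ty = target_xy
    if (nx, ny) == (tx, ty):
        return vol, tuple(spacing)
    zoom = (tx / nx, ty / ny, 1.0)
    order = 0 if is_label else 1
    out = ndimage.zoom(vol, zoom, order=order, mode="nearest", grid_mode=True)
    # grid_mode=True can be off by one voxel for awkward ratios; enforce shape
    out = out[:tx, :ty, :]
    new_spacing = (spacing[0] * nx / tx, spacing[1] * ny / ty, spacing[2])
    return out, new_spacing


def extract_patches(vol: GrayVolume | np.ndarray,
                    patch_shape: tuple[int, int, int] = (256, 256, 16)) -> PatchSet:
    """Tile a volume into non-overlapping patches of ``patch_shape``.

    Each axis is zero-padded up to the next multiple of the patch size, so
    ``stitch_patches(extract_patches(v), v.shape)`` returns ``v`` exactly.
    """
    arr = vol.values if isinstance(vol, GrayVolume) else np.asarray(vol)
    if any(p <= 0 for p in patch_shape):
        raise ValueError(f"patch dimensions must be positive, got {patch_shape}")
    src_shape = arr.shape
    padded = tuple(math.ceil(s / p) * p for s, p in zip(src_shape, patch_shape))
    pad = tuple(ps - s for ps, s in zip(padded, src_shape))
    if any(pad):
        arr = np.pad(arr, [(0, p) for p in pad])
    patches, placements = [], []
    px, py, pz = patch_shape
    for x0 in range(0, padded[0], px):
        for y0 in range(0, padded[1], py):
            for z0 in range(0, padded[2], pz):
                patches.append(arr[x0:x0 + px, y0:y0 + py, z0:z0 + pz].copy())
                placements.append((x0, y0, z0))
    return PatchSet(patches=patches, placements=placements, pad_record=pad,
                    source_shape=src_shape, patch_shape=tuple(patch_shape))


def stitch_patches(ps: PatchSet, target_shape: tuple[int, int, int] | None = None,
                   dtype=None) -> np.ndarray:
    """Reassemble patches into the source volume, discarding padding."""
    if not ps.patches:
        raise ValueError("cannot stitch an empty PatchSet")
    target_shape = tuple(target_shape or ps.source_shape)
    px, py, pz = ps.patch_shape
    padded = tuple(t + p for t, p in zip(target_shape, ps.pad_record))
    out = np.zeros(padded, dtype=dtype or ps.patches[0].dtype)
    for patch, (x0, y0, z0) in zip(ps.patches, ps.placements):
        if x0 + px > padded[0] or y0 + py > padded[1] or z0 + pz > padded[2]:
            raise ValueError(f"placement {(x0, y0, z0)} out of bounds for "
                             f"padded shape {padded}")
        out[x0:x0 + px, y0:y0 + py, z0:z0 + pz] = patch
    return out[:target_shape[0], :target_shape[1], :target_shape[2]]
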