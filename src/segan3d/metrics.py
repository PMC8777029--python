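"""Segmentation evaluation: Dice overlap and surface distances.

Dice is the usual set overlap ``2|A∩B| / (|A| + |B|)``.  The Hausdorff
distance (HD, exact 100th percentile) and the average symmetric surface
distance (ASSD) operate on mask *surfaces* — mask voxels with at least
one face-adjacent (6-connected) background neighbour, with the outside
of the array counted as background — and are reported in millimetres via
the anisotropic voxel spacing.  Nearest-surface distances are taken from
a Euclidean distance transform computed with the physical spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class BinaryMaskPair:
    """Ground truth ``a``, prediction ``b``, and the shared voxel spacing."""

    a: np.ndarray
    b: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.a = np.asarray(self.a).astype(bool)
        self.b = np.asarray(self.b).astype(bool)
        if self.a.shape != self.b.shape:
            raise ValueError(f"mask shapes differ: {self.a.shape} vs {self.b.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")


def dice(p: BinaryMaskPair) -> float:
    """2|A∩B| / (|A|+|B|); two empty masks score 1.0 by convention."""
    na, nb = int(p.a.sum()), int(p.b.sum())
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(p.a, p.b).sum())
    return 2.0 * inter / (na + nb)


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with >= 1 face-adjacent background neighbour.

    The array border is treated as background, so foreground voxels on
    the volume edge belong to the surface.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("surface_voxels expects a 3D mask")
    interior = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    return mask & ~interior


def _surface_distances(src: np.ndarray, dst: np.ndarray, spacing) -> np.ndarray:
    """Distance from each surface voxel of ``src`` to the nearest surface
    voxel of ``dst``, in mm."""
    dst_surface = surface_voxels(dst)
    dt = ndimage.distance_transform_edt(~dst_surface, sampling=spacing)
    return dt[surface_voxels(src)]


def hausdorff(p: BinaryMaskPair) -> float:
    """Exact symmetric Hausdorff distance between mask surfaces (mm)."""
    if not p.a.any() or not p.b.any():
        raise ValueError("Hausdorff distance is undefined for an empty mask")
    d_ab = _surface_distances(p.a, p.b, p.spacing)
    d_ba = _surface_distances(p.b, p.a, p.spacing)
    return float(max(d_ab.max(), d_ba.max()))


def assd(p: BinaryMaskPair) -> float:
    """Average symmetric surface distance (mm): mean of all nearest-surface
    distances pooled over both directions."""
    if not p.a.any() or not p.b.any():
        raise ValueError("ASSD is undefined for an empty mask")
    d_ab = _surface_distances(p.a, p.b, p.spacing)
    d_ba = _surface_distances(p.b, p.a, p.spacing)
    return float(np.concatenate([d_ab, d_ba]).mean())


def evaluate_pair(a: np.ndarray, b: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> dict:
    """Convenience: all three metrics for one truth/prediction pair."""
    p = BinaryMaskPair(a=a, b=b, spacing=spacing)
    out = {"dice": dice(p)}
    if p.a.any() and p.b.any():
        out["hausdorff_mm"] = hausdorff(p)
        out["assd_mm"] = assd(p)
    else:
        out["hausdorff_mm"] = float("nan")
        out["assd_mm"] = float("nan")
    return out
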