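"""Synthetic 3D CT phantoms for exercising the segmentation pipeline.

Each phantom emulates the regime of an abdominal CT around the liver: a
bright, lobed organ (a union of 1-3 overlapping ellipsoids) whose
interior gray level is *heterogeneous* (a smooth low-frequency cosine
field), sitting in darker soft tissue, with the organ boundary blurred
and Gaussian HU noise everywhere.  Default contrasts (+120 HU organ over
-60 HU background) keep both classes inside the [-200, +200] HU liver
window so that windowing preserves the contrast.

The ground-truth label is the *pre-blur* ellipsoid mask: blurring models
partial-volume softening of intensities only, so a perfect segmenter
scores Dice 1 by construction.

All randomness flows from a single integer seed; per-sample seeds are
derived with ``numpy``'s ``SeedSequence`` spawning, so datasets are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .preprocess import HUVolume, write_nifti


@dataclass
class PhantomParams:
    shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    organ_hu_mean: float = 120.0
    background_hu_mean: float = -60.0
    hu_noise_sd: float = 20.0
    boundary_blur_sigma: float = 1.5
    organ_axes_range: tuple[float, float] = (0.25, 0.45)
    heterogeneity_amplitude: float = 40.0
    max_lobes: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.organ_hu_mean <= self.background_hu_mean:
            raise ValueError("organ must be brighter than background")
        if self.hu_noise_sd < 0 or self.boundary_blur_sigma < 0:
            raise ValueError("noise sd and blur sigma must be >= 0")
        lo, hi = self.organ_axes_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError("organ_axes_range must satisfy 0 < lo <= hi < 0.5 "
                             "(semi-axes as fractions of the volume extent)")


@dataclass
class PhantomSample:
    image: HUVolume
    label: np.ndarray
    is_labeled: bool = True

    def __post_init__(self):
        if self.label.shape != self.image.shape:
            raise ValueError("label shape must equal image shape")


@dataclass
class DatasetManifest:
    """Split bookkeeping: ids, per-id file paths, and the global seed."""

    labeled_ids: list[str]
    unlabeled_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    images: dict[str, str]
    labels: dict[str, str]
    seed: int
    root: str = "."
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        groups = [set(self.labeled_ids), set(self.unlabeled_ids),
                  set(self.val_ids), set(self.test_ids)]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if groups[i] & groups[j]:
                    raise ValueError("manifest id sets must be pairwise disjoint")
        for sid in self.labeled_ids + self.val_ids + self.test_ids:
            if sid not in self.labels:
                raise ValueError(f"sample {sid} requires a label file")
        for sid in self.unlabeled_ids:
            if sid in self.labels:
                raise ValueError(f"unlabeled sample {sid} must not carry a label")

    @property
    def all_ids(self) -> list[str]:
        return self.labeled_ids + self.unlabeled_ids + self.val_ids + self.test_ids

    def image_path(self, sid: str) -> Path:
        return Path(self.root) / self.images[sid]

    def label_path(self, sid: str) -> Path:
        return Path(self.root) / self.labels[sid]

    def save(self, path) -> None:
        doc = {"seed": self.seed, "labeled_ids": list(self.labeled_ids),
               "unlabeled_ids": list(self.unlabeled_ids),
               "val_ids": list(self.val_ids), "test_ids": list(self.test_ids),
               "images": dict(self.images), "labels": dict(self.labels),
               "params": dict(self.params)}
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        path = Path(path)
        doc = yaml.safe_load(path.read_text())
        return cls(labeled_ids=doc["labeled_ids"], unlabeled_ids=doc["unlabeled_ids"],
                   val_ids=doc["val_ids"], test_ids=doc["test_ids"],
                   images=doc["images"], labels=doc["labels"], seed=doc["seed"],
                   root=str(path.parent), params=doc.get("params", {}))


def _ellipsoid_mask(shape, center, semi_axes, rot=None) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                        indexing="ij")
    pts = np.stack([g - c for g, c in zip(grids, center)])
    if rot is not None:
        pts = np.einsum("ij,j...->i...", rot, pts)
    q = sum((pts[i] / semi_axes[i]) ** 2 for i in range(3))
    return q <= 1.0


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation via QR of a Gaussian matrix."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _heterogeneity_field(shape, amplitude, rng, n_modes: int = 3) -> np.ndarray:
    """Smooth low-frequency intensity modulation: a sum of cosine modes."""
    field = np.zeros(shape, dtype=np.float64)
    grids = np.meshgrid(*[np.arange(s) / s for s in shape], indexing="ij")
    for _ in range(n_modes):
        freq = rng.integers(1, 3, size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        mode = np.ones(shape)
        for g, f, ph in zip(grids, freq, phase):
            mode = mode * np.cos(2 * np.pi * f * g + ph)
        field += mode
    return amplitude / n_modes * field


def generate_phantom(p: PhantomParams) -> PhantomSample:
    """Generate one phantom: image in HU plus its crisp binary organ label."""
    rng = np.random.default_rng(p.seed)
    shape = np.array(p.shape, dtype=np.float64)
    lo, hi = p.organ_axes_range

    for _ in range(32):  # resample until the organ fraction is plausible
        semi = rng.uniform(lo, hi, size=3) * shape
        if np.any(semi >= shape / 2):
            semi = np.minimum(semi, shape / 2 - 0.5)
        center = np.array([rng.uniform(a, s - a) for a, s in zip(semi, shape)])
        mask = _ellipsoid_mask(p.shape, center, semi, _random_rotation(rng))
        for _ in range(int(rng.integers(0, p.max_lobes))):  # extra lobes
            scale = rng.uniform(0.4, 0.7)
            offset = rng.uniform(-0.5, 0.5, size=3) * semi
            mask |= _ellipsoid_mask(p.shape, center + offset, semi * scale,
                                    _random_rotation(rng))
        frac = mask.mean()
        if 0.02 < frac < 0.5:
            break
    else:
        raise ValueError(f"could not place an organ with fraction in (0.02, 0.5) "
                         f"for shape {p.shape} and axes range {p.organ_axes_range}")

    hu = np.full(p.shape, p.background_hu_mean, dtype=np.float64)
    hetero = _heterogeneity_field(p.shape, p.heterogeneity_amplitude, rng)
    hu[mask] = p.organ_hu_mean + hetero[mask]
    if p.boundary_blur_sigma > 0:
        hu = ndimage.gaussian_filter(hu, p.boundary_blur_sigma)
    if p.hu_noise_sd > 0:
        hu = hu + rng.normal(0.0, p.hu_noise_sd, size=p.shape)
    image = HUVolume(values=hu, spacing=p.spacing)
    return PhantomSample(image=image, label=mask.astype(np.uint8))


def _replace_seed(p: PhantomParams, seed: int) -> PhantomParams:
    from dataclasses import replace
    return replace(p, seed=seed)


def generate_dataset(n_labeled: int, n_unlabeled: int, n_val: int, n_test: int,
                     p: PhantomParams, out_dir) -> DatasetManifest:
    """Write a labeled/unlabeled/val/test phantom dataset to NIfTI files.

    Per-sample seeds are spawned deterministically from ``p.seed``, so the
    same arguments always produce identical files.
    """
    if min(n_labeled, n_unlabeled, n_val, n_test) < 0:
        raise ValueError("sample counts must be >= 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    groups = [("labeled", n_labeled), ("unlabeled", n_unlabeled),
              ("val", n_val), ("test", n_test)]
    ss = np.random.SeedSequence(p.seed)
    children = ss.spawn(sum(n for _, n in groups))
    seeds = iter(int(c.generate_state(1)[0] % (2 ** 31)) for c in children)

    ids: dict[str, list[str]] = {g: [] for g, _ in groups}
    images: dict[str, str] = {}
    labels: dict[str, str] = {}
    for group, count in groups:
        for i in range(count):
            sid = f"{group}_{i:03d}"
            sample = generate_phantom(_replace_seed(p, next(seeds)))
            img_name = f"{sid}_image.nii.gz"
            write_nifti(sample.image.values, sample.image.spacing,
                        out_dir / img_name, dtype=np.float32)
            images[sid] = img_name
            if group != "unlabeled":
                lbl_name = f"{sid}_label.nii.gz"
                write_nifti(sample.label, sample.image.spacing,
                            out_dir / lbl_name, dtype=np.uint8)
                labels[sid] = lbl_name
            ids[group].append(sid)

    manifest = DatasetManifest(labeled_ids=ids["labeled"], unlabeled_ids=ids["unlabeled"],
                               val_ids=ids["val"], test_ids=ids["test"],
                               images=images, labels=labels, seed=p.seed,
                               root=str(out_dir),
                               params={"shape": list(p.shape),
                                       "spacing": list(p.spacing)})
    manifest.save(out_dir / "manifest.yaml")
    return manifest
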