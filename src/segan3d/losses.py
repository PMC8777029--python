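"""Label scheme and loss terms of the semi-supervised adversarial game.

The discriminator outputs K+1 = 3 per-voxel classes: the K = 2 real
classes (background 0, liver 1) and a synthetic *fake* class (2) that
real data never carries as ground truth.  Its loss is the exact sum

    L_discriminator = L_labeled + L_unlabeled + L_fake

with, writing ``p_k`` for the per-voxel class probabilities:

* ``L_labeled``   — cross entropy of the true class *conditioned on the
  voxel being real*, i.e. on the renormalised probabilities
  ``p_y / (p_0 + p_1)`` (the standard (K+1)-class semi-supervised GAN
  construction).  It is therefore invariant to the fake-class mass at a
  fixed real-class ratio.
* ``L_unlabeled`` — ``-log(1 - p_fake)``: real but unlabeled voxels are
  pushed away from the fake class, whichever real class they take.
* ``L_fake``      — ``-log p_fake`` on generated patches, every voxel of
  which carries the fake target.

The generator minimises a feature-matching objective: the squared L2
distance between the mean (over batch and space) discriminator features
of real and generated patches.

Voxel sums are reported as means (sum / voxel count) so values are
patch-size independent; ``reduction="sum"`` restores the raw sums.
Logs are clamped at 1e-8 for numerical safety.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.tensor import Tensor
from .segnet import FAKE, FeatureMap, PredictionMap

EPS = 1e-8
N_REAL_CLASSES = 2  # K; the fake class index equals K


def _as_prob_tensor(pred) -> tuple[Tensor, bool]:
    """Normalise input to a (N, 3, D, H, W) tensor.

    Returns the tensor and whether the caller passed a plain array (in
    which case a float is returned by the loss).
    """
    if isinstance(pred, Tensor):
        if pred.ndim != 5 or pred.shape[1] != 3:
            raise ValueError("expected a (N, 3, D, H, W) probability tensor")
        return pred, False
    if isinstance(pred, PredictionMap):
        arr = pred.probs
    else:
        arr = np.asarray(pred)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError("expected probabilities of shape (D, H, W, 3)")
    return Tensor(np.moveaxis(arr, -1, 0)[None]), True


def _reduce(voxelwise: Tensor, reduction: str) -> Tensor:
    if reduction == "mean":
        return voxelwise.mean()
    if reduction == "sum":
        return voxelwise.sum()
    raise ValueError(f"unknown reduction {reduction!r}")


def labeled_loss(pred, label: np.ndarray, reduction: str = "mean"):
    """Conditional cross entropy on labeled real data."""
    probs, to_float = _as_prob_tensor(pred)
    label = np.asarray(label)
    uniq = np.unique(label)
    if np.any((uniq != 0) & (uniq != 1)):
        raise ValueError(f"ground-truth labels must be in {{0, 1}}; the fake class "
                         f"is never a ground-truth class (got values {uniq.tolist()})")
    if label.ndim == 3:
        label = label[None]
    if label.shape != (probs.shape[0],) + probs.shape[2:]:
        raise ValueError("label shape must match the prediction's spatial shape")
    y = label.astype(probs.dtype)[:, None]
    p0 = probs[:, 0:1]
    p1 = probs[:, 1:2]
    p_true = p1 * Tensor(y) + p0 * Tensor(1.0 - y)
    p_real = (p0 + p1).clip(EPS, None)
    cond = (p_true / p_real).clip(EPS, 1.0)
    out = _reduce(-cond.log(), reduction)
    return out.item() if to_float else out


def unlabeled_loss(pred, reduction: str = "mean"):
    """-log(1 - p_fake) on unlabeled real data."""
    probs, to_float = _as_prob_tensor(pred)
    p_fake = probs[:, FAKE:FAKE + 1]
    out = _reduce(-((1.0 - p_fake).clip(EPS, 1.0)).log(), reduction)
    return out.item() if to_float else out


def fake_loss(pred, reduction: str = "mean"):
    """-log(p_fake) on generated patches (fake target at every voxel)."""
    probs, to_float = _as_prob_tensor(pred)
    p_fake = probs[:, FAKE:FAKE + 1]
    out = _reduce(-(p_fake.clip(EPS, 1.0)).log(), reduction)
    return out.item() if to_float else out


def discriminator_loss(labeled, unlabeled, fake):
    """Exact sum of the three discriminator terms."""
    parts = [labeled, unlabeled, fake]
    vals = [p.item() if isinstance(p, Tensor) else float(p) for p in parts]
    if not all(np.isfinite(v) for v in vals):
        raise FloatingPointError(f"non-finite discriminator loss components: "
                                 f"labeled={vals[0]}, unlabeled={vals[1]}, fake={vals[2]}")
    if any(isinstance(p, Tensor) for p in parts):
        total = parts[0]
        for p in parts[1:]:
            total = total + p
        return total
    return vals[0] + vals[1] + vals[2]


def _mean_features(f) -> Tensor:
    if isinstance(f, Tensor):
        if f.ndim != 5:
            raise ValueError("feature tensors must be (N, C, D, H, W)")
        return f.mean(axis=(0, 2, 3, 4))
    if isinstance(f, FeatureMap):
        arr = f.values
    else:
        arr = np.asarray(f)
    if arr.ndim != 4:
        raise ValueError("feature arrays must be 4D (spatial x channels)")
    return Tensor(arr.mean(axis=(0, 1, 2)))


def generator_loss(real_feat, fake_feat):
    """Feature matching: squared L2 distance between mean features."""
    mr = _mean_features(real_feat)
    mf = _mean_features(fake_feat)
    if mr.shape != mf.shape:
        raise ValueError(f"feature channel counts differ: {mr.shape} vs {mf.shape}")
    d = mr - mf
    out = (d * d).sum()
    if isinstance(real_feat, Tensor) or isinstance(fake_feat, Tensor):
        return out
    return out.item()


@dataclass
class LossReport:
    """One training step's loss components; total = labeled + unlabeled + fake."""

    labeled: float
    unlabeled: float
    fake: float
    generator: float = float("nan")

    def __post_init__(self):
        for name in ("labeled", "unlabeled", "fake"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise FloatingPointError(f"non-finite loss component {name}={v}")

    @property
    def discriminator_total(self) -> float:
        return discriminator_loss(self.labeled, self.unlabeled, self.fake)

    CSV_HEADER = "step,labeled,unlabeled,fake,discriminator_total,generator"

    def csv_row(self, step: int) -> str:
        return (f"{step},{self.labeled:.6g},{self.unlabeled:.6g},{self.fake:.6g},"
                f"{self.discriminator_total:.6g},{self.generator:.6g}")
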