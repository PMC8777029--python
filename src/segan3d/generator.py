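"""Feature-restoration generator.

Instead of decoding random noise — which fails to learn a 3D CT
distribution — the generator *restores* an image patch from a randomly
chosen subset of the discriminator's bottleneck feature channels.  The
unselected channels are zero-masked (rather than dropped) so the
generator always sees a fixed input width; because the missing subset is
random, the generator learns to complete the real-image distribution at
any position, and its outputs differ from the real patch, enlarging the
effective dataset.

Architecture: four stride-2 transposed-convolution stages (undoing the
encoder's four halvings), each followed by normalisation and ReLU, and a
final 1x1x1 convolution squashed to one intensity channel in [0, 1] by a
sigmoid — the same scale as the real network inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.tensor import Tensor
from .segnet import FeatureMap, NetConfig


@dataclass
class GenConfig:
    keep_fraction: float = 0.5
    n_upsample_stages: int = 4
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.keep_fraction <= 1.0):
            raise ValueError(f"keep_fraction must be in (0, 1], got {self.keep_fraction}")
        if self.n_upsample_stages < 1:
            raise ValueError("n_upsample_stages must be >= 1")

    def to_dict(self) -> dict:
        return {"keep_fraction": self.keep_fraction,
                "n_upsample_stages": self.n_upsample_stages, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "GenConfig":
        return cls(**d)


@dataclass
class MaskedFeatures:
    """Bottleneck features with the unselected channels zeroed."""

    values: Tensor
    selection: np.ndarray  # boolean, one flag per channel

    def __post_init__(self):
        if self.values.ndim != 5:
            raise ValueError("MaskedFeatures expects a (N, C, D, H, W) tensor")
        if self.selection.shape != (self.values.shape[1],):
            raise ValueError("selection must have one flag per channel")

    @property
    def n_selected(self) -> int:
        return int(self.selection.sum())


def select_feature_subset(f, keep_fraction: float = 0.5,
                          seed: int | np.random.Generator = 0) -> MaskedFeatures:
    """Keep a uniformly random subset of round(keep_fraction * C) channels
    (at least 1), zero-masking the rest.

    ``f`` may be a (N, C, D, H, W) tensor/array or a spatial-last
    :class:`FeatureMap`.
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    if isinstance(f, FeatureMap):
        t = Tensor(np.moveaxis(f.values, -1, 0)[None].astype(np.float32))
    elif isinstance(f, Tensor):
        t = f
    else:
        arr = np.asarray(f, dtype=np.float32)
        if arr.ndim == 4:
            arr = arr[None]
        t = Tensor(arr)
    c = t.shape[1]
    if c < 1:
        raise ValueError("feature map must have at least one channel")
    k = max(1, int(round(keep_fraction * c)))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(c, size=k, replace=False)
    selection = np.zeros(c, dtype=bool)
    selection[chosen] = True
    mask = selection.astype(t.dtype).reshape(1, c, 1, 1, 1)
    return MaskedFeatures(values=t * Tensor(mask), selection=selection)


class FeatureGenerator(nn.Module):
    """Upsampling decoder from masked bottleneck features to a fake patch."""

    def __init__(self, in_channels: int, cfg: GenConfig | None = None,
                 norm: str = "instance"):
        cfg = cfg or GenConfig()
        self.cfg = cfg
        self.in_channels = in_channels
        rng = np.random.default_rng(cfg.seed)
        stages = []
        c = in_channels
        for _ in range(cfg.n_upsample_stages):
            c_out = max(4, c // 2)
            stages.append(_UpStage(c, c_out, norm, rng))
            c = c_out
        self.stages = nn.ModuleList(stages)
        self.head = nn.Conv3d(c, 1, kernel=1, rng=rng)

    def __call__(self, mf: MaskedFeatures | Tensor) -> Tensor:
        """Generate a fake patch on [0, 1], shape (N, 1, D*16, H*16, W*16)."""
        h = mf.values if isinstance(mf, MaskedFeatures) else mf
        if h.shape[1] != self.in_channels:
            raise ValueError(f"generator expects {self.in_channels} input channels, "
                             f"got {h.shape[1]}")
        for stage in self.stages:
            h = stage(h)
        return self.head(h).sigmoid()

    def generate(self, mf: MaskedFeatures, patch_shape: tuple[int, int, int]) -> np.ndarray:
        """Inference: a fake (D, H, W) patch matching ``patch_shape``."""
        with nn.no_grad():
            out = self(mf)
        if out.data.shape[2:] != tuple(patch_shape):
            raise ValueError(f"generated shape {out.data.shape[2:]} does not match "
                             f"the requested patch shape {tuple(patch_shape)}")
        return out.data[0, 0]


class _UpStage(nn.Module):
    def __init__(self, c_in: int, c_out: int, norm: str, rng: np.random.Generator):
        self.up = nn.UpConv3d(c_in, c_out, rng=rng)
        self.norm = nn.make_norm(norm, c_out)

    def __call__(self, x: Tensor) -> Tensor:
        return self.norm(self.up(x)).relu()


def build_generator_for(net_cfg: NetConfig, gen_cfg: GenConfig | None = None) -> FeatureGenerator:
    """Generator sized to a discriminator's bottleneck tap."""
    gen_cfg = gen_cfg or GenConfig()
    if gen_cfg.n_upsample_stages != net_cfg.depth:
        raise ValueError("n_upsample_stages must match the discriminator depth")
    in_channels = net_cfg.base_channels * 2 ** (net_cfg.depth - 1)
    return FeatureGenerator(in_channels, gen_cfg, norm=net_cfg.norm)
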