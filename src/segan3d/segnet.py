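"""Improved 3D U-Net: SE-module encoder/decoder with a pyramid-pooling
bottleneck and a (K+1)-class per-voxel head.

The network is a 4-level encoder-decoder.  Every convolution block is an
*SE module*: two 3x3x3 convolutions, the first of which sets resolution
(stride) and channel count, with a squeeze-and-excitation channel
attention applied after the second.  The encoder performs all four
downsamplings with stride-2 convolutions (there is no stride-1 stem: the
very first convolution already halves resolution).  At the
minimum-resolution point a pyramid pooling module pools the feature map
to three sizes (1, 2 and 5 by default), fuses each with a 1x1x1
convolution, upsamples trilinearly and concatenates everything back
before a channel-reducing 1x1x1 convolution.  The decoder mirrors the
encoder with stride-2 transposed convolutions and skip concatenations;
after the final upsampling the original input patch is concatenated
("spliced") before the last convolution to 3 channels with a per-voxel
softmax.

The 3 output classes are background (0), liver (1) and *fake* (2): the
same network doubles as the discriminator of the semi-supervised GAN,
scoring whether a voxel comes from a generated patch.  Two internal taps
are returned by :meth:`SegNet3D.forward`: the pyramid-pooled bottleneck
(the generator's input) and the last hidden decoder features (used by
the feature-matching generator loss).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, concat


BACKGROUND, LIVER, FAKE = 0, 1, 2
CLASS_NAMES = ("background", "liver", "fake")
AXIS_NAMES = ("x", "y", "z")


@dataclass
class NetConfig:
    base_channels: int = 16
    depth: int = 4
    se_reduction_r: int = 4
    pool_sizes: tuple[int, ...] = (1, 2, 5)
    n_classes: int = 3
    norm: str = "instance"
    seed: int = 0

    def __post_init__(self):
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.depth != 4:
            raise ValueError("the architecture is defined with 4 downsampling stages")
        if not self.pool_sizes or any(s < 1 for s in self.pool_sizes):
            raise ValueError("pool_sizes must be non-empty positive ints")
        if self.n_classes != 3:
            raise ValueError("the discriminator head has exactly 3 classes")
        self.pool_sizes = tuple(int(s) for s in self.pool_sizes)

    def to_dict(self) -> dict:
        return {"base_channels": self.base_channels, "depth": self.depth,
                "se_reduction_r": self.se_reduction_r,
                "pool_sizes": list(self.pool_sizes), "n_classes": self.n_classes,
                "norm": self.norm, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        d = dict(d)
        d["pool_sizes"] = tuple(d.get("pool_sizes", (1, 2, 5)))
        return cls(**d)


@dataclass
class FeatureMap:
    """Spatial-last view of an activation array: (D, H, W, C)."""

    values: np.ndarray
    level_tag: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ValueError("FeatureMap requires a 4D (spatial x channels) array")

    @property
    def channels(self) -> int:
        return self.values.shape[-1]


@dataclass
class PredictionMap:
    """Per-voxel class probabilities, spatial x 3, order (background, liver, fake)."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs)
        if self.probs.ndim != 4 or self.probs.shape[-1] != 3:
            raise ValueError("PredictionMap requires shape (D, H, W, 3)")
        sums = self.probs.sum(axis=-1)
        if self.probs.min() < -1e-6 or np.abs(sums - 1.0).max() > 1e-5:
            raise ValueError("probabilities must be non-negative and sum to 1")

    def argmax_mask(self) -> np.ndarray:
        """Binary liver mask: argmax over the two *real* classes.

        The fake class is a training device; its probability mass is
        discarded at inference (the labeled cross entropy constrains only
        the renormalised real-class probabilities, so the raw fake mass
        carries no segmentation information).  Ties break toward
        background.
        """
        cls = np.argmax(self.probs[..., :FAKE], axis=-1)
        return (cls == LIVER).astype(np.uint8)


def tensor_to_feature_map(t: Tensor | np.ndarray, level_tag: str = "") -> FeatureMap:
    """Convert a (1, C, D, H, W) activation tensor to a FeatureMap."""
    arr = t.data if isinstance(t, Tensor) else np.asarray(t)
    if arr.ndim == 5:
        if arr.shape[0] != 1:
            raise ValueError("expected a single-sample activation")
        arr = arr[0]
    return FeatureMap(values=np.moveaxis(arr, 0, -1), level_tag=level_tag)


class SEBlock(nn.Module):
    """Squeeze-and-excitation channel attention.

    Global average pooling (squeeze), a bottleneck of two fully connected
    layers with reduction ``r`` (excitation), and a sigmoid producing one
    weight in (0, 1) per channel which rescales its channel.
    """

    def __init__(self, channels: int, r: int, rng: np.random.Generator):
        hidden = max(1, channels // r)
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)
        self.hidden = hidden

    def weights(self, x: Tensor) -> Tensor:
        z = F.global_avg_pool3d(x)            # (N, C)
        z = self.fc1(z).relu()
        return self.fc2(z).sigmoid()          # (N, C) in (0, 1)

    def __call__(self, x: Tensor) -> Tensor:
        w = self.weights(x)
        n, c = w.shape
        return x * w.reshape(n, c, 1, 1, 1)


def se_weights(f, se: SEBlock) -> np.ndarray:
    """Per-channel SE weights for a feature map (inference helper)."""
    if isinstance(f, FeatureMap):
        arr = np.moveaxis(f.values, -1, 0)[None]
    elif isinstance(f, Tensor):
        arr = f.data
    else:
        arr = np.asarray(f)
        if arr.ndim == 4:  # spatial x C
            arr = np.moveaxis(arr, -1, 0)[None]
    with nn.no_grad():
        return se.weights(Tensor(arr.astype(np.float32))).data[0]


class SEModule(nn.Module):
    """Two 3x3x3 convolutions; the first sets stride/width, the second is
    followed by SE channel weighting, a Scale, and a ReLU."""

    def __init__(self, c_in: int, c_out: int, stride: int, cfg: NetConfig,
                 rng: np.random.Generator):
        if stride not in (1, 2):
            raise ValueError("SEModule stride must be 1 or 2")
        self.stride = stride
        self.conv1 = nn.Conv3d(c_in, c_out, kernel=3, stride=stride, rng=rng)
        self.norm1 = nn.make_norm(cfg.norm, c_out)
        self.conv2 = nn.Conv3d(c_out, c_out, kernel=3, stride=1, rng=rng)
        self.norm2 = nn.make_norm(cfg.norm, c_out)
        self.se = SEBlock(c_out, cfg.se_reduction_r, rng)

    def __call__(self, x: Tensor) -> Tensor:
        if self.stride == 2:
            for ax, s in zip(AXIS_NAMES, x.shape[2:]):
                if s % 2:
                    raise ValueError(f"spatial axis {ax} (size {s}) not divisible "
                                     f"by stride 2")
        h = self.norm1(self.conv1(x)).relu()
        h = self.norm2(self.conv2(h))
        return self.se(h).relu()


class PyramidPooling(nn.Module):
    """Multi-scale context at the bottleneck: parallel adaptive average
    poolings (default output sizes 1, 2 and 5), each fused by a 1x1x1
    convolution and trilinearly upsampled, concatenated with the input,
    then reduced back to the input width by a final 1x1x1 convolution."""

    def __init__(self, channels: int, cfg: NetConfig, rng: np.random.Generator):
        self.pool_sizes = cfg.pool_sizes
        branch_ch = max(1, channels // 4)
        self.branch_convs = nn.ModuleList(
            [nn.Conv3d(channels, branch_ch, kernel=1, rng=rng)
             for _ in cfg.pool_sizes])
        fused = channels + branch_ch * len(cfg.pool_sizes)
        self.fuse = nn.Conv3d(fused, channels, kernel=1, rng=rng)
        self.norm = nn.make_norm(cfg.norm, channels)

    def __call__(self, x: Tensor) -> Tensor:
        spatial = x.shape[2:]
        outs = [x]
        for size, conv in zip(self.pool_sizes, self.branch_convs):
            pooled = F.adaptive_avg_pool3d(x, (size, size, size))
            outs.append(F.upsample_trilinear3d(conv(pooled), spatial))
        return self.norm(self.fuse(concat(outs, axis=1))).relu()


class _DecoderGroup(nn.Module):
    def __init__(self, c_in: int, c_skip: int, cfg: NetConfig,
                 rng: np.random.Generator):
        c_out = c_in // 2
        self.up = nn.UpConv3d(c_in, c_out, rng=rng)
        self.up_norm = nn.make_norm(cfg.norm, c_out)
        self.mod1 = SEModule(c_out + c_skip, c_out, 1, cfg, rng)
        self.mod2 = SEModule(c_out, c_out, 1, cfg, rng)

    def __call__(self, x: Tensor, skip: Tensor) -> Tensor:
        h = self.up_norm(self.up(x)).relu()
        h = concat([h, skip], axis=1)
        return self.mod2(self.mod1(h))


class SegNet3D(nn.Module):
    """The improved 3D U-Net / (K+1)-class discriminator."""

    def __init__(self, cfg: NetConfig | None = None):
        cfg = cfg or NetConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        b = cfg.base_channels
        widths = [b * 2 ** i for i in range(cfg.depth)]          # b, 2b, 4b, 8b

        groups = []
        c_in = 1
        for w in widths:
            groups.append(_EncoderGroup(c_in, w, cfg, rng))
            c_in = w
        self.encoder = nn.ModuleList(groups)
        self.pyramid = PyramidPooling(widths[-1], cfg, rng)
        self.decoder = nn.ModuleList(
            [_DecoderGroup(widths[i + 1], widths[i], cfg, rng)
             for i in reversed(range(cfg.depth - 1))])           # 8b->4b->2b->b
        self.final_up = nn.UpConv3d(b, b, rng=rng)
        self.final_norm = nn.make_norm(cfg.norm, b)
        # per-voxel linear classifier over spliced features, as in U-Net
        self.head = nn.Conv3d(b + 1, cfg.n_classes, kernel=1, rng=rng)

    # -- shape contract -------------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        div = 2 ** self.cfg.depth
        for ax, s in zip(AXIS_NAMES, x.shape[2:]):
            if s % div:
                raise ValueError(f"spatial axis {ax} has size {s}, which is not "
                                 f"divisible by {div}")

    @staticmethod
    def _as_batch(patch) -> Tensor:
        if isinstance(patch, Tensor):
            t = patch
        else:
            arr = np.asarray(patch, dtype=np.float32)
            if arr.ndim == 3:
                arr = arr[None, None]
            elif arr.ndim == 4:
                arr = arr[:, None]
            t = Tensor(arr)
        if t.ndim != 5:
            raise ValueError("input must be (D,H,W), (N,D,H,W) or (N,1,D,H,W)")
        return t

    def forward(self, patch) -> tuple[Tensor, dict[str, Tensor]]:
        """Run the network on [0,1]-scaled input.

        Returns per-voxel class probabilities of shape (N, 3, D, H, W) and
        the two internal taps ``bottleneck`` (pyramid-pooled encoder
        output) and ``feature_match`` (last hidden decoder features).
        """
        x = self._as_batch(patch)
        self._check_input(x.data)
        skips = []
        h = x
        for group in self.encoder:
            h = group(h)
            skips.append(h)
        h = self.pyramid(h)
        bottleneck = h
        for group, skip in zip(self.decoder, reversed(skips[:-1])):
            h = group(h, skip)
        h = self.final_norm(self.final_up(h)).relu()
        feature_match = h
        h = concat([h, x], axis=1)
        logits = self.head(h)
        probs = F.softmax_channels(logits)
        return probs, {"bottleneck": bottleneck, "feature_match": feature_match}

    __call__ = forward

    def predict_probs(self, patch: np.ndarray) -> PredictionMap:
        """Inference on one [0,1] patch; returns a spatial-last PredictionMap."""
        with nn.no_grad():
            probs, _ = self.forward(patch)
        return PredictionMap(probs=np.moveaxis(probs.data[0], 0, -1))

    @property
    def bottleneck_channels(self) -> int:
        return self.cfg.base_channels * 2 ** (self.cfg.depth - 1)


class _EncoderGroup(nn.Module):
    """Two SE modules; the first downsamples (stride 2) and widens."""

    def __init__(self, c_in: int, c_out: int, cfg: NetConfig,
                 rng: np.random.Generator):
        self.mod1 = SEModule(c_in, c_out, 2, cfg, rng)
        self.mod2 = SEModule(c_out, c_out, 1, cfg, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.mod2(self.mod1(x))
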