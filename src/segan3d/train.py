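"""Alternating adversarial optimisation and whole-volume inference.

Each iteration performs one discriminator update followed by one
generator update (a 1:1 schedule; configurable):

* **Discriminator step** — a labeled patch, an unlabeled patch (when
  available) and a freshly generated fake patch are pushed through the
  segmentation network in one batch; the three loss terms are summed and
  one Adam step is applied to the discriminator only.  The fake patch is
  generated with the current generator but treated as a constant, so no
  gradient reaches the generator.
* **Generator step** — an unlabeled patch is pushed through the (frozen)
  discriminator to tap its mean features and bottleneck; a random
  channel subset of the bottleneck drives the generator, whose fake
  patch is scored by the discriminator again; the feature-matching loss
  is backpropagated through the discriminator *into the generator*, and
  one Adam step is applied to the generator only.

Training monitors the validation Dice every ``val_every`` steps and
keeps the best-scoring parameters; it stops at ``max_steps``, after
``patience`` validations without improvement, or once an optional
training-set Dice target is reached.  Defaults follow the adversarial
recipe: Adam, discriminator lr 1e-4, generator lr 3e-4, batch size 1.

Everything is driven by numpy generators seeded from one integer, so
runs are bit-reproducible (``deterministic_mode`` records this contract).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .generator import FeatureGenerator, GenConfig, build_generator_for, select_feature_subset
from .losses import LossReport, fake_loss, generator_loss, labeled_loss, unlabeled_loss
from .metrics import BinaryMaskPair, dice
from .nn.tensor import Tensor
from .phantom import DatasetManifest
from .preprocess import (GrayVolume, extract_patches, hu_to_gray, read_ct_volume,
                         stitch_patches, to_network_input)
from .segnet import NetConfig, SegNet3D


@dataclass
class TrainConfig:
    lr_discriminator: float = 1e-4
    lr_generator: float = 3e-4
    batch_size: int = 1
    max_steps: int = 2000
    val_every: int = 25
    patience: int = 20
    stop_train_dice: float | None = None
    d_steps_per_g_step: int = 1
    seed: int = 0
    deterministic_mode: bool = True
    patch_shape: tuple[int, int, int] | None = None

    def __post_init__(self):
        if self.lr_discriminator <= 0 or self.lr_generator <= 0:
            raise ValueError("learning rates must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainState:
    net: SegNet3D
    gen: FeatureGenerator
    opt_d: nn.Adam
    opt_g: nn.Adam
    rng: np.random.Generator
    keep_fraction: float = 0.5
    step: int = 0
    best_val_dice: float = -1.0
    best_step: int = -1
    loss_history: list[LossReport] = field(default_factory=list)
    val_history: list[tuple[int, float]] = field(default_factory=list)
    train_dice_history: list[tuple[int, float]] = field(default_factory=list)
    _best_params: dict | None = None

    def snapshot_best(self, val_dice: float) -> None:
        if val_dice > self.best_val_dice:
            self.best_val_dice = val_dice
            self.best_step = self.step
            self._best_params = {"d": self.net.state_dict(),
                                 "g": self.gen.state_dict()}

    def restore_best(self) -> None:
        if self._best_params is not None:
            self.net.load_state_dict(self._best_params["d"])
            self.gen.load_state_dict(self._best_params["g"])


def init_state(net_cfg: NetConfig, gen_cfg: GenConfig, train_cfg: TrainConfig) -> TrainState:
    net = SegNet3D(net_cfg)
    gen = build_generator_for(net_cfg, gen_cfg)
    return TrainState(net=net, gen=gen,
                      opt_d=nn.Adam(net.parameters(), lr=train_cfg.lr_discriminator),
                      opt_g=nn.Adam(gen.parameters(), lr=train_cfg.lr_generator),
                      rng=np.random.default_rng(train_cfg.seed),
                      keep_fraction=gen_cfg.keep_fraction)


# -- single optimisation steps -------------------------------------------------

def make_fake_patch(state: TrainState, source_x: np.ndarray) -> np.ndarray:
    """Generate a fake patch from a real patch's bottleneck features.

    Runs without graph recording: the result is a constant input for the
    discriminator step.
    """
    with nn.no_grad():
        _, taps = state.net.forward(source_x)
        mf = select_feature_subset(taps["bottleneck"], state.keep_fraction, state.rng)
        fake = state.gen(mf)
    return fake.data[0, 0]


def discriminator_step(state: TrainState, labeled_x: np.ndarray, labeled_y: np.ndarray,
                       unlabeled_x: np.ndarray | None) -> LossReport:
    """One Adam update of the discriminator on L_labeled + L_unlabeled + L_fake.

    Generator parameters are untouched (the fake patch enters as a
    constant).  With no unlabeled patch the unlabeled term contributes 0.
    """
    fake_x = make_fake_patch(state, unlabeled_x if unlabeled_x is not None else labeled_x)
    stack = [labeled_x, unlabeled_x, fake_x] if unlabeled_x is not None \
        else [labeled_x, fake_x]
    batch = Tensor(np.stack(stack).astype(np.float32)[:, None])

    state.opt_d.zero_grad()
    state.gen.zero_grad()
    probs, _ = state.net.forward(batch)
    l_lab = labeled_loss(probs[0:1], labeled_y[None])
    l_unl = unlabeled_loss(probs[1:2]) if unlabeled_x is not None else None
    l_fake = fake_loss(probs[-1:])
    total = l_lab + l_unl + l_fake if l_unl is not None else l_lab + l_fake
    if not np.isfinite(total.item()):
        raise FloatingPointError(
            f"non-finite discriminator loss: labeled={l_lab.item()}, "
            f"unlabeled={'0' if l_unl is None else l_unl.item()}, fake={l_fake.item()}")
    total.backward()
    state.opt_d.step()
    return LossReport(labeled=l_lab.item(),
                      unlabeled=0.0 if l_unl is None else l_unl.item(),
                      fake=l_fake.item())


def generator_step(state: TrainState, unlabeled_x: np.ndarray) -> float:
    """One Adam update of the generator on the feature-matching loss.

    The discriminator is used for feature tapping only; its parameters
    are bit-identical before and after.
    """
    with nn.no_grad():
        _, taps_real = state.net.forward(unlabeled_x)
        real_feat = Tensor(taps_real["feature_match"].data.copy())
        bottleneck = Tensor(taps_real["bottleneck"].data.copy())
    state.opt_g.zero_grad()
    state.net.zero_grad()
    mf = select_feature_subset(bottleneck, state.keep_fraction, state.rng)
    fake = state.gen(mf)
    _, taps_fake = state.net.forward(fake)
    g_loss = generator_loss(real_feat, taps_fake["feature_match"])
    val = g_loss.item()
    if not np.isfinite(val):
        raise FloatingPointError(f"non-finite generator loss: {val}")
    g_loss.backward()
    state.opt_g.step()
    return val


# -- data loading --------------------------------------------------------------

def _net_patch_shape(shape: tuple[int, int, int], divisor: int = 16) -> tuple[int, ...]:
    return tuple(int(math.ceil(s / divisor) * divisor) for s in shape)


def load_training_arrays(manifest: DatasetManifest, ids: list[str],
                         with_labels: bool,
                         patch_shape: tuple[int, int, int] | None = None):
    """Read, window and patch the samples for the given ids.

    Returns a list of (input_patch, label_patch-or-None) pairs with the
    inputs on the [0, 1] network scale.  Volumes whose extent is not a
    multiple of the patch shape are zero-padded by the patcher.
    """
    out = []
    for sid in ids:
        vol = read_ct_volume(manifest.image_path(sid))
        gray = hu_to_gray(vol)
        x = to_network_input(gray)
        pshape = patch_shape or _net_patch_shape(x.shape)
        xs = extract_patches(x, pshape)
        if with_labels:
            lbl = read_ct_volume(manifest.label_path(sid)).values.astype(np.uint8)
            ys = extract_patches(lbl, pshape)
            out.extend((xp, yp) for xp, yp in zip(xs.patches, ys.patches))
        else:
            out.extend((xp, None) for xp in xs.patches)
    return out


def _volume_dice(state: TrainState, manifest: DatasetManifest, ids: list[str],
                 patch_shape=None) -> float:
    scores = []
    for sid in ids:
        vol = read_ct_volume(manifest.image_path(sid))
        gray = hu_to_gray(vol)
        pred = predict(gray, state, patch_shape=patch_shape)
        truth = read_ct_volume(manifest.label_path(sid)).values.astype(np.uint8)
        scores.append(dice(BinaryMaskPair(a=truth, b=pred, spacing=vol.spacing)))
    return float(np.mean(scores)) if scores else float("nan")


# -- the full loop -------------------------------------------------------------

def fit(manifest: DatasetManifest, net_cfg: NetConfig | None = None,
        gen_cfg: GenConfig | None = None, train_cfg: TrainConfig | None = None,
        log_path=None) -> TrainState:
    """Train discriminator and generator on a phantom/CT dataset manifest."""
    net_cfg = net_cfg or NetConfig()
    gen_cfg = gen_cfg or GenConfig()
    train_cfg = train_cfg or TrainConfig()
    if not manifest.labeled_ids:
        raise ValueError("training requires at least one labeled sample")
    if not manifest.val_ids:
        raise ValueError("training requires at least one validation sample")

    labeled = load_training_arrays(manifest, manifest.labeled_ids, True,
                                   train_cfg.patch_shape)
    unlabeled = load_training_arrays(manifest, manifest.unlabeled_ids, False,
                                     train_cfg.patch_shape)
    state = init_state(net_cfg, gen_cfg, train_cfg)
    order_rng = np.random.default_rng(train_cfg.seed + 1)

    log_rows = [LossReport.CSV_HEADER]
    bad_validations = 0
    lab_order: list[int] = []
    unl_order: list[int] = []
    for step in range(train_cfg.max_steps):
        state.step = step
        if not lab_order:
            lab_order = list(order_rng.permutation(len(labeled)))
        if unlabeled and not unl_order:
            unl_order = list(order_rng.permutation(len(unlabeled)))
        xl, yl = labeled[lab_order.pop()]
        xu = unlabeled[unl_order.pop()][0] if unlabeled else None

        report = discriminator_step(state, xl, yl, xu)
        if (step + 1) % train_cfg.d_steps_per_g_step == 0:
            report.generator = generator_step(state, xu if xu is not None else xl)
        state.loss_history.append(report)
        log_rows.append(report.csv_row(step))

        if (step + 1) % train_cfg.val_every == 0:
            val_dice = _volume_dice(state, manifest, manifest.val_ids,
                                    train_cfg.patch_shape)
            train_dice = _volume_dice(state, manifest, manifest.labeled_ids,
                                      train_cfg.patch_shape)
            state.val_history.append((step, val_dice))
            state.train_dice_history.append((step, train_dice))
            improved = val_dice > state.best_val_dice
            state.snapshot_best(val_dice)
            bad_validations = 0 if improved else bad_validations + 1
            if (train_cfg.stop_train_dice is not None
                    and train_dice >= train_cfg.stop_train_dice):
                break
            if bad_validations >= train_cfg.patience:
                break

    state.restore_best()
    if log_path is not None:
        Path(log_path).write_text("\n".join(log_rows) + "\n")
    return state


# -- inference -----------------------------------------------------------------

def predict(vol: GrayVolume | np.ndarray, state: TrainState | SegNet3D,
            patch_shape: tuple[int, int, int] | None = None) -> np.ndarray:
    """Segment a whole gray volume: patch, forward, argmax, stitch.

    The fake class is a training device only; its probability mass is
    discarded and each voxel takes the argmax over the two real classes,
    so the output is binary.
    """
    net = state.net if isinstance(state, TrainState) else state
    if isinstance(vol, GrayVolume):
        x = to_network_input(vol)
    else:
        x = np.asarray(vol, dtype=np.float32)
        if x.size and x.max() > 1.0:
            x = x / 255.0
    pshape = patch_shape or _net_patch_shape(x.shape)
    ps = extract_patches(x, pshape)
    masks = []
    for patch in ps.patches:
        pm = net.predict_probs(patch)
        masks.append(pm.argmax_mask())
    ps_masks = type(ps)(patches=masks, placements=ps.placements,
                        pad_record=ps.pad_record, source_shape=ps.source_shape,
                        patch_shape=ps.patch_shape)
    return stitch_patches(ps_masks, x.shape)


# -- checkpointing -------------------------------------------------------------

def save_checkpoint(path, state: TrainState, net_cfg: NetConfig,
                    gen_cfg: GenConfig) -> None:
    """Self-describing checkpoint: all parameters plus both configs."""
    arrays = {f"d.{k}": v for k, v in state.net.state_dict().items()}
    arrays.update({f"g.{k}": v for k, v in state.gen.state_dict().items()})
    meta = json.dumps({"net": net_cfg.to_dict(), "gen": gen_cfg.to_dict(),
                       "step": state.step, "best_val_dice": state.best_val_dice})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[SegNet3D, FeatureGenerator, NetConfig, GenConfig]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        net_cfg = NetConfig.from_dict(meta["net"])
        gen_cfg = GenConfig.from_dict(meta["gen"])
        net = SegNet3D(net_cfg)
        gen = build_generator_for(net_cfg, gen_cfg)
        net.load_state_dict({k[2:]: data[k] for k in data.files if k.startswith("d.")})
        gen.load_state_dict({k[2:]: data[k] for k in data.files if k.startswith("g.")})
    return net, gen, net_cfg, gen_cfg
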