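"""Training recipe: Gaussian weight initialization, SGD with momentum and
weight decay, polynomial learning-rate decay, random subvolume sampling
with in-slice rotation augmentation, and softmax cross-entropy loss.

The recipe follows the volumetric dense-network convention: the optimizer
is plain SGD (batch size 4, weight decay 5e-4, momentum 0.05), the base
learning rate 0.05 decays as ``base_lr * (1 - iter/max_iter)**0.9`` over
40000 iterations, and training samples are 32^3 subvolumes cropped at
random from the training volumes.  A step schedule (divide by 10 every 50
epochs) is available behind a config switch; the poly policy is the
default.  Desk-scale parameter choices for tests live with the tests, not
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .msdensenet import MSDenseNet
from .volio import ROTATION_AXES


@dataclass
class TrainConfig:
    batch_size: int = 4
    weight_decay: float = 0.0005
    momentum: float = 0.05
    base_lr: float = 0.05
    poly_power: float = 0.9
    max_iterations: int = 40000
    init_sigma: float = 0.01
    subvolume_size: int = 32
    #: probability that a sampled patch is centered on a foreground voxel
    p_foreground: float = 0.5
    #: probability that a sampled patch is rotation-augmented
    p_augment: float = 0.5
    #: iterations between validation passes; 0 disables validation
    validation_interval: int = 0
    #: "poly" (default) or "step" (divide by 10 every step_epochs epochs)
    lr_schedule: str = "poly"
    step_epochs: int = 50
    #: defines one epoch for the step schedule with random patch sampling
    patches_per_volume: int = 8
    seed: int = 0

    def validate(self):
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.poly_power <= 0:
            raise ValueError("poly_power must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.lr_schedule not in ("poly", "step"):
            raise ValueError("lr_schedule must be 'poly' or 'step'")
        return self


@dataclass
class LossCurve:
    """Per-iteration training loss and periodic validation loss (nats/voxel)."""

    train_loss: list = field(default_factory=list)
    val_iterations: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"iteration": np.arange(1, len(self.train_loss) + 1),
                           "train_loss": self.train_loss})
        val = pd.Series(np.nan, index=df.index)
        for it, v in zip(self.val_iterations, self.val_loss):
            val.iloc[it - 1] = v
        df["val_loss"] = val
        return df

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def poly_lr(iteration: int, cfg: TrainConfig) -> float:
    """``base_lr * (1 - iteration/max_iterations) ** poly_power``."""
    if not 0 <= iteration <= cfg.max_iterations:
        raise ValueError(f"iteration {iteration} outside [0, {cfg.max_iterations}]")
    return cfg.base_lr * (1.0 - iteration / cfg.max_iterations) ** cfg.poly_power


def step_lr(iteration: int, cfg: TrainConfig, n_train_volumes: int) -> float:
    """Step schedule: base_lr divided by 10 every ``step_epochs`` epochs.

    With random patch sampling one epoch is defined as
    ``ceil(n_train * patches_per_volume / batch_size)`` iterations.
    """
    iters_per_epoch = max(1, int(np.ceil(
        n_train_volumes * cfg.patches_per_volume / cfg.batch_size)))
    epoch = iteration // iters_per_epoch
    return cfg.base_lr * 10.0 ** (-(epoch // cfg.step_epochs))


def init_weights(net: MSDenseNet, cfg: TrainConfig, seed: int) -> MSDenseNet:
    """Draw every convolution weight i.i.d. N(0, init_sigma); BN scale 1,
    shift 0; biases 0.  Reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    for name, p in net.parameters():
        if name.endswith(".weight"):
            p.data = (rng.normal(0.0, cfg.init_sigma, size=p.data.shape)
                      .astype(p.data.dtype))
        elif name.endswith(".gamma"):
            p.data = np.ones_like(p.data)
        else:  # beta, bias
            p.data = np.zeros_like(p.data)
    for bn in net.batchnorms():
        bn.running_mean[:] = 0.0
        bn.running_var[:] = 1.0
    return net


def sample_subvolume(volume, mask, rng, size: int = 32, p_fg: float = 0.5):
    """Crop an aligned (patch, label) pair of shape ``size^3``.

    With probability ``p_fg`` the patch center lies on a foreground voxel of
    ``mask``; otherwise the center is uniform over all voxels.  In both
    cases the origin is clamped so the patch stays inside the volume —
    sampling centers rather than origins keeps border voxels covered at a
    rate comparable to interior voxels (a uniform *origin* would cover a
    corner voxel orders of magnitude less often).
    """
    vd = volume.data if hasattr(volume, "data") else np.asarray(volume)
    md = mask.data if hasattr(mask, "data") else np.asarray(mask)
    shape = np.asarray(vd.shape)
    if np.any(shape < size):
        raise ValueError(f"volume shape {tuple(shape)} smaller than patch {size}")
    fg = None
    if p_fg > 0 and rng.random() < p_fg:
        fg = np.argwhere(md > 0)
    if fg is not None and len(fg):
        center = fg[rng.integers(len(fg))]
    else:
        center = np.array([rng.integers(0, s) for s in shape])
    origin = np.clip(center - size // 2, 0, shape - size)
    sl = tuple(slice(int(o), int(o + size)) for o in origin)
    return vd[sl], md[sl]


def cross_entropy_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean over voxels of -log p(true class), in nats per voxel.

    ``probabilities`` has a class axis 1 of per-voxel probabilities summing
    to one; ``labels`` holds integer class indices without that axis.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    lab = np.asarray(labels)
    if p.ndim != lab.ndim + 1 or p.shape[:1] + p.shape[2:] != lab.shape:
        raise ValueError(f"shape mismatch: probabilities {p.shape} vs labels {lab.shape}")
    ptrue = np.take_along_axis(p, lab[:, None].astype(np.int64), axis=1)
    return float(-np.log(np.maximum(ptrue, 1e-12)).mean())


class SGD:
    """SGD with classical momentum and L2 weight decay."""

    def __init__(self, params, momentum, weight_decay):
        self.params = list(params)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for _, p in self.params]

    def step(self, lr):
        for (name, p), v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= (lr * v).astype(p.data.dtype)
            p.grad = None


def _augment(patch, label, rng):
    k = int(rng.integers(1, 4))  # 90, 180 or 270 degrees
    return (np.ascontiguousarray(np.rot90(patch, k, axes=ROTATION_AXES)),
            np.ascontiguousarray(np.rot90(label, k, axes=ROTATION_AXES)))


def train(net: MSDenseNet, train_pairs, cfg: TrainConfig, val_pairs=None,
          checkpoint_path=None, initialize=True, log=None):
    """Run the full SGD recipe; returns ``(net, LossCurve)``.

    ``train_pairs``/``val_pairs`` are sequences of (VolumeImage, LabelMask).
    Each iteration draws ``batch_size`` random subvolumes (foreground-biased
    with probability ``p_foreground``), rotates each by a random in-slice
    right angle with probability ``p_augment``, and takes one SGD step at
    the scheduled learning rate.  Validation (if enabled) computes the
    cross-entropy of full-volume fused predictions on held-out pairs.
    A non-finite loss aborts with a diagnostic.
    """
    cfg.validate()
    if not train_pairs:
        raise ValueError("empty training set")
    if initialize:
        init_weights(net, cfg, cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = SGD(net.parameters(), cfg.momentum, cfg.weight_decay)
    curve = LossCurve()
    size = cfg.subvolume_size
    for it in range(cfg.max_iterations):
        xs, ys = [], []
        for _ in range(cfg.batch_size):
            vi = rng.integers(len(train_pairs))
            patch, label = sample_subvolume(train_pairs[vi][0], train_pairs[vi][1],
                                            rng, size, cfg.p_foreground)
            if rng.random() < cfg.p_augment:
                patch, label = _augment(patch, label, rng)
            xs.append(patch)
            ys.append(label)
        x = np.stack(xs)[:, None].astype(np.float32)
        y = np.stack(ys).astype(np.int64)
        logits = net.forward(x, train=True, rng=rng)
        loss = nn.softmax_cross_entropy(logits, y)
        lv = float(loss.data)
        if not np.isfinite(lv):
            raise FloatingPointError(
                f"non-finite training loss at iteration {it + 1} "
                f"(lr={_lr(it, cfg, len(train_pairs)):.3g}); aborting")
        loss.backward()
        lr = _lr(it, cfg, len(train_pairs))
        opt.step(lr)
        curve.train_loss.append(lv)
        if log is not None and ((it + 1) % max(1, cfg.max_iterations // 20) == 0
                                or it == 0):
            log(f"iter {it + 1}/{cfg.max_iterations} lr={lr:.4f} "
                f"loss={lv:.4f} seed={cfg.seed}")
        if (cfg.validation_interval and val_pairs
                and (it + 1) % cfg.validation_interval == 0):
            curve.val_iterations.append(it + 1)
            curve.val_loss.append(validation_loss(net, val_pairs))
    if checkpoint_path is not None:
        net.save(checkpoint_path)
    return net, curve


def _lr(iteration, cfg, n_train):
    if cfg.lr_schedule == "poly":
        return poly_lr(iteration, cfg)
    return step_lr(iteration, cfg, n_train)


def validation_loss(net, val_pairs, stride=None):
    """Cross-entropy of fused full-volume predictions on held-out pairs."""
    from .inference import predict_volume  # deferred: circular import
    losses = []
    for vol, mask in val_pairs:
        _, prob = predict_volume(net, vol, patch=net.cfg.subvolume_size,
                                 stride=stride or net.cfg.subvolume_size)
        p = np.stack([1.0 - prob.data, prob.data])[None]
        losses.append(cross_entropy_loss(p, mask.data[None].astype(np.int64)))
    return float(np.mean(losses))
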