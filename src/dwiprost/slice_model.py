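"""Slice-level classifier: a fully pre-activated bottleneck residual network.

The default architecture is 41 weighted layers deep: a 7x7/stride-2 stem
convolution, a 3x3 max pool, four bottleneck blocks at widths
(64, 64, 256), nine at (128, 128, 512), a 7x7 average pool, dropout and a
fully connected softmax head over the two classes (tumor slice / no
tumor). Every bottleneck applies (BN -> ReLU -> conv) three times on the
residual branch (1x1 reduce, 3x3, 1x1 expand); the output is ``F(x) + x``
when shapes match, or ``F(x) + W_s x`` through a 1x1 projection when the
block changes width or resolution.

Because each network's weights start from a different random draw, five
independently trained replicas ("stacked generalization") capture
slightly different slice evidence; their probability outputs are the raw
material for the patient-level classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import nn
from .nn import (AvgPool2d, BatchNorm2d, Conv2d, Dropout, Linear, MaxPool2d,
                 Module, Param, ReLU, ReduceLROnPlateau, SGD, conv_out_size,
                 cross_entropy, softmax)


@dataclass
class ArchitectureConfig:
    """Structure of the slice classifier.

    The default values give the 41-weighted-layer network:
    1 stem conv + 3x4 + 3x9 block convs + 1 fully connected = 41
    (projection shortcuts, pooling, BN and dropout carry no count).
    """

    in_channels: int = 6
    in_size: int = 66
    stem_filters: int = 64
    stem_kernel: int = 7
    stem_stride: int = 2
    block1_width: int = 64     # bottleneck base width; expansion x4 -> 256
    block1_repeats: int = 4
    block2_width: int = 128    # expansion x4 -> 512
    block2_repeats: int = 9
    expansion: int = 4
    avgpool: int = 7
    dropout_rate: float = 0.90
    hidden_units: int = 0      # optional hidden FC layer before the head
    n_classes: int = 2

    def __post_init__(self):
        if min(self.stem_filters, self.block1_width, self.block2_width,
               self.block1_repeats, self.block2_repeats) < 1:
            raise ValueError("widths and repeats must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class TrainingConfig:
    """SGD hyperparameters for one network."""

    lr0: float = 0.001
    plateau_factor: float = 10.0
    plateau_patience: int = 5
    batch_size: int = 8
    weight_decay: float = 1e-6
    momentum: float = 0.90
    max_epochs: int = 100
    seed: int = 0
    class_weighting: bool = False

    def __post_init__(self):
        if self.lr0 <= 0 or self.batch_size < 1:
            raise ValueError("lr0 must be positive and batch_size >= 1")


def reduced_architecture(dropout_rate: float = 0.25) -> ArchitectureConfig:
    """A narrow single-repeat variant (8 weighted layers) for CPU-scale runs."""
    return ArchitectureConfig(stem_filters=16, block1_width=16, block1_repeats=1,
                              block2_width=32, block2_repeats=1,
                              dropout_rate=dropout_rate)


@dataclass
class SliceProbability:
    """Softmax output of one network for one slice: p (PCa) + n = 1."""

    patient_id: str
    slice_index: int
    p: float
    n: float


class PreActBottleneck(Module):
    """Three-convolution residual unit with full pre-activation.

    Residual branch: (BN -> ReLU -> 1x1 conv w) -> (BN -> ReLU -> 3x3 conv
    w, stride s) -> (BN -> ReLU -> 1x1 conv 4w). Shortcut: identity when
    the input already has 4w channels and stride 1, else a 1x1 projection
    convolution (not counted as a weighted layer).
    """

    def __init__(self, in_ch: int, width: int, stride: int = 1,
                 expansion: int = 4, rng: Optional[np.random.Generator] = None):
        out_ch = width * expansion
        self.bn1, self.relu1 = BatchNorm2d(in_ch), ReLU()
        self.conv1 = Conv2d(in_ch, width, 1, rng=rng)
        self.bn2, self.relu2 = BatchNorm2d(width), ReLU()
        self.conv2 = Conv2d(width, width, 3, stride=stride, rng=rng)
        self.bn3, self.relu3 = BatchNorm2d(width), ReLU()
        self.conv3 = Conv2d(width, out_ch, 1, rng=rng)
        self.proj = None
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng,
                               is_projection=True)
        self.out_ch = out_ch

    def forward(self, x, train):
        f = self.bn1.forward(x, train)
        f = self.relu1.forward(f, train)
        f = self.conv1.forward(f, train)
        f = self.bn2.forward(f, train)
        f = self.relu2.forward(f, train)
        f = self.conv2.forward(f, train)
        f = self.bn3.forward(f, train)
        f = self.relu3.forward(f, train)
        f = self.conv3.forward(f, train)
        short = x if self.proj is None else self.proj.forward(x, train)
        return f + short

    def backward(self, gout):
        gshort = gout if self.proj is None else self.proj.backward(gout)
        g = self.conv3.backward(gout)
        g = self.relu3.backward(g)
        g = self.bn3.backward(g)
        g = self.conv2.backward(g)
        g = self.relu2.backward(g)
        g = self.bn2.backward(g)
        g = self.conv1.backward(g)
        g = self.relu1.backward(g)
        g = self.bn1.backward(g)
        return g + gshort


class ResNet(Module):
    """Pre-activation bottleneck ResNet for 6-channel 66x66 slice stacks."""

    def __init__(self, config: ArchitectureConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        c = config
        self.config = c
        self.stem = Conv2d(c.in_channels, c.stem_filters, c.stem_kernel,
                           stride=c.stem_stride, rng=rng)
        self.maxpool = MaxPool2d(3, stride=2, pad=1)
        blocks: List[PreActBottleneck] = []
        in_ch = c.stem_filters
        for r in range(c.block1_repeats):
            blocks.append(PreActBottleneck(in_ch, c.block1_width, 1, c.expansion, rng))
            in_ch = blocks[-1].out_ch
        for r in range(c.block2_repeats):
            stride = 2 if r == 0 else 1  # downsample entering block 2
            blocks.append(PreActBottleneck(in_ch, c.block2_width, stride, c.expansion, rng))
            in_ch = blocks[-1].out_ch
        self.blocks = blocks
        self.final_bn, self.final_relu = BatchNorm2d(in_ch), ReLU()
        self.avgpool = AvgPool2d(c.avgpool)
        self.dropout = Dropout(c.dropout_rate, rng=np.random.default_rng(rng.integers(2**31)))
        size = conv_out_size(c.in_size, c.stem_kernel, c.stem_stride, (c.stem_kernel - 1) // 2)
        size = conv_out_size(size, 3, 2, 1)          # maxpool
        size = conv_out_size(size, 3, 2, 1)          # block-2 stride
        pooled = conv_out_size(size, min(c.avgpool, size), c.avgpool, 0)
        if size < 2 or pooled < 1:
            raise ValueError("input size too small for the pooling cascade")
        feat = in_ch * pooled * pooled
        if c.hidden_units:
            self.hidden = Linear(feat, c.hidden_units, rng=rng)
            self.hidden_relu = ReLU()
            feat = c.hidden_units
        else:
            self.hidden = None
        self.fc = Linear(feat, c.n_classes, rng=rng)
        self._flat_shape = None

    def forward(self, x, train=False):
        h = self.stem.forward(x, train)
        h = self.maxpool.forward(h, train)
        for blk in self.blocks:
            h = blk.forward(h, train)
        h = self.final_bn.forward(h, train)
        h = self.final_relu.forward(h, train)
        h = self.avgpool.forward(h, train)
        self._flat_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        h = self.dropout.forward(h, train)
        if self.hidden is not None:
            h = self.hidden_relu.forward(self.hidden.forward(h, train), train)
        return self.fc.forward(h, train)

    def backward(self, gout):
        g = self.fc.backward(gout)
        if self.hidden is not None:
            g = self.hidden.backward(self.hidden_relu.backward(g))
        g = self.dropout.backward(g)
        g = g.reshape(self._flat_shape)
        g = self.avgpool.backward(g)
        g = self.final_relu.backward(g)
        g = self.final_bn.backward(g)
        for blk in reversed(self.blocks):
            g = blk.backward(g)
        g = self.maxpool.backward(g)
        return self.stem.backward(g)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities in evaluation mode (dropout off, running BN)."""
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.concatenate(out, axis=0)

    # -- serialization -----------------------------------------------------
    def state_arrays(self) -> dict:
        arrays = {}
        for i, m in enumerate(self.modules()):
            for name, v in m.__dict__.items():
                if isinstance(v, Param):
                    arrays[f"m{i}.{name}"] = v.value
                elif name in ("running_mean", "running_var"):
                    arrays[f"m{i}.{name}"] = v
        return arrays

    def load_state_arrays(self, arrays: dict) -> None:
        for i, m in enumerate(self.modules()):
            for name, v in m.__dict__.items():
                key = f"m{i}.{name}"
                if isinstance(v, Param):
                    v.value[...] = arrays[key]
                elif name in ("running_mean", "running_var"):
                    m.__dict__[name][...] = arrays[key]


def build_resnet41(config: Optional[ArchitectureConfig] = None, seed: int = 0) -> ResNet:
    """Instantiate the slice classifier (default: the 41-layer network)."""
    return ResNet(config or ArchitectureConfig(), seed=seed)


def count_weighted_layers(model: ResNet) -> int:
    """Number of convolutional + fully connected layers.

    Projection shortcuts, pooling, batch norm, activations and dropout do
    not count. For repeats (r1, r2) the closed form is ``2 + 3*(r1 + r2)``.
    """
    n = 0
    for m in model.modules():
        if isinstance(m, Conv2d) and not m.is_projection:
            n += 1
        elif isinstance(m, Linear):
            n += 1
    return n


def _to_nchw(stacks: Sequence[np.ndarray]) -> np.ndarray:
    """(N, 66, 66, 6) channel-last stacks -> NCHW float64."""
    arr = np.asarray(stacks, dtype=float)
    if arr.ndim != 4:
        raise ValueError("expected an array of HxWxC stacks")
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2))


def train_cnn(
    train_stacks: Sequence[np.ndarray],
    train_labels: Sequence[int],
    val_stacks: Sequence[np.ndarray],
    val_labels: Sequence[int],
    arch: Optional[ArchitectureConfig] = None,
    config: Optional[TrainingConfig] = None,
) -> Tuple[ResNet, pd.DataFrame]:
    """Train one slice classifier by SGD with a plateau LR schedule.

    Minimizes softmax cross-entropy (binary cross-entropy on the PCa
    probability for two classes). The learning rate is divided by
    ``plateau_factor`` when the validation loss has not improved for
    ``plateau_patience`` consecutive epochs. Fully deterministic for a
    fixed seed on a single thread.

    Returns the trained model and a history frame with columns
    epoch, train_loss, val_loss, lr.
    """
    cfg = config or TrainingConfig()
    x = _to_nchw(train_stacks)
    y = np.asarray(train_labels, dtype=int)
    xv = _to_nchw(val_stacks)
    yv = np.asarray(val_labels, dtype=int)
    if len(np.unique(y)) < 2:
        warnings.warn("training labels contain a single class; proceeding")
    model = build_resnet41(arch, seed=cfg.seed)
    opt = SGD(model.params(), lr=cfg.lr0, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    sched = ReduceLROnPlateau(opt, factor=cfg.plateau_factor,
                              patience=cfg.plateau_patience)
    cw = None
    if cfg.class_weighting and len(np.unique(y)) == 2:
        counts = np.bincount(y, minlength=2)
        cw = counts.sum() / (2.0 * np.maximum(counts, 1))
    rng = np.random.default_rng(cfg.seed + 10_000)
    history = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(y))
        losses = []
        for i in range(0, len(y), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits = model.forward(x[idx], train=True)
            loss, dlogits = cross_entropy(logits, y[idx], cw)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_logits = []
        for i in range(0, len(yv), 64):
            val_logits.append(model.forward(xv[i : i + 64], train=False))
        val_loss, _ = cross_entropy(np.concatenate(val_logits), yv, None)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss, "lr": opt.lr})
        sched.step(val_loss)
    return model, pd.DataFrame(history)


def predict_slices(
    model: ResNet,
    stacks: Sequence[np.ndarray],
    patient_ids: Optional[Sequence[str]] = None,
    slice_indices: Optional[Sequence[int]] = None,
) -> List[SliceProbability]:
    """Per-slice (p, n) softmax probabilities in evaluation mode."""
    x = _to_nchw(stacks)
    if x.shape[2] != model.config.in_size or x.shape[1] != model.config.in_channels:
        raise ValueError(
            f"stack shape {x.shape[1:]} does not match model input "
            f"({model.config.in_channels}, {model.config.in_size}, {model.config.in_size})"
        )
    probs = model.predict_proba(x)
    n_items = x.shape[0]
    pids = patient_ids if patient_ids is not None else [""] * n_items
    sids = slice_indices if slice_indices is not None else list(range(n_items))
    return [SliceProbability(str(pid), int(si), float(pr[1]), float(pr[0]))
            for pid, si, pr in zip(pids, sids, probs)]


def train_ensemble(
    train_stacks, train_labels, val_stacks, val_labels,
    arch: Optional[ArchitectureConfig] = None,
    config: Optional[TrainingConfig] = None,
    n_members: int = 5,
    base_seed: int = 0,
) -> Tuple[List[ResNet], List[pd.DataFrame]]:
    """Train ``n_members`` networks differing only in their random seed.

    Identical data and hyperparameters; member k uses seed
    ``base_seed + k``, so initial weights, dropout masks and batch orders
    differ across members — the source of ensemble diversity.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    cfg = config or TrainingConfig()
    models, histories = [], []
    for k in range(n_members):
        member_cfg = TrainingConfig(**{**asdict(cfg), "seed": base_seed + k})
        m, h = train_cnn(train_stacks, train_labels, val_stacks, val_labels,
                         arch, member_cfg)
        models.append(m)
        histories.append(h)
    return models, histories


def save_model(model: ResNet, path) -> None:
    """Persist weights + running statistics + architecture to an .npz file."""
    meta = {f"config.{k}": np.asarray(v) for k, v in asdict(model.config).items()}
    with open(path, "wb") as fh:  # keep the exact filename (no .npz suffix)
        np.savez(fh, **model.state_arrays(), **meta)


def load_model(path) -> ResNet:
    with np.load(path) as data:
        cfg_kwargs = {}
        arrays = {}
        for key in data.files:
            if key.startswith("config."):
                name = key[len("config."):]
                cfg_kwargs[name] = float(data[key]) if name == "dropout_rate" else int(data[key])
            else:
                arrays[key] = data[key]
        config = ArchitectureConfig(**cfg_kwargs)
        model = ResNet(config, seed=0)
        model.load_state_arrays(arrays)
    return model
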