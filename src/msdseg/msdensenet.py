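"""Dual-path multiscale densely connected 3D segmentation network.

The network keeps two parallel feature streams:

* the **depth path** (scale ``s1``) works at full resolution and is densely
  connected — the input of its ``l``-th transformation layer is the channel
  concatenation of the initial feature map and every previous depth-path
  output;
* the **scaled path** (``s2``) works at half resolution.  Its ``l``-th layer
  consumes the stride-2 pooled initial map, every previous scaled-path
  output, and stride-2 pooled copies of the depth-path outputs up to layer
  ``l`` ("diagonal" connections), so coarse features see fine features of
  every depth from the first layer on.

A transformation layer is BN -> ReLU -> 3x3x3 convolution (growth-rate
output channels) -> dropout.  Only the scaled path feeds the classifier: a
decoder compresses the final scaled-path concatenation, upsamples once by a
2x2x2 transposed convolution, and emits per-voxel 2-class logits at full
resolution.

Channel bookkeeping is exposed as the pure function :func:`expected_channels`
so the realized structure of a built network can be verified against the
closed form.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from . import nn


@dataclass
class NetworkConfig:
    """Architecture hyperparameters; defaults are the reference configuration."""

    depth_layers: int = 8
    scaled_layers: int = 9
    growth_rate: int = 12
    initial_channels: int = 16
    dropout_rate: float = 0.2
    num_classes: int = 2
    kernel: int = 3
    subvolume_size: int = 32
    decoder_compress_channels: int = 128
    decoder_up_channels: int = 64

    def validate(self):
        if self.depth_layers < 1 or self.scaled_layers < 1:
            raise ValueError("layer counts must be >= 1")
        if self.growth_rate < 1 or self.initial_channels < 1:
            raise ValueError("growth_rate and initial_channels must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        return self


REFERENCE_CONFIG = NetworkConfig()


def expected_channels(scale: int, layer: int, cfg: NetworkConfig) -> int:
    """Input channel count of transformation layer ``layer`` at ``scale``.

    Depth path (scale 1): ``c0 + (l-1)*k`` — the initial map plus all
    previous depth outputs.  Scaled path (scale 2): additionally the
    diagonally pooled depth outputs up to ``min(l, depth_layers)``:
    ``c0 + (l-1)*k + min(l, depth_layers)*k``.
    """
    c0, k = cfg.initial_channels, cfg.growth_rate
    if scale == 1:
        if not 1 <= layer <= cfg.depth_layers:
            raise ValueError(f"depth-path layer {layer} out of range")
        return c0 + (layer - 1) * k
    if scale == 2:
        if not 1 <= layer <= cfg.scaled_layers:
            raise ValueError(f"scaled-path layer {layer} out of range")
        return c0 + (layer - 1) * k + min(layer, cfg.depth_layers) * k
    raise ValueError(f"scale must be 1 or 2, got {scale}")


class _TransformationLayer:
    """BN -> ReLU -> 3x3x3 conv (k channels) -> dropout."""

    def __init__(self, in_channels, growth_rate, kernel, dropout_rate):
        self.bn = nn.BatchNorm3d(in_channels)
        self.conv = nn.Conv3d(in_channels, growth_rate, kernel=kernel, bias=False)
        self.dropout_rate = dropout_rate

    def __call__(self, x, train, rng):
        y = self.conv(nn.relu(self.bn(x, train)))
        return nn.dropout(y, self.dropout_rate, rng, train)

    def parameters(self, prefix):
        for name, p in self.bn.parameters():
            yield f"{prefix}.bn.{name}", p
        for name, p in self.conv.parameters():
            yield f"{prefix}.conv.{name}", p


class MSDenseNet:
    """Built network; see module docstring for the topology."""

    def __init__(self, cfg: NetworkConfig):
        cfg.validate()
        self.cfg = cfg
        c0, k = cfg.initial_channels, cfg.growth_rate
        self.conv_init = nn.Conv3d(1, c0, kernel=cfg.kernel, bias=False)
        self.s1_layers = [
            _TransformationLayer(expected_channels(1, l, cfg), k, cfg.kernel,
                                 cfg.dropout_rate)
            for l in range(1, cfg.depth_layers + 1)
        ]
        self.s2_layers = [
            _TransformationLayer(expected_channels(2, l, cfg), k, cfg.kernel,
                                 cfg.dropout_rate)
            for l in range(1, cfg.scaled_layers + 1)
        ]
        # channels of the final scaled-path concatenation
        self.final_s2_channels = (c0 + cfg.scaled_layers * k
                                  + min(cfg.scaled_layers + 1, cfg.depth_layers) * k)
        dc, du = cfg.decoder_compress_channels, cfg.decoder_up_channels
        self.dec_bn1 = nn.BatchNorm3d(self.final_s2_channels)
        self.dec_compress = nn.Conv3d(self.final_s2_channels, dc, kernel=1, bias=False)
        self.dec_up = nn.ConvTranspose3d_s2(dc, du)
        self.dec_bn2 = nn.BatchNorm3d(du)
        self.dec_conv = nn.Conv3d(du, du, kernel=cfg.kernel, bias=False)
        self.dec_classify = nn.Conv3d(du, cfg.num_classes, kernel=1, bias=True)

    # -- structure ---------------------------------------------------------

    def parameters(self):
        yield from (("conv_init." + n, p) for n, p in self.conv_init.parameters())
        for i, layer in enumerate(self.s1_layers, start=1):
            yield from layer.parameters(f"s1.{i}")
        for i, layer in enumerate(self.s2_layers, start=1):
            yield from layer.parameters(f"s2.{i}")
        for name, obj in [("dec_bn1", self.dec_bn1), ("dec_compress", self.dec_compress),
                          ("dec_up", self.dec_up), ("dec_bn2", self.dec_bn2),
                          ("dec_conv", self.dec_conv), ("dec_classify", self.dec_classify)]:
            yield from ((f"{name}.{n}", p) for n, p in obj.parameters())

    def batchnorms(self):
        for layer in self.s1_layers + self.s2_layers:
            yield layer.bn
        yield self.dec_bn1
        yield self.dec_bn2

    def describe(self):
        """One row per transformation layer with realized channel counts."""
        rows = []
        for scale, layers in ((1, self.s1_layers), (2, self.s2_layers)):
            for i, layer in enumerate(layers, start=1):
                co, ci = layer.conv.weight.shape[:2]
                rows.append({"scale": scale, "layer": i,
                             "in_channels": int(ci), "out_channels": int(co)})
        return rows

    # -- forward -----------------------------------------------------------

    def forward(self, x, train=False, rng=None):
        """Run the network on ``x`` (N, 1, D, H, W); returns logits Tensor.

        Spatial dims must be even (one stride-2 scale split).
        """
        if rng is None:
            rng = np.random.default_rng(0)
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(np.asarray(x, dtype=np.float32))
        d, h, w = x.shape[2:]
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even, got {(d, h, w)}")
        f0 = self.conv_init(x)
        s1_feats = [f0]
        s1_outs = []
        for layer in self.s1_layers:
            out = layer(nn.concat_channels(s1_feats), train, rng)
            s1_outs.append(out)
            s1_feats.append(out)
        pooled_init = nn.maxpool3d_s2(f0)
        pooled_s1 = [nn.maxpool3d_s2(o) for o in s1_outs]
        s2_outs = []
        for l, layer in enumerate(self.s2_layers, start=1):
            inp = nn.concat_channels(
                [pooled_init] + s2_outs + pooled_s1[:min(l, self.cfg.depth_layers)])
            s2_outs.append(layer(inp, train, rng))
        final = nn.concat_channels(
            [pooled_init] + s2_outs
            + pooled_s1[:min(self.cfg.scaled_layers + 1, self.cfg.depth_layers)])
        y = self.dec_compress(nn.relu(self.dec_bn1(final, train)))
        y = self.dec_up(y)
        y = self.dec_conv(nn.relu(self.dec_bn2(y, train)))
        y = nn.dropout(y, self.cfg.dropout_rate, rng, train)
        return self.dec_classify(y)

    def predict_proba(self, x):
        """Per-voxel class probabilities (N, num_classes, D, H, W), eval mode."""
        with nn.no_grad():
            logits = self.forward(x, train=False)
            return nn.softmax_channels(logits).data

    # -- checkpointing -----------------------------------------------------

    def state_dict(self):
        state = {name: p.data for name, p in self.parameters()}
        for i, bn in enumerate(self.batchnorms()):
            state[f"_bn{i}.running_mean"] = bn.running_mean
            state[f"_bn{i}.running_var"] = bn.running_var
        return state

    def load_state_dict(self, state):
        for name, p in self.parameters():
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.astype(p.data.dtype)
        for i, bn in enumerate(self.batchnorms()):
            bn.running_mean = np.asarray(state[f"_bn{i}.running_mean"], dtype=np.float64)
            bn.running_var = np.asarray(state[f"_bn{i}.running_var"], dtype=np.float64)

    def save(self, path):
        np.savez_compressed(path, _config=json.dumps(dataclasses.asdict(self.cfg)),
                            **self.state_dict())

    @classmethod
    def load(cls, path):
        with np.load(path, allow_pickle=False) as f:
            cfg = NetworkConfig(**json.loads(str(f["_config"])))
            net = cls(cfg)
            net.load_state_dict({k: f[k] for k in f.files if k != "_config"})
        return net


def build_network(cfg: NetworkConfig = None) -> MSDenseNet:
    """Construct the network from ``cfg`` (reference configuration if None)."""
    return MSDenseNet(cfg if cfg is not None else NetworkConfig())


def count_parameters(net: MSDenseNet) -> int:
    """Exact count of trainable scalars (conv kernels, biases, BN scale/shift)."""
    return int(sum(p.size for _, p in net.parameters()))
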