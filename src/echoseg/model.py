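"""Expanded U-Net: a dropout-regularised encoder–decoder for grey-level maps.

The network is the classic symmetric U shape — per level two 3x3 same-padded
convolutions, 2x2 max-pool down-sampling, stride-2 transposed-convolution
up-sampling and skip-connection concatenation ("fusion") — with three
modifications aimed at ultrasound texture:

* dropout layers (7 at the default depth of 4) after each fusion, after the
  two deepest encoder blocks and after the bottleneck;
* batch normalization after every convolution and deconvolution, with
  leaky-ReLU activations;
* a 1x1 convolution head mapping the 8-channel top-level feature map to a
  3-channel grey-level output, through a per-pixel softmax (or, optionally,
  per-channel sigmoid).

With the softmax head the three output channels sum to one at every pixel, so
the channel-mean grey map of any prediction is 255/3 = 85: benign regions
trained on the (0.5, 0.5, 0.5) soft label sit exactly at their expected grey
reduction (alpha = 85/127.5 ≈ 0.667), while a grey level above 85 is only
reachable with the sigmoid head.  Both heads are supported; see
docs/methods.md for the trade-off.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn

__all__ = ["ArchitectureConfig", "ConfigurationError", "ExpandedUNet", "build_expanded_unet"]


class ConfigurationError(ValueError):
    """Raised when an architecture configuration or input is inconsistent."""


@dataclass(frozen=True)
class ArchitectureConfig:
    """Hyper-parameters defining the expanded U-Net graph.

    Parameters
    ----------
    depth : int
        Number of down-sampling steps; input sides must be divisible by
        ``2**depth``.
    base_channels : int
        Feature channels at the top level (8 by default, so the head maps an
        8-channel feature vector to the 3-channel output).
    dropout_rate : float
        Shielding probability P of every dropout layer (default 0.5).
    leaky_slope : float
        Negative slope of the leaky-ReLU activations.
    head : str
        ``"softmax"`` (per-pixel channels sum to 1) or ``"sigmoid"``.
    input_size : (int, int)
        Default spatial size used for validation and summaries.
    batch_norm : bool
        Normalize after every convolution/deconvolution (default True).
    dropout_after : tuple of str, optional
        Names of the positions that receive a dropout layer; ``None`` selects
        the default placement (every fusion, the two deepest encoder blocks
        and the bottleneck — 7 layers at depth 4).
    """

    depth: int = 4
    base_channels: int = 8
    dropout_rate: float = 0.5
    leaky_slope: float = 0.01
    head: str = "softmax"
    input_size: tuple[int, int] = (64, 64)
    batch_norm: bool = True
    dropout_after: tuple[str, ...] | None = None
    out_channels: int = field(default=3, init=False)

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if self.base_channels < 1:
            raise ConfigurationError("base_channels must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.head not in ("softmax", "sigmoid"):
            raise ConfigurationError(f"unknown head activation {self.head!r}")
        div = 2 ** self.depth
        h, w = self.input_size
        if h % div or w % div:
            raise ConfigurationError(
                f"input_size {self.input_size} must have both sides divisible by "
                f"2**depth = {div}")

    def default_dropout_placement(self) -> tuple[str, ...]:
        """Fusions at every decoder level plus the two deepest encoder blocks
        and the bottleneck (``depth + 3`` layers; 7 at the default depth)."""
        names = [f"fuse{l}" for l in range(self.depth)]
        names += [f"enc{l}" for l in range(max(0, self.depth - 2), self.depth)]
        names.append("bottleneck")
        return tuple(sorted(names))

    def dropout_positions(self) -> tuple[str, ...]:
        if self.dropout_after is not None:
            return tuple(self.dropout_after)
        return self.default_dropout_placement()

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in
             ("depth", "base_channels", "dropout_rate", "leaky_slope", "head",
              "batch_norm")}
        d["input_size"] = list(self.input_size)
        d["dropout_after"] = (None if self.dropout_after is None
                              else list(self.dropout_after))
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "ArchitectureConfig":
        d = json.loads(s)
        d["input_size"] = tuple(d["input_size"])
        if d.get("dropout_after") is not None:
            d["dropout_after"] = tuple(d["dropout_after"])
        return cls(**d)


class _ConvBlock:
    """Two (conv 3x3 -> [BN] -> leaky ReLU) stages."""

    def __init__(self, c_in: int, c_out: int, cfg: ArchitectureConfig,
                 rng: np.random.Generator) -> None:
        self.layers: list[nn.Layer] = []
        for cin in (c_in, c_out):
            self.layers.append(nn.Conv2d(cin, c_out, 3, rng))
            if cfg.batch_norm:
                self.layers.append(nn.BatchNorm2d(c_out))
            self.layers.append(nn.LeakyReLU(cfg.leaky_slope))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, d: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d


class ExpandedUNet:
    """The expanded U-Net model: construction, forward, backward, checkpoints.

    ``forward`` expects a batch of normalized greyscale images — shape
    ``(N, H, W)`` or ``(N, 1, H, W)`` with values in [0, 1] — and returns the
    per-pixel 3-channel prediction map ``(N, 3, H, W)``.  Dropout is active
    only when ``train=True``; inference is deterministic.
    """

    def __init__(self, cfg: ArchitectureConfig | None = None, seed: int = 0) -> None:
        self.cfg = cfg if cfg is not None else ArchitectureConfig()
        self.rng = np.random.default_rng(seed)
        self._build()

    # -- construction ------------------------------------------------------

    def _build(self) -> None:
        cfg = self.cfg
        rng = self.rng
        drop_at = set(cfg.dropout_positions())
        self._drop_names: list[str] = []

        def maybe_dropout(name: str) -> nn.Dropout | None:
            if name in drop_at and cfg.dropout_rate >= 0.0:
                self._drop_names.append(name)
                return nn.Dropout(cfg.dropout_rate, rng)
            return None

        ch = [cfg.base_channels * 2 ** l for l in range(cfg.depth + 1)]
        self.enc_blocks: list[_ConvBlock] = []
        self.enc_drop: list[nn.Dropout | None] = []
        self.pools: list[nn.MaxPool2d] = []
        c_prev = 1
        for l in range(cfg.depth):
            self.enc_blocks.append(_ConvBlock(c_prev, ch[l], cfg, rng))
            self.enc_drop.append(maybe_dropout(f"enc{l}"))
            self.pools.append(nn.MaxPool2d())
            c_prev = ch[l]
        self.bottleneck = _ConvBlock(c_prev, ch[cfg.depth], cfg, rng)
        self.bottleneck_drop = maybe_dropout("bottleneck")

        self.ups: list[nn.ConvTranspose2d] = []
        self.up_norms: list[nn.BatchNorm2d | None] = []
        self.fuse_drop: list[nn.Dropout | None] = []
        self.dec_blocks: list[_ConvBlock] = []
        for l in range(cfg.depth):  # indexed by the level they restore
            self.ups.append(nn.ConvTranspose2d(ch[l + 1], ch[l], rng))
            self.up_norms.append(nn.BatchNorm2d(ch[l]) if cfg.batch_norm else None)
            self.fuse_drop.append(maybe_dropout(f"fuse{l}"))
            self.dec_blocks.append(_ConvBlock(2 * ch[l], ch[l], cfg, rng))
        self.head = nn.Conv2d(ch[0], cfg.out_channels, 1, rng)

        self._layers: list[nn.Layer] = []
        for blk in self.enc_blocks:
            self._layers.extend(blk.layers)
        self._layers.extend(d for d in self.enc_drop if d is not None)
        self._layers.extend(self.pools)
        self._layers.extend(self.bottleneck.layers)
        if self.bottleneck_drop is not None:
            self._layers.append(self.bottleneck_drop)
        for l in range(cfg.depth):
            self._layers.append(self.ups[l])
            if self.up_norms[l] is not None:
                self._layers.append(self.up_norms[l])
            if self.fuse_drop[l] is not None:
                self._layers.append(self.fuse_drop[l])
            self._layers.extend(self.dec_blocks[l].layers)
        self._layers.append(self.head)

    # -- forward / backward ------------------------------------------------

    def _validate_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[:, None]
        if x.ndim != 4 or x.shape[1] != 1:
            raise ConfigurationError(
                f"expected input of shape (N, H, W) or (N, 1, H, W), got {x.shape}")
        div = 2 ** self.cfg.depth
        _, _, h, w = x.shape
        if h % div or w % div:
            raise ConfigurationError(
                f"input spatial size {h}x{w} must be divisible by 2**depth = {div}")
        if x.min() < -1e-9 or x.max() > 1 + 1e-9:
            raise ValueError(
                f"input image values must lie in [0, 1]; got range "
                f"[{x.min():.4g}, {x.max():.4g}]")
        return x

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = self._validate_input(x)
        skips: list[np.ndarray] = []
        h = x
        for l in range(self.cfg.depth):
            h = self.enc_blocks[l].forward(h, train)
            if self.enc_drop[l] is not None:
                h = self.enc_drop[l].forward(h, train)
            skips.append(h)
            h = self.pools[l].forward(h, train)
        h = self.bottleneck.forward(h, train)
        if self.bottleneck_drop is not None:
            h = self.bottleneck_drop.forward(h, train)
        for l in reversed(range(self.cfg.depth)):
            h = self.ups[l].forward(h, train)
            if self.up_norms[l] is not None:
                h = self.up_norms[l].forward(h, train)
            h = np.concatenate([skips[l], h], axis=1)
            if self.fuse_drop[l] is not None:
                h = self.fuse_drop[l].forward(h, train)
            h = self.dec_blocks[l].forward(h, train)
        z = self.head.forward(h, train)
        if self.cfg.head == "softmax":
            p = nn.channel_softmax(z)
        else:
            p = nn.sigmoid(z)
        self._probs = p
        return p

    def backward(self, dprobs: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output probabilities."""
        p = self._probs
        if self.cfg.head == "softmax":
            d = nn.softmax_backward(p, dprobs)
        else:
            d = nn.sigmoid_backward(p, dprobs)
        d = self.head.backward(d)
        d_skip: dict[int, np.ndarray] = {}
        for l in range(self.cfg.depth):  # reverse of the decoder loop
            d = self.dec_blocks[l].backward(d)
            if self.fuse_drop[l] is not None:
                d = self.fuse_drop[l].backward(d)
            c = self.ups[l].out_channels
            d_skip[l] = d[:, :c]
            du = d[:, c:]
            if self.up_norms[l] is not None:
                du = self.up_norms[l].backward(du)
            d = self.ups[l].backward(du)
        if self.bottleneck_drop is not None:
            d = self.bottleneck_drop.backward(d)
        d = self.bottleneck.backward(d)
        for l in reversed(range(self.cfg.depth)):
            d = self.pools[l].backward(d) + d_skip[l]
            if self.enc_drop[l] is not None:
                d = self.enc_drop[l].backward(d)
            d = self.enc_blocks[l].backward(d)

    # -- introspection -----------------------------------------------------

    @property
    def layers(self) -> list[nn.Layer]:
        return self._layers

    def count_dropout_layers(self) -> int:
        return sum(isinstance(l, nn.Dropout) for l in self._layers)

    def num_parameters(self) -> int:
        return sum(p.size for l in self._layers for p in l.params.values())

    def describe(self) -> list[dict]:
        """Ordered layer descriptions (kind, channels, kernel, dropout flags)."""
        out = []
        for layer in self._layers:
            d: dict = {"kind": type(layer).__name__}
            for attr in ("in_channels", "out_channels", "kernel_size",
                         "channels", "rate", "negative_slope"):
                if hasattr(layer, attr):
                    d[attr] = getattr(layer, attr)
            out.append(d)
        return out

    def summary_text(self) -> str:
        buf = io.StringIO()
        cfg = self.cfg
        buf.write(f"ExpandedUNet depth={cfg.depth} base_channels={cfg.base_channels} "
                  f"head={cfg.head} params={self.num_parameters()}\n")
        buf.write(f"dropout (P={cfg.dropout_rate}) at: "
                  f"{', '.join(sorted(self._drop_names)) or 'none'}\n")
        for i, d in enumerate(self.describe()):
            extras = " ".join(f"{k}={v}" for k, v in d.items() if k != "kind")
            buf.write(f"  [{i:3d}] {d['kind']} {extras}\n")
        return buf.getvalue()

    # -- checkpoints -------------------------------------------------------

    def save(self, path: str) -> None:
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self._layers):
            for name, p in layer.params.items():
                arrays[f"param_{i}_{name}"] = p
            if isinstance(layer, nn.BatchNorm2d):
                arrays[f"state_{i}_running_mean"] = layer.running_mean
                arrays[f"state_{i}_running_var"] = layer.running_var
        arrays["config_json"] = np.frombuffer(self.cfg.to_json().encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "ExpandedUNet":
        with np.load(path) as data:
            cfg = ArchitectureConfig.from_json(bytes(data["config_json"]).decode())
            model = cls(cfg)
            for i, layer in enumerate(model._layers):
                for name in layer.params:
                    key = f"param_{i}_{name}"
                    if key not in data:
                        raise ConfigurationError(
                            f"checkpoint {path} does not match the architecture: "
                            f"missing {key}")
                    if data[key].shape != layer.params[name].shape:
                        raise ConfigurationError(
                            f"checkpoint {path} does not match the architecture: "
                            f"{key} has shape {data[key].shape}, expected "
                            f"{layer.params[name].shape}")
                    layer.params[name] = data[key].copy()
                if isinstance(layer, nn.BatchNorm2d):
                    layer.running_mean = data[f"state_{i}_running_mean"].copy()
                    layer.running_var = data[f"state_{i}_running_var"].copy()
        return model


def build_expanded_unet(cfg: ArchitectureConfig | None = None,
                        seed: int = 0) -> ExpandedUNet:
    """Construct an expanded U-Net from an :class:`ArchitectureConfig`."""
    return ExpandedUNet(cfg, seed=seed)
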