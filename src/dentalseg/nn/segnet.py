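"""SegNet-style encoder-decoder for per-pixel classification.

The encoder stacks conv+BN+ReLU blocks, each followed by 2x2 stride-2
max-pooling; the decoder mirrors it with 2x2 stride-2 transposed
convolutions (learnable upsampling) followed by BN, and additive skip
connections bring the encoder's pre-pool feature map into the decoder at
the matching scale.  A 3x3 classifier conv produces per-pixel class
scores, normalised by a softmax.  Optional channel + spatial attention
is inserted either at the encoder-decoder transition (``center``) or on
the final feature map before the classifier (``end``).

Two depth regimes: ``encoder_layers=13`` builds the full VGG-style
encoder (13 conv layers in 5 pooling blocks); smaller values build one
conv per block — the 4-block reduced model is the desk-scale default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .attention import ChannelAttention, SpatialAttention
from .layers import BatchNorm2d, Conv2d, ConvTranspose2d, MaxPool2d, ReLU

__all__ = ["SegNet", "SegNetConfig", "build_segnet", "load_segnet", "save_segnet"]

_VGG13_BLOCKS = [[64, 64], [128, 128], [256, 256, 256], [512, 512, 512], [512, 512, 512]]


@dataclass(frozen=True)
class SegNetConfig:
    encoder_layers: int = 4  # 13 = full VGG encoder; else one conv per block
    attention_placement: str = "none"  # none | end | center
    n_classes: int = 28
    input_size: int = 128
    in_channels: int = 3
    base_channels: int = 16  # reduced-model width; doubled per block, capped

    def __post_init__(self) -> None:
        if self.attention_placement not in ("none", "end", "center"):
            raise ValueError(
                f"attention_placement must be none/end/center, got {self.attention_placement!r}"
            )
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.encoder_layers < 1:
            raise ValueError("encoder needs at least one layer")

    @property
    def blocks(self) -> list[list[int]]:
        if self.encoder_layers == 13:
            return [list(b) for b in _VGG13_BLOCKS]
        return [[self.base_channels * 2 ** min(k, 2)] for k in range(self.encoder_layers)]


class _ConvBNReLU:
    def __init__(self, c_in, c_out, rng):
        self.conv = Conv2d(c_in, c_out, rng=rng)
        self.bn = BatchNorm2d(c_out)
        self.relu = ReLU()

    def params(self):
        return self.conv.params() + self.bn.params()

    def forward(self, x, train):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, grad):
        return self.conv.backward(self.bn.backward(self.relu.backward(grad)))


class _UpBNReLU:
    def __init__(self, c_in, c_out, rng):
        self.up = ConvTranspose2d(c_in, c_out, rng=rng)
        self.bn = BatchNorm2d(c_out)
        self.relu = ReLU()

    def params(self):
        return self.up.params() + self.bn.params()

    def forward(self, x, train):
        return self.relu.forward(self.bn.forward(self.up.forward(x, train), train), train)

    def backward(self, grad):
        return self.up.backward(self.bn.backward(self.relu.backward(grad)))


class SegNet:
    """Encoder-decoder with additive skips; see module docstring."""

    def __init__(self, config: SegNetConfig, seed: int = 0):
        blocks = config.blocks
        if config.input_size % (2 ** len(blocks)) != 0:
            raise ValueError(
                f"input_size {config.input_size} not divisible by the "
                f"total downsampling factor {2 ** len(blocks)}"
            )
        self.config = config
        rng = np.random.default_rng(seed)
        self.enc_blocks = []
        c_prev = config.in_channels
        for chans in blocks:
            stages = []
            for c in chans:
                stages.append(_ConvBNReLU(c_prev, c, rng))
                c_prev = c
            self.enc_blocks.append(stages)
        self.pools = [MaxPool2d() for _ in blocks]

        self.center_attention = None
        self.end_attention = None
        c_bottom = blocks[-1][-1]
        if config.attention_placement == "center":
            self.center_attention = [ChannelAttention(c_bottom, rng=rng),
                                     SpatialAttention(rng=rng)]

        self.dec_blocks = []
        for k in reversed(range(len(blocks))):
            c_in = blocks[k][-1]
            c_out = blocks[k - 1][-1] if k > 0 else blocks[0][0]
            stages = [_UpBNReLU(c_in, c_in, rng)]  # upsample to the skip's scale
            mirror = list(reversed(blocks[k]))
            for i, _ in enumerate(mirror):
                c_next = mirror[i + 1] if i + 1 < len(mirror) else c_out
                stages.append(_ConvBNReLU(c_in, c_next, rng))
                c_in = c_next
            self.dec_blocks.append(stages)

        c_final = blocks[0][0]
        if config.attention_placement == "end":
            self.end_attention = [ChannelAttention(c_final, rng=rng),
                                  SpatialAttention(rng=rng)]
        self.head = Conv2d(c_final, config.n_classes, rng=rng)

    # -- parameter plumbing -------------------------------------------------
    def _modules(self):
        for stages in self.enc_blocks:
            yield from stages
        yield from self.pools
        if self.center_attention:
            yield from self.center_attention
        for stages in self.dec_blocks:
            yield from stages
        if self.end_attention:
            yield from self.end_attention
        yield self.head

    def params(self):
        out = []
        for m in self._modules():
            out.extend(m.params())
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params()))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights) -> None:
        for (p, _), w in zip(self.params(), weights, strict=True):
            p[...] = w

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Input (N, C, H, W) float32 -> per-pixel class logits."""
        skips = []
        for stages, pool in zip(self.enc_blocks, self.pools):
            for s in stages:
                x = s.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        if self.center_attention:
            for a in self.center_attention:
                x = a.forward(x, train)
        for stages, skip in zip(self.dec_blocks, reversed(skips)):
            x = stages[0].forward(x, train)
            x = x + skip  # additive skip connection at matching scale
            for s in stages[1:]:
                x = s.forward(x, train)
        if self.end_attention:
            for a in self.end_attention:
                x = a.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.head.backward(grad)
        if self.end_attention:
            for a in reversed(self.end_attention):
                grad = a.backward(grad)
        skip_grads = []  # collected shallowest-first
        for stages in reversed(self.dec_blocks):
            for s in reversed(stages[1:]):
                grad = s.backward(grad)
            skip_grads.append(grad)  # gradient flowing into the additive skip
            grad = stages[0].backward(grad)
        if self.center_attention:
            for a in reversed(self.center_attention):
                grad = a.backward(grad)
        for pool, stages, sg in zip(
            reversed(self.pools), reversed(self.enc_blocks), reversed(skip_grads)
        ):
            grad = pool.backward(grad) + sg
            for s in reversed(stages):
                grad = s.backward(grad)
        return grad

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)


def build_segnet(config: SegNetConfig, seed: int = 0) -> SegNet:
    """Construct a SegNet with deterministic initial weights."""
    return SegNet(config, seed=seed)


def save_segnet(model: SegNet, path) -> None:
    """Checkpoint: weights as .npz plus a JSON sidecar with the config."""
    path = Path(path)
    np.savez(path, *[p for p, _ in model.params()])
    cfg = dict(model.config.__dict__)
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))


def load_segnet(path) -> SegNet:
    path = Path(path)
    cfg = SegNetConfig(**json.loads(path.with_suffix(".json").read_text()))
    model = SegNet(cfg)
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    model.set_weights([data[k] for k in data.files])
    return model
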