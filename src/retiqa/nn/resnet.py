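"""18-layer residual network with channel dropout in every block.

Standard basic-block topology: a 7x7 stem convolution, 3x3 max-pool, four
stages of two residual blocks (stage widths 64/128/256/512 scaled by
``width_scale``), global average pooling and a linear head.  Each block
carries a 2-D dropout layer after its second convolution's normalisation,
inside the residual branch — kept active at inference for
Monte-Carlo-Dropout uncertainty estimation.

``width_scale`` shrinks every stage width by the same factor so the full
topology trains quickly on a CPU; 1.0 reproduces the standard channel
counts.
"""

from __future__ import annotations

import copy

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    Dropout2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
)

STAGE_WIDTHS = (64, 128, 256, 512)
#: total spatial downsampling factor from input to the pooled features
DOWNSAMPLE_FACTOR = 32


class BasicBlock:
    """conv-bn-relu-conv-bn-dropout + shortcut, then relu."""

    def __init__(self, c_in: int, c_out: int, stride: int, dropout_rate: float,
                 *, rng: np.random.Generator) -> None:
        self.conv1 = Conv2d(c_in, c_out, 3, stride=stride, pad=1, rng=rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, stride=1, pad=1, rng=rng)
        self.bn2 = BatchNorm2d(c_out)
        self.dropout = Dropout2d(dropout_rate)
        self.relu2 = ReLU()
        self.projection = stride != 1 or c_in != c_out
        if self.projection:
            self.conv_sc = Conv2d(c_in, c_out, 1, stride=stride, pad=0, rng=rng)
            self.bn_sc = BatchNorm2d(c_out)

    def leaves(self):
        yield "conv1", self.conv1
        yield "bn1", self.bn1
        yield "conv2", self.conv2
        yield "bn2", self.bn2
        if self.projection:
            yield "conv_sc", self.conv_sc
            yield "bn_sc", self.bn_sc

    def forward(self, x, mode, rng=None):
        out = self.conv1.forward(x, mode, rng)
        out = self.bn1.forward(out, mode, rng)
        out = self.relu1.forward(out, mode, rng)
        out = self.conv2.forward(out, mode, rng)
        out = self.bn2.forward(out, mode, rng)
        out = self.dropout.forward(out, mode, rng)
        if self.projection:
            short = self.bn_sc.forward(self.conv_sc.forward(x, mode, rng), mode, rng)
        else:
            short = x
        return self.relu2.forward(out + short, mode, rng)

    def backward(self, dout):
        d = self.relu2.backward(dout)
        d_main = self.dropout.backward(d)
        d_main = self.bn2.backward(d_main)
        d_main = self.conv2.backward(d_main)
        d_main = self.relu1.backward(d_main)
        d_main = self.bn1.backward(d_main)
        dx = self.conv1.backward(d_main)
        if self.projection:
            dx = dx + self.conv_sc.backward(self.bn_sc.backward(d))
        else:
            dx = dx + d
        return dx


class DropoutResNet:
    """The full network: image ``(N, C, H, W)`` -> per-category logits ``(N, K)``."""

    def __init__(self, in_channels: int, n_outputs: int, *, width_scale: float = 1.0,
                 dropout_rate: float = 0.2, input_side: int = 64, seed: int = 0) -> None:
        if input_side < DOWNSAMPLE_FACTOR or input_side % DOWNSAMPLE_FACTOR:
            raise ValueError(
                f"input side {input_side} incompatible with downsampling depth; "
                f"must be a positive multiple of {DOWNSAMPLE_FACTOR}"
            )
        if width_scale <= 0:
            raise ValueError("width_scale must be positive")
        self.in_channels = in_channels
        self.n_outputs = n_outputs
        self.input_side = input_side
        self.dropout_rate = dropout_rate
        self.width_scale = width_scale
        widths = [max(1, round(w * width_scale)) for w in STAGE_WIDTHS]

        ss = np.random.SeedSequence(seed)
        rng = np.random.default_rng(ss)
        self.conv1 = Conv2d(in_channels, widths[0], 7, stride=2, pad=3, rng=rng)
        self.bn1 = BatchNorm2d(widths[0])
        self.relu = ReLU()
        self.maxpool = MaxPool2d(3, 2, 1)
        self.blocks: list[BasicBlock] = []
        c_in = widths[0]
        for stage, c_out in enumerate(widths):
            for b in range(2):
                stride = 2 if (stage > 0 and b == 0) else 1
                self.blocks.append(
                    BasicBlock(c_in, c_out, stride, dropout_rate, rng=rng)
                )
                c_in = c_out
        self.gap = GlobalAvgPool()
        self.fc = Linear(c_in, n_outputs, rng=rng)

    # -- parameter bookkeeping ------------------------------------------------

    def leaves(self):
        """Named leaf modules in a fixed, deterministic order."""
        yield "conv1", self.conv1
        yield "bn1", self.bn1
        for i, block in enumerate(self.blocks):
            for name, leaf in block.leaves():
                yield f"block{i}.{name}", leaf
        yield "fc", self.fc

    def zero_grad(self) -> None:
        for _, leaf in self.leaves():
            leaf.zero_grad()

    def n_params(self, convolutional_only: bool = False) -> int:
        total = 0
        for name, leaf in self.leaves():
            if convolutional_only and not isinstance(leaf, Conv2d):
                continue
            total += sum(v.size for v in leaf.params.values())
        return total

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for name, leaf in self.leaves():
            for k, v in leaf.params.items():
                state[f"{name}.{k}"] = v.copy()
            for k, v in leaf.buffers.items():
                state[f"{name}.buffer.{k}"] = v.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, leaf in self.leaves():
            for k in leaf.params:
                leaf.params[k] = state[f"{name}.{k}"].copy()
            for k in leaf.buffers:
                leaf.buffers[k] = state[f"{name}.buffer.{k}"].copy()

    # -- computation ----------------------------------------------------------

    def forward(self, x: np.ndarray, mode: str = "eval",
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Return per-category logits; apply a sigmoid for probabilities."""
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (N, {self.in_channels}, H, W) input, got {x.shape}"
            )
        out = self.conv1.forward(x, mode, rng)
        out = self.bn1.forward(out, mode, rng)
        out = self.relu.forward(out, mode, rng)
        out = self.maxpool.forward(out, mode, rng)
        for block in self.blocks:
            out = block.forward(out, mode, rng)
        out = self.gap.forward(out, mode, rng)
        return self.fc.forward(out, mode, rng)

    def predict_proba(self, x: np.ndarray, mode: str = "eval",
                      rng: np.random.Generator | None = None) -> np.ndarray:
        from scipy.special import expit

        return expit(self.forward(x, mode, rng))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.fc.backward(dlogits)
        d = self.gap.backward(d)
        for block in reversed(self.blocks):
            d = block.backward(d)
        d = self.maxpool.backward(d)
        d = self.relu.backward(d)
        d = self.bn1.backward(d)
        return self.conv1.backward(d)

    def copy(self) -> "DropoutResNet":
        return copy.deepcopy(self)
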