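"""Residual classifier architectures on the numpy backend.

2D: ResNet-50 and ResNeXt-50 (cardinality 32, base width 4) with the
standard 7x7 stem. 3D: ResNet-18 (basic blocks) and ResNet-50 (bottleneck
blocks) with a 3x3x3 first convolution. Every net ends in global average
pooling and a 2-way dense head. A ``width_mult`` below 1 scales channel
counts down for desk-scale training without changing depth or topology.
"""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm, ConvNd, GlobalAvgPool, Linear, MaxPoolNd, Module, ReLU, Sequential


def _scale(ch: int, width_mult: float, multiple: int = 1) -> int:
    return max(multiple, int(round(ch * width_mult / multiple)) * multiple)


class Bottleneck(Module):
    """1x1 -> 3x3 (grouped, strided) -> 1x1 with identity or projected skip."""

    expansion = 4

    def __init__(self, ndim, in_ch, width, out_ch, stride, groups, rng):
        self.conv1 = ConvNd(ndim, in_ch, width, 1, rng=rng)
        self.bn1 = BatchNorm(width)
        self.conv2 = ConvNd(ndim, width, width, 3, stride=stride, padding=1, groups=groups, rng=rng)
        self.bn2 = BatchNorm(width)
        self.conv3 = ConvNd(ndim, width, out_ch, 1, rng=rng)
        self.bn3 = BatchNorm(out_ch)
        self.relu1, self.relu2, self.relu3 = ReLU(), ReLU(), ReLU()
        self.downsample = None
        if stride != 1 or in_ch != out_ch:
            self.downsample = Sequential(
                ConvNd(ndim, in_ch, out_ch, 1, stride=stride, rng=rng), BatchNorm(out_ch)
            )

    def forward(self, x):
        identity = self.downsample(x) if self.downsample else x
        out = self.relu1(self.bn1(self.conv1(x)))
        out = self.relu2(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        return self.relu3(out + identity)

    def backward(self, grad):
        grad = self.relu3.backward(grad)
        g_id = grad
        g = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(
                self.conv2.backward(self.bn2.backward(self.relu2.backward(
                    self.conv3.backward(self.bn3.backward(grad))
                )))
            ))
        )
        if self.downsample:
            g = g + self.downsample.backward(g_id)
        else:
            g = g + g_id
        return g


class BasicBlock(Module):
    """Two 3x3 convolutions with identity or projected skip (ResNet-18/34)."""

    expansion = 1

    def __init__(self, ndim, in_ch, width, out_ch, stride, groups, rng):
        assert groups == 1
        self.conv1 = ConvNd(ndim, in_ch, out_ch, 3, stride=stride, padding=1, rng=rng)
        self.bn1 = BatchNorm(out_ch)
        self.conv2 = ConvNd(ndim, out_ch, out_ch, 3, padding=1, rng=rng)
        self.bn2 = BatchNorm(out_ch)
        self.relu1, self.relu2 = ReLU(), ReLU()
        self.downsample = None
        if stride != 1 or in_ch != out_ch:
            self.downsample = Sequential(
                ConvNd(ndim, in_ch, out_ch, 1, stride=stride, rng=rng), BatchNorm(out_ch)
            )

    def forward(self, x):
        identity = self.downsample(x) if self.downsample else x
        out = self.relu1(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        return self.relu2(out + identity)

    def backward(self, grad):
        grad = self.relu2.backward(grad)
        g_id = grad
        g = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(
                self.conv2.backward(self.bn2.backward(grad))
            ))
        )
        if self.downsample:
            g = g + self.downsample.backward(g_id)
        else:
            g = g + g_id
        return g


class ResNet(Module):
    """Generic 2D/3D residual classifier with a 2-way softmax head."""

    def __init__(
        self,
        ndim: int,
        block: type,
        layers: tuple[int, ...],
        in_channels: int,
        n_outputs: int = 2,
        groups: int = 1,
        base_width: int = 64,
        width_mult: float = 1.0,
        stem: str = "7x7",
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.ndim = ndim
        stem_ch = _scale(64, width_mult)
        if stem == "7x7":
            self.stem_conv = ConvNd(ndim, in_channels, stem_ch, 7, stride=2, padding=3, rng=rng)
        else:  # 3x3 stem, the 3D nets' 3x3x3 first layer
            self.stem_conv = ConvNd(ndim, in_channels, stem_ch, 3, stride=2, padding=1, rng=rng)
        self.stem_bn = BatchNorm(stem_ch)
        self.stem_relu = ReLU()
        self.maxpool = MaxPoolNd(ndim, 3, 2, 1)
        self.stages: list[Module] = []
        in_ch = stem_ch
        for si, (planes, n_blocks) in enumerate(zip((64, 128, 256, 512), layers)):
            stride = 1 if si == 0 else 2
            out_ch = _scale(planes * block.expansion, width_mult)
            blocks = []
            for bi in range(n_blocks):
                if block is Bottleneck:
                    width = _scale(
                        int(planes * base_width / 64.0) * groups, width_mult, multiple=groups
                    )
                else:
                    width = out_ch
                blocks.append(
                    block(ndim, in_ch, width, out_ch, stride if bi == 0 else 1,
                          groups if block is Bottleneck else 1, rng)
                )
                in_ch = out_ch
            self.stages.append(Sequential(*blocks))
        self.gap = GlobalAvgPool()
        self.fc = Linear(in_ch, n_outputs, rng=rng)
        self.n_outputs = n_outputs

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        x = self.maxpool(self.stem_relu(self.stem_bn(self.stem_conv(x))))
        for stage in self.stages:
            x = stage(x)
        return self.fc(self.gap(x))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.gap.backward(self.fc.backward(grad))
        for stage in reversed(self.stages):
            grad = stage.backward(grad)
        return self.stem_conv.backward(
            self.stem_bn.backward(self.stem_relu.backward(self.maxpool.backward(grad)))
        )


def resnet50_2d(width_mult=1.0, in_channels=3, seed=0) -> ResNet:
    return ResNet(2, Bottleneck, (3, 4, 6, 3), in_channels, width_mult=width_mult, seed=seed)


def resnext50_2d_c32(width_mult=1.0, in_channels=3, seed=0, cardinality=32) -> ResNet:
    return ResNet(
        2, Bottleneck, (3, 4, 6, 3), in_channels,
        groups=cardinality, base_width=4, width_mult=width_mult, seed=seed,
    )


def resnet18_3d(width_mult=1.0, in_channels=1, seed=0) -> ResNet:
    return ResNet(3, BasicBlock, (2, 2, 2, 2), in_channels, width_mult=width_mult,
                  stem="3x3", seed=seed)


def resnet50_3d(width_mult=1.0, in_channels=1, seed=0) -> ResNet:
    return ResNet(3, Bottleneck, (3, 4, 6, 3), in_channels, width_mult=width_mult,
                  stem="3x3", seed=seed)
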