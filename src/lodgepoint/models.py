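"""Canonical CNN classifier architectures built on the NumPy framework.

Three image classifiers are provided for lodging-degree recognition:
AlexNet, VGG16 (13 convolutional + 3 fully connected layers) and
MobileNetV2 (inverted residuals with linear bottlenecks).  Layer plans
follow the standard published architectures, so at a 1000-class output the
trainable parameter totals are the canonical 61,100,840 / 138,357,544 /
3,504,872.  MobileNetV2 additionally accepts a width multiplier so a
scaled-down variant can be trained on CPU at reduced resolution.
"""

from __future__ import annotations

import numpy as np

from .nn import (
    AdaptiveAvgPool2d,
    BatchNorm2d,
    Conv2d,
    Dropout,
    Flatten,
    Linear,
    MaxPool2d,
    Network,
    ReLU,
    ReLU6,
    Residual,
    Sequential,
)

__all__ = ["build_model", "count_parameters", "MODEL_NAMES"]

MODEL_NAMES = ("alexnet", "vgg16", "mobilenetv2")


def count_parameters(model: Network) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(p.value.size for p in model.params()))


def _alexnet(num_classes: int, rng: np.random.Generator) -> Network:
    body = Sequential(
        Conv2d(3, 64, 11, stride=4, padding=2, rng=rng), ReLU(), MaxPool2d(3, 2),
        Conv2d(64, 192, 5, padding=2, rng=rng), ReLU(), MaxPool2d(3, 2),
        Conv2d(192, 384, 3, padding=1, rng=rng), ReLU(),
        Conv2d(384, 256, 3, padding=1, rng=rng), ReLU(),
        Conv2d(256, 256, 3, padding=1, rng=rng), ReLU(), MaxPool2d(3, 2),
        AdaptiveAvgPool2d(6),
        Flatten(),
        Dropout(0.5), Linear(256 * 6 * 6, 4096, rng=rng), ReLU(),
        Dropout(0.5), Linear(4096, 4096, rng=rng), ReLU(),
        Linear(4096, num_classes, rng=rng),
    )
    return Network(body, "alexnet")


_VGG16_PLAN = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
               512, 512, 512, "M", 512, 512, 512, "M"]


def _vgg16(num_classes: int, rng: np.random.Generator) -> Network:
    layers: list = []
    cin = 3
    for item in _VGG16_PLAN:
        if item == "M":
            layers.append(MaxPool2d(2, 2))
        else:
            layers += [Conv2d(cin, item, 3, padding=1, rng=rng), ReLU()]
            cin = item
    layers += [
        AdaptiveAvgPool2d(7),
        Flatten(),
        Linear(512 * 7 * 7, 4096, rng=rng), ReLU(), Dropout(0.5),
        Linear(4096, 4096, rng=rng), ReLU(), Dropout(0.5),
        Linear(4096, num_classes, rng=rng),
    ]
    return Network(Sequential(*layers), "vgg16")


def _make_divisible(v: float, divisor: int = 8) -> int:
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


def _conv_bn_relu6(cin: int, cout: int, k: int, stride: int, groups: int,
                   rng: np.random.Generator) -> list:
    pad = (k - 1) // 2
    return [
        Conv2d(cin, cout, k, stride=stride, padding=pad, groups=groups, bias=False, rng=rng),
        BatchNorm2d(cout),
        ReLU6(),
    ]


def _inverted_residual(cin: int, cout: int, stride: int, expand: int,
                       rng: np.random.Generator):
    hidden = int(round(cin * expand))
    layers: list = []
    if expand != 1:
        layers += _conv_bn_relu6(cin, hidden, 1, 1, 1, rng)  # pointwise expand
    layers += _conv_bn_relu6(hidden, hidden, 3, stride, hidden, rng)  # depthwise
    layers += [  # linear bottleneck projection (no activation)
        Conv2d(hidden, cout, 1, bias=False, rng=rng),
        BatchNorm2d(cout),
    ]
    body = Sequential(*layers)
    if stride == 1 and cin == cout:
        return Residual(body)
    return body


# (expansion t, channels c, repeats n, first stride s)
_MOBILENETV2_PLAN = [
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
]


def _mobilenetv2(num_classes: int, rng: np.random.Generator,
                 width_mult: float = 1.0) -> Network:
    cin = _make_divisible(32 * width_mult)
    layers: list = _conv_bn_relu6(3, cin, 3, 2, 1, rng)
    for t, c, n, s in _MOBILENETV2_PLAN:
        cout = _make_divisible(c * width_mult)
        for i in range(n):
            layers.append(_inverted_residual(cin, cout, s if i == 0 else 1, t, rng))
            cin = cout
    last = _make_divisible(1280 * max(1.0, width_mult))
    layers += _conv_bn_relu6(cin, last, 1, 1, 1, rng)
    layers += [
        AdaptiveAvgPool2d(1),
        Flatten(),
        Dropout(0.2),
        Linear(last, num_classes, rng=rng),
    ]
    return Network(Sequential(*layers), "mobilenetv2")


def build_model(name: str, num_classes: int = 4, seed: int = 0,
                width_mult: float = 1.0) -> Network:
    """Build a seeded, randomly initialised classifier.

    ``width_mult`` only affects MobileNetV2; the softmax classifier head is
    sized to ``num_classes``.  The same seed yields identical initial
    weights.
    """
    rng = np.random.default_rng(seed)
    if name == "alexnet":
        return _alexnet(num_classes, rng)
    if name == "vgg16":
        return _vgg16(num_classes, rng)
    if name == "mobilenetv2":
        return _mobilenetv2(num_classes, rng, width_mult)
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
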