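"""The five time-series classifier architectures.

Layer structures follow the standard review implementations for univariate
time-series classification; widths and kernel sizes are configuration, not
ground truth, and every default can be overridden through
``ModelSpec.hyperparams``.  Default convolutional widths are reduced relative
to the GPU-scale reference configurations so that single-CPU training of a
full pairwise analysis stays tractable; the reference widths can be restored
via hyperparameters.

* ``mlp`` — four fully-connected layers (three hidden ReLU layers with
  dropout, softmax head).  A baseline that ignores temporal structure.
* ``cnn`` — two sigmoid convolution + average-pooling blocks, flatten,
  sigmoid classifier head.
* ``resnet`` — three residual blocks of three convolution+batch-norm layers
  each (9 convolutional layers), global average pooling, softmax: 11 layers.
* ``fcn`` — three convolution/batch-norm/ReLU blocks, global average
  pooling, softmax; no fully-connected hidden layers.
* ``mcdcnn`` — convolution/max-pool blocks applied per input stream (a
  single stream for univariate segments), flatten, dense ReLU, softmax.
"""

from __future__ import annotations

from ._engine import (
    AvgPool1D,
    BatchNorm,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    GlobalAvgPool,
    MaxPool1D,
    Network,
    ReLU,
    Residual,
    Sigmoid,
)


def _conv_bn_relu(c_in: int, c_out: int, k: int) -> list:
    return [Conv1D(c_in, c_out, k), BatchNorm(c_out), ReLU()]


def build_mlp(input_length: int, hp: dict) -> Network:
    width = hp.get("width", 500)
    layers = [
        Dropout(hp.get("dropout_in", 0.1)),
        Dense(input_length, width),
        ReLU(),
        Dropout(hp.get("dropout_hidden", 0.2)),
        Dense(width, width),
        ReLU(),
        Dropout(hp.get("dropout_hidden", 0.2)),
        Dense(width, width),
        ReLU(),
        Dropout(hp.get("dropout_out", 0.3)),
        Dense(width, 2),
    ]
    return Network(layers, head="softmax", conv_input=False)


def build_cnn(input_length: int, hp: dict) -> Network:
    f1, f2 = hp.get("filters", (6, 12))
    k = hp.get("kernel", 7)
    pool = hp.get("pool", 3)
    t = input_length - k + 1  # valid padding
    t = t // pool
    t = t - k + 1
    t = t // pool
    if t < 1:
        raise ValueError("input too short for the CNN architecture")
    layers = [
        Conv1D(1, f1, k, padding="valid"),
        Sigmoid(),
        AvgPool1D(pool),
        Conv1D(f1, f2, k, padding="valid"),
        Sigmoid(),
        AvgPool1D(pool),
        Flatten(),
        Dense(f2 * t, 2),
    ]
    return Network(layers, head="sigmoid")


def build_resnet(input_length: int, hp: dict) -> Network:  # noqa: ARG001
    f1, f2, f3 = hp.get("filters", (16, 32, 32))
    kernels = hp.get("kernels", (8, 5, 3))

    def block(c_in: int, c_out: int) -> Residual:
        k1, k2, k3 = kernels
        body = (
            _conv_bn_relu(c_in, c_out, k1)
            + _conv_bn_relu(c_out, c_out, k2)
            + [Conv1D(c_out, c_out, k3), BatchNorm(c_out)]
        )
        shortcut = (
            [Conv1D(c_in, c_out, 1), BatchNorm(c_out)] if c_in != c_out else [BatchNorm(c_out)]
        )
        return Residual(body, shortcut)

    layers = [block(1, f1), block(f1, f2), block(f2, f3), GlobalAvgPool(), Dense(f3, 2)]
    return Network(layers, head="softmax")


def build_fcn(input_length: int, hp: dict) -> Network:  # noqa: ARG001
    f1, f2, f3 = hp.get("filters", (16, 32, 16))
    k1, k2, k3 = hp.get("kernels", (8, 5, 3))
    layers = (
        _conv_bn_relu(1, f1, k1)
        + _conv_bn_relu(f1, f2, k2)
        + _conv_bn_relu(f2, f3, k3)
        + [GlobalAvgPool(), Dense(f3, 2)]
    )
    return Network(layers, head="softmax")


def build_mcdcnn(input_length: int, hp: dict) -> Network:
    f = hp.get("filters", 8)
    k = hp.get("kernel", 5)
    dense_width = hp.get("dense_width", 64)
    t = input_length - k + 1
    t = t // 2
    t = t - k + 1
    t = t // 2
    if t < 1:
        raise ValueError("input too short for the MCDCNN architecture")
    layers = [
        Conv1D(1, f, k, padding="valid"),
        ReLU(),
        MaxPool1D(2),
        Conv1D(f, f, k, padding="valid"),
        ReLU(),
        MaxPool1D(2),
        Flatten(),
        Dense(f * t, dense_width),
        ReLU(),
        Dense(dense_width, 2),
    ]
    return Network(layers, head="softmax")


BUILDERS = {
    "mlp": build_mlp,
    "cnn": build_cnn,
    "resnet": build_resnet,
    "fcn": build_fcn,
    "mcdcnn": build_mcdcnn,
}
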