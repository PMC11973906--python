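"""Layer modules on top of the autograd core.

Mirrors the familiar ``Module``/``Parameter`` idiom: modules own parameters,
compose recursively, expose ``state_dict``/``load_state_dict`` for plain
``.npz`` checkpoints, and switch between train and eval mode (which only
matters for batch normalization).
"""

from __future__ import annotations

import numpy as np

from . import tensor as F
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal ---------------------------------------------------------
    def children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self.children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self.children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self.children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- serialization -----------------------------------------------------
    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buf:" + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=np.float32).reshape(p.data.shape)
        for name, b in self.named_buffers():
            b[...] = state["buf:" + name]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    """2-D convolution; ``depthwise=True`` gives one filter per channel."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, *,
                 stride: int = 1, dilation: int = 1, padding: int | None = None,
                 depthwise: bool = False, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if depthwise and out_channels != in_channels:
            raise ValueError("depthwise convolution requires out_channels == in_channels")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.dilation = dilation
        self.depthwise = depthwise
        if padding is None:  # 'same' for odd kernels at stride 1
            padding = dilation * (kernel_size - 1) // 2
        self.padding = padding
        rng = rng or np.random.default_rng()
        fan_in = kernel_size * kernel_size * (1 if depthwise else in_channels)
        shape = (out_channels, 1 if depthwise else in_channels,
                 kernel_size, kernel_size)
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), shape))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation,
                        depthwise=self.depthwise)

    def named_parameters(self, prefix: str = ""):
        yield prefix + "weight", self.weight
        if self.bias is not None:
            yield prefix + "bias", self.bias


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        return F.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, training=self.training,
                              momentum=self.momentum, eps=self.eps)


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class ReLU6(Module):
    def forward(self, x):
        return F.relu6(x)


class Sigmoid(Module):
    def forward(self, x):
        return F.sigmoid(x)


class Upsample(Module):
    """Bilinear resize to an absolute size or by an integer factor."""

    def __init__(self, size: tuple[int, int] | None = None, scale: int | None = None):
        super().__init__()
        if (size is None) == (scale is None):
            raise ValueError("give exactly one of size or scale")
        self.size = tuple(size) if size is not None else None
        self.scale = scale

    def forward(self, x):
        size = self.size
        if size is None:
            size = (x.shape[2] * self.scale, x.shape[3] * self.scale)
        return F.resize_bilinear(x, size)


class AdaptiveAvgPool2d(Module):
    def __init__(self, output_size: int | tuple[int, int]):
        super().__init__()
        if isinstance(output_size, int):
            output_size = (output_size, output_size)
        self.output_size = tuple(output_size)

    def forward(self, x):
        return F.adaptive_avg_pool2d(x, self.output_size)
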