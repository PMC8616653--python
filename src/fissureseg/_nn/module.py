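"""Layer and container abstractions on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autodiff as F
from .autodiff import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "DepthwiseConv2d",
    "ConvTranspose2x",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2x2",
    "Linear",
    "Identity",
    "count_params",
]

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class: recursive parameter discovery, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix=""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix=""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode=True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        state = {"param." + k: p.data.copy() for k, p in self.named_parameters()}
        state.update({"buffer." + k: b.copy() for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state):
        for k, p in self.named_parameters():
            src = state["param." + k]
            if src.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {src.shape} vs {p.data.shape}")
            p.data = np.asarray(src, dtype=p.data.dtype).copy()
        for k, b in self.named_buffers():
            b[...] = state["buffer." + k]


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _he_init(rng, shape, fan_in):
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, rng, stride=1,
                 padding=0, bias=True, zero_init=False):
        super().__init__()
        if isinstance(kernel_size, int):
            kernel_size = (kernel_size, kernel_size)
        kh, kw = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kh * kw
        self.struct = ("conv", kh, kw, in_channels, out_channels, bias)
        w = np.zeros((out_channels, in_channels, kh, kw), dtype=DTYPE) if zero_init \
            else _he_init(rng, (out_channels, in_channels, kh, kw), fan_in)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels, kernel_size, rng, padding=0, bias=False):
        super().__init__()
        if isinstance(kernel_size, int):
            kernel_size = (kernel_size, kernel_size)
        kh, kw = kernel_size
        self.padding = padding
        self.struct = ("conv", kh, kw, 1, channels, bias)  # kh*kw per channel
        self.weight = Parameter(_he_init(rng, (channels, kh, kw), kh * kw))
        self.bias = Parameter(np.zeros(channels, dtype=DTYPE)) if bias else None

    def forward(self, x):
        return F.depthwise_conv2d(x, self.weight, self.bias, padding=self.padding)


class ConvTranspose2x(Module):
    """Learnable x2 upsampling: transposed conv, kernel 2, stride 2."""

    def __init__(self, in_channels, out_channels, rng, bias=True):
        super().__init__()
        self.struct = ("conv", 2, 2, in_channels, out_channels, bias)
        self.weight = Parameter(_he_init(rng, (in_channels, out_channels, 2, 2), in_channels * 4))
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE)) if bias else None

    def forward(self, x):
        return F.conv_transpose2x2(x, self.weight, self.bias)


class BilinearUp2x(Module):
    """Fixed (parameter-free) bilinear x2 upsampling."""

    def forward(self, x):
        return F.bilinear_up2x(x)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.struct = ("bn", channels)
        self.gamma = Parameter(np.ones(channels, dtype=DTYPE))
        self.beta = Parameter(np.zeros(channels, dtype=DTYPE))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def forward(self, x):
        return F.batchnorm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            momentum=self.momentum, eps=self.eps, training=self.training,
        )


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class MaxPool2x2(Module):
    def forward(self, x):
        return F.maxpool2x2(x)


class Linear(Module):
    def __init__(self, in_features, out_features, rng, bias=True):
        super().__init__()
        self.struct = ("linear", in_features, out_features, bias)
        self.weight = Parameter(_he_init(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=DTYPE)) if bias else None

    def forward(self, x):
        out = F.matmul(x, self.weight)
        if self.bias is not None:
            out = F.add(out, self.bias)
        return out


class Identity(Module):
    def forward(self, x):
        return x


def count_params(module: Module) -> int:
    """Number of trainable scalars in a module tree."""
    return int(sum(p.data.size for p in module.parameters()))
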