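"""Layer/module abstractions on top of the autograd engine.

Modules hold parameters (Tensors) and submodules discovered by attribute
reflection, expose ``parameters()`` / ``state_dict()`` and a train/eval
switch.  Leaf layers optionally record (module, in/out shape) tuples into an
active :class:`ShapeTrace`, which the complexity module uses to profile
FLOPs without a second bookkeeping path.
"""

from __future__ import annotations

import math

import numpy as np

from . import autograd as ag
from .autograd import Tensor

_ACTIVE_TRACE = None


class ShapeTrace:
    """Context recording every leaf layer call with its in/out shapes."""

    def __init__(self):
        self.records = []  # (module, in_shape, out_shape)

    def __enter__(self):
        global _ACTIVE_TRACE
        self._prev = _ACTIVE_TRACE
        _ACTIVE_TRACE = self
        return self

    def __exit__(self, *exc):
        global _ACTIVE_TRACE
        _ACTIVE_TRACE = self._prev
        return False


def _record(module, in_shape, out_shape):
    if _ACTIVE_TRACE is not None:
        _ACTIVE_TRACE.records.append((module, in_shape, out_shape))


class Module:
    def __init__(self):
        self.training = True

    # -- reflection --------------------------------------------------------
    def _children(self):
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        yield f"{name}.{i}", m

    def _own_params(self):
        for name, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield name, v

    def named_parameters(self, prefix=""):
        for name, p in self._own_params():
            yield prefix + name, p
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization -------------------------------------------------
    def state_dict(self):
        sd = {name: p.data.copy() for name, p in self.named_parameters()}
        for prefix, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                sd[prefix + "running_mean"] = m.running_mean.copy()
                sd[prefix + "running_var"] = m.running_var.copy()
        return sd

    def _named_modules(self, prefix=""):
        yield prefix, self
        for cname, child in self._children():
            yield from child._named_modules(prefix + cname + ".")

    def load_state_dict(self, sd):
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.asarray(sd[name], dtype=np.float32).reshape(p.data.shape)
        for prefix, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(sd[prefix + "running_mean"], np.float32)
                m.running_var = np.asarray(sd[prefix + "running_var"], np.float32)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel, stride=1,
                 padding=None, bias=False, rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels <= 0 or out_channels <= 0:
            raise ValueError("channel counts must be positive")
        if stride not in (1, 2):
            raise ValueError(f"unsupported stride {stride}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = (kernel - 1) // 2 if padding is None else padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel * kernel
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Tensor(
            rng.uniform(-bound, bound, (out_channels, in_channels, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = (
            Tensor(rng.uniform(-bound, bound, out_channels), requires_grad=True)
            if bias else None
        )

    def forward(self, x):
        out = ag.conv2d(x, self.weight, self.bias, self.stride, self.padding)
        _record(self, x.shape, out.shape)
        return out


class BatchNorm2d(Module):
    def __init__(self, channels, eps=1e-3, momentum=0.03):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.weight = Tensor(np.ones(channels), requires_grad=True)
        self.bias = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        out = ag.batchnorm(x, self.weight, self.bias, self.running_mean,
                           self.running_var, self.training, self.momentum,
                           self.eps)
        _record(self, x.shape, out.shape)
        return out


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class MaxPool2d(Module):
    """Either 2x2/stride-2 downsampling pool or k x k/stride-1 same pool."""

    def __init__(self, kernel=2, stride=2):
        super().__init__()
        if not ((kernel == 2 and stride == 2) or stride == 1):
            raise ValueError("supported pools: 2x2 stride 2, or stride-1 same")
        self.kernel = kernel
        self.stride = stride

    def forward(self, x):
        if self.stride == 2:
            out = ag.maxpool2x2(x)
        else:
            out = ag.maxpool_same(x, self.kernel)
        _record(self, x.shape, out.shape)
        return out


class Upsample(Module):
    def forward(self, x):
        out = ag.upsample2x(x)
        _record(self, x.shape, out.shape)
        return out


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.mods)

    def __getitem__(self, i):
        return self.mods[i]
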