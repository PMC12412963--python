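"""Network building blocks for the fruit detector.

The vocabulary follows the architecture's own block names:

* ``CBS``  — convolution + batch norm + SiLU, the universal unit.
* ``MPC``  — two-branch downsampler: each branch opens with a 1x1 CBS at the
  incoming resolution; one branch then max-pools 2x2/s2, the other applies a
  3x3 stride-2 CBS.  The halves are concatenated, so downsampling mixes a
  pooled (high-frequency-preserving) view with a learned strided view.
* ``C4``   — the bottleneck replacement: a 1x1 CBS expands ``c -> 2c``, the
  result is split channel-wise into two halves, each half runs through its
  own 3x3 CBS, and a final 1x1 CBS projects the concatenation back to ``c``.
  Exactly four CBS units, no residual addition.
* ``C2fR`` — cross-stage partial block with C4 inside: two parallel 1x1 CBS
  entries at half width; one stream passes through a chain of C4 units; the
  two streams are concatenated and fused by a final 1x1 CBS.
* ``SPPR`` — reduced spatial pyramid pooling: one 5x5 stride-1 max pool
  (instead of SPPF's three chained pools), concatenated with its input and
  projected.

``C3`` (YOLOv5) and ``C2f``/``SPPF`` (YOLOv8) are included as faithful
references for the ablation variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .nn import autograd as ag
from .nn.layers import BatchNorm2d, Conv2d, MaxPool2d, Module, SiLU


class BlockKind(str, Enum):
    CBS = "CBS"
    C3 = "C3"
    C2F = "C2f"
    C4 = "C4"
    C2FR = "C2fR"
    MPC = "MPC"
    SPPR = "SPPR"
    SPPF = "SPPF"
    UPSAMPLE = "Upsample"
    CONCAT = "Concat"
    HEAD = "Head"


@dataclass(frozen=True)
class BlockSpec:
    """Declarative description of one block; drives construction and the
    per-layer rows of the complexity report."""

    kind: BlockKind
    in_channels: int
    out_channels: int
    kernel: int = 1
    stride: int = 1
    repeats: int = 1

    def __post_init__(self):
        if self.in_channels <= 0 or self.out_channels <= 0:
            raise ValueError("channels must be positive")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class FeatureMapSpec:
    channels: int
    height: int
    width: int
    stride_from_input: int

    def __post_init__(self):
        s = self.stride_from_input
        if s < 1 or (s & (s - 1)):
            raise ValueError("stride_from_input must be a power of two")


class CBS(Module):
    """Conv (no bias) + BatchNorm + SiLU."""

    def __init__(self, c1, c2, k=1, s=1, rng=None):
        super().__init__()
        self.conv = Conv2d(c1, c2, k, s, bias=False, rng=rng)
        self.bn = BatchNorm2d(c2)
        self.act = SiLU()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


def make_cbs(in_channels, out_channels, kernel, stride, rng=None) -> CBS:
    return CBS(in_channels, out_channels, kernel, stride, rng=rng)


class MPC(Module):
    """Maxpool-plus-conv downsampler; output channels split evenly across
    the pooled branch and the strided-conv branch."""

    def __init__(self, c1, c2, rng=None):
        super().__init__()
        if c2 % 2:
            raise ValueError("MPC out_channels must be even")
        c = c2 // 2
        self.cv_pool = CBS(c1, c, 1, 1, rng=rng)
        self.pool = MaxPool2d(2, 2)
        self.cv_pre = CBS(c1, c, 1, 1, rng=rng)
        self.cv_down = CBS(c, c, 3, 2, rng=rng)

    def forward(self, x):
        a = self.pool(self.cv_pool(x))
        b = self.cv_down(self.cv_pre(x))
        return ag.cat([a, b], axis=1)


def make_mpc(in_channels, out_channels, rng=None) -> MPC:
    return MPC(in_channels, out_channels, rng=rng)


class C4(Module):
    """Four-CBS split/concat unit (bottleneck replacement, no residual)."""

    def __init__(self, c, rng=None):
        super().__init__()
        if c % 2:
            raise ValueError("C4 channels must be even")
        self.cv1 = CBS(c, 2 * c, 1, 1, rng=rng)
        self.cv2 = CBS(c, c, 3, 1, rng=rng)
        self.cv3 = CBS(c, c, 3, 1, rng=rng)
        self.cv4 = CBS(2 * c, c, 1, 1, rng=rng)
        self._c = c

    def forward(self, x):
        y = self.cv1(x)
        a, b = y[:, : self._c], y[:, self._c:]
        return self.cv4(ag.cat([self.cv2(a), self.cv3(b)], axis=1))


def make_c4(channels, rng=None) -> C4:
    return C4(channels, rng=rng)


class C2fR(Module):
    """Cross-stage block with a C4 chain.

    Two wrapper topologies exist for this block and both are kept:

    * ``retain=False`` (default, the calibrated choice): two half-width
      1x1 CBS entries, C4 units chained on one stream, concatenation of
      the two streams, 1x1 CBS fuse — three wrapper CBS in total.
    * ``retain=True``: C2f-style — one 1x1 CBS entry producing two
      half-width streams, every intermediate C4 output retained, all
      streams concatenated into the fuse CBS.
    """

    def __init__(self, c1, c2, n=1, retain=False, rng=None):
        super().__init__()
        if c2 % 2:
            raise ValueError("C2fR out_channels must be even")
        if n < 1:
            raise ValueError("n_repeats must be >= 1")
        c = c2 // 2
        self.retain = retain
        self._c = c
        if retain:
            self.cv1 = CBS(c1, 2 * c, 1, 1, rng=rng)
            self.m = [C4(c, rng=rng) for _ in range(n)]
            self.cv3 = CBS((2 + n) * c, c2, 1, 1, rng=rng)
        else:
            self.cv1 = CBS(c1, c, 1, 1, rng=rng)
            self.cv2 = CBS(c1, c, 1, 1, rng=rng)
            self.m = [C4(c, rng=rng) for _ in range(n)]
            self.cv3 = CBS(2 * c, c2, 1, 1, rng=rng)

    def forward(self, x):
        if self.retain:
            y = self.cv1(x)
            ys = [y[:, : self._c], y[:, self._c:]]
            for m in self.m:
                ys.append(m(ys[-1]))
            return self.cv3(ag.cat(ys, axis=1))
        y = self.cv1(x)
        for m in self.m:
            y = m(y)
        return self.cv3(ag.cat([y, self.cv2(x)], axis=1))


def make_c2fr(in_channels, out_channels, n_repeats=1, retain=False,
              rng=None) -> C2fR:
    return C2fR(in_channels, out_channels, n_repeats, retain, rng=rng)


class Bottleneck(Module):
    """Standard residual bottleneck (1x1 then 3x3 for C3; 3x3/3x3 for C2f)."""

    def __init__(self, c1, c2, shortcut=True, k=(1, 3), e=1.0, rng=None):
        super().__init__()
        ch = int(c2 * e)
        self.cv1 = CBS(c1, ch, k[0], 1, rng=rng)
        self.cv2 = CBS(ch, c2, k[1], 1, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(Module):
    """YOLOv5 cross-stage partial block (reference implementation)."""

    def __init__(self, c1, c2, n=1, shortcut=True, rng=None):
        super().__init__()
        c = c2 // 2
        self.cv1 = CBS(c1, c, 1, 1, rng=rng)
        self.cv2 = CBS(c1, c, 1, 1, rng=rng)
        self.m = [Bottleneck(c, c, shortcut, k=(1, 3), e=1.0, rng=rng)
                  for _ in range(n)]
        self.cv3 = CBS(2 * c, c2, 1, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        for m in self.m:
            y = m(y)
        return self.cv3(ag.cat([y, self.cv2(x)], axis=1))


class C2f(Module):
    """YOLOv8 cross-stage block (reference implementation): all intermediate
    bottleneck outputs are retained and concatenated."""

    def __init__(self, c1, c2, n=1, shortcut=True, rng=None):
        super().__init__()
        if c2 % 2:
            raise ValueError("C2f out_channels must be even")
        self._c = c2 // 2
        self.cv1 = CBS(c1, 2 * self._c, 1, 1, rng=rng)
        self.m = [Bottleneck(self._c, self._c, shortcut, k=(3, 3), e=1.0, rng=rng)
                  for _ in range(n)]
        self.cv2 = CBS((2 + n) * self._c, c2, 1, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        ys = [y[:, : self._c], y[:, self._c:]]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(ag.cat(ys, axis=1))


def make_c3(in_channels, out_channels, n_repeats=1, shortcut=True, rng=None) -> C3:
    return C3(in_channels, out_channels, n_repeats, shortcut, rng=rng)


def make_c2f(in_channels, out_channels, n_repeats=1, shortcut=True, rng=None) -> C2f:
    return C2f(in_channels, out_channels, n_repeats, shortcut, rng=rng)


class SPPR(Module):
    """Reduced spatial pyramid pooling: a single 5x5 stride-1 max pool."""

    def __init__(self, c1, c2, k=5, rng=None):
        super().__init__()
        c = c1 // 2
        self.cv1 = CBS(c1, c, 1, 1, rng=rng)
        self.pool = MaxPool2d(k, 1)
        self.cv2 = CBS(2 * c, c2, 1, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        return self.cv2(ag.cat([y, self.pool(y)], axis=1))


def make_sppr(in_channels, out_channels, rng=None) -> SPPR:
    return SPPR(in_channels, out_channels, rng=rng)


class SPPF(Module):
    """YOLOv5 fast spatial pyramid pooling (three chained 5x5 pools)."""

    def __init__(self, c1, c2, k=5, rng=None):
        super().__init__()
        c = c1 // 2
        self.cv1 = CBS(c1, c, 1, 1, rng=rng)
        self.pool = MaxPool2d(k, 1)
        self.cv2 = CBS(4 * c, c2, 1, 1, rng=rng)

    def forward(self, x):
        y1 = self.cv1(x)
        y2 = self.pool(y1)
        y3 = self.pool(y2)
        y4 = self.pool(y3)
        return self.cv2(ag.cat([y1, y2, y3, y4], axis=1))


_SLOT_BUILDERS = {
    "C3": lambda c1, c2, n, rng: C3(c1, c2, n, rng=rng),
    "C2f": lambda c1, c2, n, rng: C2f(c1, c2, n, rng=rng),
    "C2fR": lambda c1, c2, n, rng: C2fR(c1, c2, n, rng=rng),
}


def build_slot(kind: str, c1: int, c2: int, n: int, rng=None) -> Module:
    """Instantiate a backbone C-slot block by kind name."""
    try:
        return _SLOT_BUILDERS[kind](c1, c2, n, rng)
    except KeyError:
        raise ValueError(f"unknown slot kind {kind!r}") from None
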