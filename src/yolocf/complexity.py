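"""Parameter and FLOP accounting.

Two counting conventions are provided:

* ``mac2_standard`` — the convention detector papers on the YOLOv5 platform
  report: two operations per multiply-accumulate, summed over every
  convolution (bias adds included), pooling/activation/concat/upsample
  ignored.  This is the convention used for the headline GFLOPs numbers.
* ``eq7_paper`` — a layer-wise "output area x layer parameters" rendering
  (one operation per MAC, batch-norm parameters included); kept as a
  documentation-grade alternative.

Parameter counts always include batch-norm affine terms and are obtained by
enumerating the model's actual arrays; an analytic re-derivation from layer
hyper-parameters (`count_params_analytic`) is exposed so the two paths can
be cross-checked.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass

import numpy as np

from .nn.layers import BatchNorm2d, Conv2d, ShapeTrace
from .model import Detector

CONVENTIONS = ("mac2_standard", "eq7_paper")


@dataclass
class LayerRow:
    name: str
    kind: str
    params: int
    flops: float  # raw op count at the profiled input


@dataclass
class ComplexityReport:
    rows: list
    total_params: int
    gflops: float
    convention: str
    input_hw: tuple

    def __post_init__(self):
        assert self.total_params == sum(r.params for r in self.rows)

    @property
    def params_m(self) -> float:
        return self.total_params / 1e6

    def to_table(self) -> str:
        lines = [f"{'layer':<28}{'kind':<14}{'params':>12}{'GFLOPs':>10}"]
        for r in self.rows:
            lines.append(f"{r.name:<28}{r.kind:<14}{r.params:>12d}"
                         f"{r.flops / 1e9:>10.3f}")
        lines.append(f"{'TOTAL':<28}{'':<14}{self.total_params:>12d}"
                     f"{self.gflops:>10.3f}")
        return "\n".join(lines)

    def to_csv(self, path=None) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["layer", "kind", "params", "gflops"])
        for r in self.rows:
            w.writerow([r.name, r.kind, r.params, r.flops / 1e9])
        w.writerow(["TOTAL", "", self.total_params, self.gflops])
        if path:
            with open(path, "w") as f:
                f.write(buf.getvalue())
        return buf.getvalue()

    def to_json(self, path=None) -> str:
        d = {"convention": self.convention, "input_hw": list(self.input_hw),
             "total_params": self.total_params, "gflops": self.gflops,
             "layers": [{"name": r.name, "kind": r.kind, "params": r.params,
                         "gflops": r.flops / 1e9} for r in self.rows]}
        s = json.dumps(d, indent=1)
        if path:
            with open(path, "w") as f:
                f.write(s)
        return s


def _module_params(module) -> int:
    return sum(p.data.size for p in module.parameters())


def count_params(model) -> int:
    """Total trainable scalars (conv kernels, biases, BN affine terms)."""
    return _module_params(model)


def count_params_analytic(model) -> int:
    """Independent re-derivation from layer hyper-parameters alone:
    conv = i*k*k*o (+o if biased); BN = 2 per channel."""
    total = 0
    for m in model.modules():
        if isinstance(m, Conv2d):
            total += m.in_channels * m.kernel ** 2 * m.out_channels
            if m.bias is not None:
                total += m.out_channels
        elif isinstance(m, BatchNorm2d):
            total += 2 * m.channels
    return total


def _trace(model, input_hw):
    H, W = input_hw
    if H % 32 or W % 32:
        raise ValueError("input size must be divisible by 32")
    was_training = model.training
    model.eval()
    with ShapeTrace() as tr:
        model(np.zeros((1, 3, H, W), dtype=np.float32))
    if was_training:
        model.train()
    return tr.records


def count_flops(model, input_hw=(640, 640), convention="mac2_standard") -> float:
    """Forward-pass cost in GFLOPs for one image at `input_hw`."""
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    total = 0.0
    for mod, _in, out in _trace(model, input_hw):
        area = out[2] * out[3]
        if convention == "mac2_standard":
            if isinstance(mod, Conv2d):
                total += 2.0 * area * mod.in_channels * mod.kernel ** 2 * mod.out_channels
                if mod.bias is not None:
                    total += area * mod.out_channels
        else:  # eq7_paper: output area x layer params
            if isinstance(mod, Conv2d):
                p = mod.in_channels * mod.kernel ** 2 * mod.out_channels
                if mod.bias is not None:
                    p += mod.out_channels
                total += area * p
            elif isinstance(mod, BatchNorm2d):
                total += area * 2 * mod.channels
    return total / 1e9


def summary(model: Detector, input_hw=(640, 640),
            convention="mac2_standard") -> ComplexityReport:
    """Per-layer complexity table mirroring the variant-comparison columns."""
    records = _trace(model, input_hw)
    # attribute each leaf record to its top-level named layer
    owner = {}
    for name, block in model._children():
        for m in block.modules():
            owner[id(m)] = (name, type(block).__name__)
    per_layer = {}
    order = []
    for mod, _in, out in records:
        name, kind = owner.get(id(mod), (type(mod).__name__, type(mod).__name__))
        if name not in per_layer:
            per_layer[name] = LayerRow(name, kind, 0, 0.0)
            order.append(name)
        row = per_layer[name]
        area = out[2] * out[3]
        if isinstance(mod, Conv2d):
            if convention == "mac2_standard":
                row.flops += 2.0 * area * mod.in_channels * mod.kernel ** 2 * mod.out_channels
                if mod.bias is not None:
                    row.flops += area * mod.out_channels
            else:
                p = mod.in_channels * mod.kernel ** 2 * mod.out_channels
                if mod.bias is not None:
                    p += mod.out_channels
                row.flops += area * p
        elif isinstance(mod, BatchNorm2d) and convention == "eq7_paper":
            row.flops += area * 2 * mod.channels
    # params per top-level layer (independent of tracing)
    for name, block in model._children():
        if name in per_layer:
            per_layer[name].params = _module_params(block)
    rows = [per_layer[n] for n in order]
    total_p = sum(r.params for r in rows)
    gflops = sum(r.flops for r in rows) / 1e9
    return ComplexityReport(rows, total_p, gflops, convention, tuple(input_hw))


def variant_complexity(num_classes: int = 7, input_hw=(640, 640),
                       variants=("cf1", "cf2", "cf3", "cf4", "cf5")) -> dict:
    """Params (M) and GFLOPs for each ablation variant — the quantities the
    architecture-comparison tables print."""
    from .model import ModelConfig, build_model

    out = {}
    for v in variants:
        m = build_model(ModelConfig(num_classes=num_classes, variant=v))
        p = count_params(m)
        assert p == count_params_analytic(m)
        g = count_flops(m, input_hw, "mac2_standard")
        out[v] = {"params": p, "params_m": p / 1e6, "gflops": g}
    return out
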