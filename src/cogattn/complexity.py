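"""Analytic complexity accounting: parameters, MACs, FLOPs, model size.

Counts come from a symbolic traversal (a shape-tracked forward pass on a
zero batch of size one), never from execution timing, so they are invariant
to batch size and hardware.  The convention is documented and fixed:

* one multiply-accumulate (MAC) = 2 FLOPs;
* convolution MACs = (Cin/groups) * k_h * k_w * Cout * H_out * W_out,
  linear MACs = in_features * out_features; a bias adds one FLOP per output
  element;
* normalization, activations and pooling are counted as one elementwise
  pass (1 FLOP per element, 0 MACs); identity/reshape layers are free.

Under this convention ``flops == 2 * macs`` holds exactly for any model made
only of bias-free convolutions and linear layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn
from ._tensor import Tensor, no_grad

__all__ = ["ComplexityReport", "count_parameters", "count_flops_macs",
           "model_size_bytes", "complexity_report"]


def count_parameters(model) -> int:
    """Total number of trainable parameter elements."""
    return int(sum(p.data.size for p in model.parameters()))


def _prod(shape):
    return int(np.prod(shape)) if shape else 0


def _cost_conv(mod, in_shapes, out_shape):
    n, cout, ho, wo = out_shape
    cin_g = mod.in_channels // mod.groups
    kh, kw = mod.kernel_size
    macs = n * cout * ho * wo * cin_g * kh * kw
    flops = 2 * macs + (n * cout * ho * wo if mod.bias is not None else 0)
    return macs, flops


def _cost_linear(mod, in_shapes, out_shape):
    n = _prod(out_shape[:-1])
    macs = n * mod.in_features * mod.out_features
    flops = 2 * macs + (n * mod.out_features if mod.bias is not None else 0)
    return macs, flops


def _cost_elementwise(mod, in_shapes, out_shape):
    return 0, _prod(out_shape)


def _cost_input_pass(mod, in_shapes, out_shape):
    return 0, _prod(in_shapes[0]) if in_shapes else 0


def _cost_free(mod, in_shapes, out_shape):
    return 0, 0


_RULES = {
    nn.Conv2d: _cost_conv,
    nn.Linear: _cost_linear,
    nn.BatchNorm2d: _cost_elementwise,
    nn.ReLU: _cost_elementwise,
    nn.Sigmoid: _cost_elementwise,
    nn.MaxPool2d: _cost_input_pass,
    nn.GlobalAvgPool2d: _cost_input_pass,
    nn.Identity: _cost_free,
    nn.Flatten: _cost_free,
}


def count_flops_macs(model, input_shape=(3, 224, 224)) -> tuple[int, int]:
    """(flops, macs) for one forward pass on a single input of ``input_shape``.

    Raises a LookupError naming any leaf layer type without a registered
    cost rule.
    """
    was_training = model.training
    model.eval()
    try:
        with no_grad(), nn.profile_scope() as prof:
            model(Tensor(np.zeros((1, *input_shape), dtype=np.float32)))
    finally:
        model.train(was_training)
    macs = flops = 0
    unknown = []
    for mod, in_shapes, out_shape in prof.records:
        rule = _RULES.get(type(mod))
        if rule is None:
            unknown.append(type(mod).__name__)
            continue
        m, f = rule(mod, in_shapes, out_shape)
        macs += m
        flops += f
    if unknown:
        raise LookupError("no cost rule registered for layer type(s): "
                          + ", ".join(sorted(set(unknown))))
    return int(flops), int(macs)


def model_size_bytes(model, dtype_bytes: int = 4) -> int:
    """Serialized weight payload: parameter count times element width."""
    if dtype_bytes not in (2, 4, 8):
        raise ValueError("dtype_bytes must be one of 2, 4, 8")
    return count_parameters(model) * dtype_bytes


@dataclass(frozen=True)
class ComplexityReport:
    parameters: int
    flops: int
    macs: int
    size_bytes: int
    input_shape: tuple

    @property
    def parameters_m(self) -> float:
        return round(self.parameters / 1e6, 2)

    @property
    def flops_g(self) -> float:
        return self.flops / 1e9

    @property
    def macs_g(self) -> float:
        return self.macs / 1e9

    @property
    def size_mb(self) -> float:
        return self.size_bytes / 2 ** 20

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters,
            "parameters_m": self.parameters_m,
            "flops": self.flops,
            "flops_g": round(self.flops_g, 4),
            "macs": self.macs,
            "macs_g": round(self.macs_g, 4),
            "model_size_bytes": self.size_bytes,
            "model_size_mb": round(self.size_mb, 2),
            "input_shape": list(self.input_shape),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_table(self, name: str = "model") -> str:
        head = f"{'Architecture':<20}{'Parameters (M)':>16}{'Model size (MB)':>17}" \
               f"{'FLOPs (G)':>12}{'MACs (G)':>12}"
        row = f"{name:<20}{self.parameters_m:>16.2f}{self.size_mb:>17.2f}" \
              f"{self.flops_g:>12.4f}{self.macs_g:>12.4f}"
        return head + "\n" + row


def complexity_report(model, input_shape=(3, 224, 224), dtype_bytes: int = 4) -> ComplexityReport:
    flops, macs = count_flops_macs(model, input_shape)
    return ComplexityReport(parameters=count_parameters(model), flops=flops, macs=macs,
                            size_bytes=model_size_bytes(model, dtype_bytes),
                            input_shape=tuple(input_shape))
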