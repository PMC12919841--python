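"""Parallel and sequential channel-spatial attention blocks (PCAB / SCAB).

Both blocks combine a *channel* attention branch (a "what" pathway: global
average and max pooling over spatial positions, fed through a shared
bottleneck MLP with reduction ratio R) and a *spatial* attention branch (a
"where" pathway: average and max pooling across channels, fused into a single
H x W map and passed through a dilated convolution plus batch normalization).

The two designs differ in how the branches compose:

* **PCAB** (parallel): the un-squashed channel map ``M_C`` (length C) and
  spatial map ``M_S`` (H x W) are broadcast against each other, summed, and a
  single sigmoid produces the channel-spatial map
  ``M_CS = sigmoid(M_C + M_S)`` in (0,1)^{C x H x W}.  The block output is the
  residual ``F + F * M_CS``.

* **SCAB** (sequential): channel attention is applied first,
  ``F_C = F * sigmoid(M_C(F))``, and the spatial map is computed *from the
  channel-refined features*, ``M_S = sigmoid(BN(DC(GAP(F_C) + GMP(F_C))))``.
  The output is ``F + F_C * M_S``.

Because every attention map lies in (0,1), both blocks satisfy the bounded
residual gain ``|output| <= 2 |input|`` elementwise, and both preserve the
(C, H, W) shape exactly.

The ablation axes reported for these blocks are exposed as configuration:
``pooling_mode`` selects GAP-only, GMP-only or their sum; ``conv_mode``
selects a standard (dilation 1) or dilated (dilation 2 by default) spatial
convolution; ``channel_fusion`` selects whether the two channel descriptors
are summed before or after the shared MLP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from ._tensor import Tensor, no_grad

__all__ = [
    "AttentionConfig", "PCAB", "SCAB", "make_block",
    "pool_channel_descriptors", "pool_spatial_descriptors", "shared_mlp",
    "channel_branch", "spatial_branch", "pcab_forward", "scab_forward",
]

POOLING_MODES = ("avg_only", "max_only", "avg_plus_max")
CONV_MODES = ("standard", "dilated")
CHANNEL_FUSIONS = ("sum_then_mlp", "mlp_then_sum")


@dataclass(frozen=True)
class AttentionConfig:
    """Structural hyperparameters shared by PCAB and SCAB.

    Parameters
    ----------
    reduction_ratio:
        Bottleneck factor R of the shared MLP; hidden width is
        ``max(1, C // R)``.  Default 16.
    kernel_size:
        Odd spatial-convolution kernel size; default 7.
    dilation:
        Dilation rate d of the spatial convolution when ``conv_mode`` is
        ``"dilated"``; the effective receptive field is ``k + (k-1)(d-1)``.
        Default 2.
    pooling_mode:
        ``"avg_plus_max"`` (default) fuses GAP and GMP descriptors by
        elementwise sum; ``"avg_only"`` / ``"max_only"`` use one descriptor.
    conv_mode:
        ``"dilated"`` (default) or ``"standard"`` (dilation forced to 1).
    channel_fusion:
        ``"mlp_then_sum"`` (default): ``MLP(GAP) + MLP(GMP)``;
        ``"sum_then_mlp"``: ``MLP(GAP + GMP)``.
    conv_bias:
        Whether the spatial convolution carries a bias term.
    """

    reduction_ratio: int = 16
    kernel_size: int = 7
    dilation: int = 2
    pooling_mode: str = "avg_plus_max"
    conv_mode: str = "dilated"
    channel_fusion: str = "mlp_then_sum"
    conv_bias: bool = True

    def __post_init__(self):
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be a positive integer")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and positive "
                             "(even kernels admit no symmetric same-padding)")
        if self.dilation < 1:
            raise ValueError("dilation must be a positive integer")
        if self.pooling_mode not in POOLING_MODES:
            raise ValueError(f"pooling_mode must be one of {POOLING_MODES}")
        if self.conv_mode not in CONV_MODES:
            raise ValueError(f"conv_mode must be one of {CONV_MODES}")
        if self.channel_fusion not in CHANNEL_FUSIONS:
            raise ValueError(f"channel_fusion must be one of {CHANNEL_FUSIONS}")

    @property
    def effective_dilation(self) -> int:
        return 1 if self.conv_mode == "standard" else self.dilation

    @property
    def effective_field(self) -> int:
        k, d = self.kernel_size, self.effective_dilation
        return k + (k - 1) * (d - 1)


def _check_feature_map(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values)
    if values.ndim != 3:
        raise ValueError(f"feature map must be 3-D (C,H,W), got shape {values.shape}")
    if min(values.shape) < 1:
        raise ValueError(f"feature map dimensions must all be >= 1, got {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError("feature map contains NaN or Inf")
    return values


class _AttentionBase(nn.Module):
    """Shared machinery of PCAB and SCAB: MLP, dilated conv, batch norm."""

    def __init__(self, channels: int, config: AttentionConfig | None = None):
        super().__init__()
        if channels < 1:
            raise ValueError("channels must be >= 1")
        config = config or AttentionConfig()
        object.__setattr__(self, "config", config)
        self.channels = channels
        hidden = max(1, channels // config.reduction_ratio)
        self.hidden = hidden
        self.fc1 = nn.Linear(channels, hidden)
        self.fc2 = nn.Linear(hidden, channels)
        d = config.effective_dilation
        k = config.kernel_size
        self.spatial_conv = nn.Conv2d(1, 1, k, padding=d * (k - 1) // 2,
                                      dilation=d, bias=config.conv_bias)
        self.spatial_bn = nn.BatchNorm2d(1)

    # -- sub-computations --------------------------------------------------
    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(self.fc1(v).relu())

    def channel_map(self, x: Tensor, apply_sigmoid: bool) -> Tensor:
        """Channel attention logits/map of shape (N, C)."""
        mode = self.config.pooling_mode
        avg = x.mean(axis=(2, 3)) if mode != "max_only" else None
        mx = x.max(axis=(2, 3)) if mode != "avg_only" else None
        if mode == "avg_only":
            out = self._mlp(avg)
        elif mode == "max_only":
            out = self._mlp(mx)
        elif self.config.channel_fusion == "sum_then_mlp":
            out = self._mlp(avg + mx)
        else:
            out = self._mlp(avg) + self._mlp(mx)
        return out.sigmoid() if apply_sigmoid else out

    def spatial_map(self, x: Tensor, apply_sigmoid: bool) -> Tensor:
        """Spatial attention logits/map of shape (N, 1, H, W)."""
        mode = self.config.pooling_mode
        avg = x.mean(axis=1, keepdims=True) if mode != "max_only" else None
        mx = x.max(axis=1, keepdims=True) if mode != "avg_only" else None
        if mode == "avg_only":
            desc = avg
        elif mode == "max_only":
            desc = mx
        else:
            desc = avg + mx
        out = self.spatial_bn(self.spatial_conv(desc))
        return out.sigmoid() if apply_sigmoid else out


class PCAB(_AttentionBase):
    """Parallel channel-spatial attention: one sigmoid over the fused maps."""

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        mc = self.channel_map(x, apply_sigmoid=False).reshape(n, c, 1, 1)
        ms = self.spatial_map(x, apply_sigmoid=False)
        mcs = (mc + ms).sigmoid()
        return x + x * mcs


class SCAB(_AttentionBase):
    """Sequential attention: channel gating first, spatial gating on its output."""

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        mc = self.channel_map(x, apply_sigmoid=True).reshape(n, c, 1, 1)
        fc = x * mc
        ms = self.spatial_map(fc, apply_sigmoid=True)
        return x + fc * ms


def make_block(kind: str, channels: int, config: AttentionConfig | None = None) -> _AttentionBase:
    kind = kind.lower()
    if kind == "pcab":
        return PCAB(channels, config)
    if kind == "scab":
        return SCAB(channels, config)
    raise ValueError(f"unknown attention kind: {kind!r} (expected 'pcab' or 'scab')")


# ---------------------------------------------------------------------------
# Functional interface on single (C, H, W) arrays
# ---------------------------------------------------------------------------

def pool_channel_descriptors(values, mode: str = "avg_plus_max"):
    """Per-channel GAP/GMP descriptors.

    Returns ``(avg, max)`` vectors of length C; in ``avg_only`` /
    ``max_only`` mode the unused descriptor is returned as None.
    """
    if mode not in POOLING_MODES:
        raise ValueError(f"pooling mode must be one of {POOLING_MODES}")
    values = _check_feature_map(values)
    avg = values.mean(axis=(1, 2)) if mode != "max_only" else None
    mx = values.max(axis=(1, 2)) if mode != "avg_only" else None
    return avg, mx


def pool_spatial_descriptors(values, mode: str = "avg_plus_max"):
    """Cross-channel GAP/GMP descriptors as ``(avg, max)`` H x W maps."""
    if mode not in POOLING_MODES:
        raise ValueError(f"pooling mode must be one of {POOLING_MODES}")
    values = _check_feature_map(values)
    avg = values.mean(axis=0) if mode != "max_only" else None
    mx = values.max(axis=0) if mode != "avg_only" else None
    return avg, mx


def shared_mlp(v, block: _AttentionBase) -> np.ndarray:
    """Apply the block's shared bottleneck MLP to a length-C vector."""
    v = np.asarray(v, dtype=np.float64)
    if v.shape != (block.channels,):
        raise ValueError(f"expected a length-{block.channels} vector, got {v.shape}")
    with no_grad():
        out = block._mlp(Tensor(v.reshape(1, -1)))
    return out.data.reshape(-1)


def channel_branch(values, block: _AttentionBase, apply_sigmoid: bool) -> np.ndarray:
    """Channel attention map M_C of one feature map (length C)."""
    values = _check_feature_map(values)
    with no_grad():
        out = block.channel_map(Tensor(values[None]), apply_sigmoid)
    return out.data.reshape(-1)


def spatial_branch(values, block: _AttentionBase, apply_sigmoid: bool) -> np.ndarray:
    """Spatial attention map M_S of one feature map (H x W); uses the block's
    running batch-norm statistics (inference behaviour)."""
    values = _check_feature_map(values)
    was_training = block.training
    block.eval()
    try:
        with no_grad():
            out = block.spatial_map(Tensor(values[None]), apply_sigmoid)
    finally:
        block.train(was_training)
    return out.data[0, 0]


def _single_forward(values, block) -> np.ndarray:
    values = _check_feature_map(values)
    was_training = block.training
    block.eval()
    try:
        with no_grad():
            out = block(Tensor(values[None]))
    finally:
        block.train(was_training)
    return out.data[0]


def pcab_forward(values, block: PCAB) -> np.ndarray:
    """Run one (C, H, W) feature map through a PCAB block (inference mode)."""
    if not isinstance(block, PCAB):
        raise TypeError("pcab_forward requires a PCAB block")
    return _single_forward(values, block)


def scab_forward(values, block: SCAB) -> np.ndarray:
    """Run one (C, H, W) feature map through a SCAB block (inference mode)."""
    if not isinstance(block, SCAB):
        raise TypeError("scab_forward requires a SCAB block")
    return _single_forward(values, block)
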