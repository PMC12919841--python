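"""CNN backbones and attention-block insertion.

Three families are provided:

* ``resnet18`` — the standard 18-layer residual network (7x7 stem, four
  stages of two Basic Blocks at widths 64/128/256/512, global average pool,
  linear head).  Attention blocks are inserted at the output of each Basic
  Block's second convolution (after its batch norm, before the shortcut
  addition) — one site per Basic Block, eight in total.

* ``mobilenetv4`` — the Conv-Small variant of MobileNetV4 (stem 32, two
  fused-conv stages, Universal Inverted Bottleneck stages at widths 96 and
  128, a 1x1 conv to 960, and a post-pool 1280-wide hidden head).  This
  variant's arithmetic gives 2.50 M trainable parameters with a 3-class head.
  Attention sites are the stem output plus every UIB block output.

* ``mini`` — a three-stage desk-scale CNN (8/16/32 channels) used by the
  synthetic-data experiments, with attention sites after the two deeper
  stages.

The input contract for resnet18/mobilenetv4 is a 3x224x224 image batch; the
mini backbone accepts any spatial size divisible by 8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from ._tensor import Tensor
from .attention import AttentionConfig, make_block

__all__ = [
    "BackboneSpec", "InsertionPlan", "build_backbone", "make_insertion_plan",
    "apply_plan", "build_model", "model_manifest",
    "ResNet18", "MobileNetV4ConvSmall", "MiniConvNet",
]

FAMILIES = ("resnet18", "mobilenetv4", "mini")


@dataclass(frozen=True)
class BackboneSpec:
    """What to build: family, variant, head width."""

    family: str = "resnet18"
    variant: str = ""          # mobilenetv4 defaults to "conv-small"
    num_classes: int = 2
    pretrained: bool = False

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown backbone family {self.family!r}; choose from {FAMILIES}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.family == "mobilenetv4" and self.variant not in ("", "conv-small"):
            raise ValueError(f"unsupported mobilenetv4 variant {self.variant!r}; "
                             "only 'conv-small' is implemented")


@dataclass
class InsertionPlan:
    """Ordered attention sites (module paths) with their channel widths."""

    attention_kind: str = "none"
    sites: list = field(default_factory=list)       # module path strings
    channels: list = field(default_factory=list)    # per-site C
    config: AttentionConfig = field(default_factory=AttentionConfig)

    def __post_init__(self):
        if self.attention_kind not in ("none", "pcab", "scab"):
            raise ValueError("attention_kind must be 'none', 'pcab' or 'scab'")
        if len(self.sites) != len(self.channels):
            raise ValueError("sites and channels must align")


class ConvBnAct(nn.Module):
    def __init__(self, cin, cout, k, stride=1, act=True):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, stride=stride, padding=(k - 1) // 2, bias=False)
        self.bn = nn.BatchNorm2d(cout)
        self.act = nn.ReLU() if act else nn.Identity()
        self.attn = nn.Identity()
        self.out_channels = cout

    def forward(self, x):
        return self.attn(self.act(self.bn(self.conv(x))))


class BasicBlock(nn.Module):
    """ResNet Basic Block; ``attn`` sits after conv2+bn2, before the shortcut add."""

    def __init__(self, cin, cout, stride=1):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(cout)
        self.relu = nn.ReLU()
        self.conv2 = nn.Conv2d(cout, cout, 3, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(cout)
        self.attn = nn.Identity()
        if stride != 1 or cin != cout:
            self.downsample = nn.Sequential(
                nn.Conv2d(cin, cout, 1, stride=stride, bias=False),
                nn.BatchNorm2d(cout))
        else:
            self.downsample = nn.Identity()
        self.out_channels = cout

    def forward(self, x):
        out = self.bn2(self.conv2(self.relu(self.bn1(self.conv1(x)))))
        out = self.attn(out)
        return (out + self.downsample(x)).relu()


class ResNet18(nn.Module):
    def __init__(self, num_classes: int):
        super().__init__()
        self.conv1 = nn.Conv2d(3, 64, 7, stride=2, padding=3, bias=False)
        self.bn1 = nn.BatchNorm2d(64)
        self.relu = nn.ReLU()
        self.maxpool = nn.MaxPool2d(3, stride=2, padding=1)
        self.layer1 = nn.Sequential(BasicBlock(64, 64), BasicBlock(64, 64))
        self.layer2 = nn.Sequential(BasicBlock(64, 128, 2), BasicBlock(128, 128))
        self.layer3 = nn.Sequential(BasicBlock(128, 256, 2), BasicBlock(256, 256))
        self.layer4 = nn.Sequential(BasicBlock(256, 512, 2), BasicBlock(512, 512))
        self.avgpool = nn.GlobalAvgPool2d()
        self.fc = nn.Linear(512, num_classes)
        self.num_classes = num_classes
        self.last_conv_layer = "layer4.1"   # default Grad-CAM target

    def attention_sites(self):
        sites = []
        for li, layer in enumerate((self.layer1, self.layer2, self.layer3, self.layer4), 1):
            for bi, block in enumerate(layer):
                sites.append((f"layer{li}.{bi}", block.out_channels))
        return sites

    def forward(self, x):
        x = self.maxpool(self.relu(self.bn1(self.conv1(x))))
        x = self.layer4(self.layer3(self.layer2(self.layer1(x))))
        return self.fc(self.avgpool(x))


class UIB(nn.Module):
    """Universal Inverted Bottleneck: optional leading depthwise conv,
    1x1 expansion, optional middle depthwise conv (carrying the stride),
    1x1 projection; residual skip when shapes allow.  ``attn`` is applied
    to the block output (after the skip)."""

    def __init__(self, cin, cout, start_k=0, mid_k=3, stride=1, expand=4):
        super().__init__()
        mid = cin * expand
        if start_k:
            self.dw_start = nn.Sequential(
                nn.Conv2d(cin, cin, start_k, padding=(start_k - 1) // 2,
                          groups=cin, bias=False),
                nn.BatchNorm2d(cin))
        else:
            self.dw_start = nn.Identity()
        self.pw_exp = nn.Sequential(nn.Conv2d(cin, mid, 1, bias=False),
                                    nn.BatchNorm2d(mid), nn.ReLU())
        if mid_k:
            self.dw_mid = nn.Sequential(
                nn.Conv2d(mid, mid, mid_k, stride=stride, padding=(mid_k - 1) // 2,
                          groups=mid, bias=False),
                nn.BatchNorm2d(mid), nn.ReLU())
        else:
            if stride != 1:
                raise ValueError("UIB stride > 1 requires a middle depthwise conv")
            self.dw_mid = nn.Identity()
        self.pw_proj = nn.Sequential(nn.Conv2d(mid, cout, 1, bias=False),
                                     nn.BatchNorm2d(cout))
        self.use_skip = (stride == 1 and cin == cout)
        self.attn = nn.Identity()
        self.out_channels = cout

    def forward(self, x):
        out = self.pw_proj(self.dw_mid(self.pw_exp(self.dw_start(x))))
        if self.use_skip:
            out = out + x
        return self.attn(out)


# (cin, cout, start_k, mid_k, stride, expand) for the Conv-Small UIB stages
_MNV4_SMALL_UIB = [
    (64, 96, 5, 5, 2, 3),
    (96, 96, 0, 3, 1, 2),
    (96, 96, 0, 3, 1, 2),
    (96, 96, 0, 3, 1, 2),
    (96, 96, 0, 3, 1, 2),
    (96, 96, 3, 0, 1, 4),
    (96, 128, 3, 3, 2, 6),
    (128, 128, 5, 5, 1, 4),
    (128, 128, 0, 5, 1, 4),
    (128, 128, 0, 5, 1, 3),
    (128, 128, 0, 3, 1, 4),
    (128, 128, 0, 3, 1, 4),
]


class MobileNetV4ConvSmall(nn.Module):
    def __init__(self, num_classes: int):
        super().__init__()
        self.stem = ConvBnAct(3, 32, 3, stride=2)
        self.stage0 = nn.Sequential(ConvBnAct(32, 32, 3, stride=2),
                                    ConvBnAct(32, 32, 1))
        self.stage1 = nn.Sequential(ConvBnAct(32, 96, 3, stride=2),
                                    ConvBnAct(96, 64, 1))
        self.blocks = nn.Sequential(*[UIB(*cfg) for cfg in _MNV4_SMALL_UIB])
        self.final_conv = ConvBnAct(128, 960, 1)
        self.avgpool = nn.GlobalAvgPool2d()
        # 1x1 conv applied after pooling == a dense layer on the pooled vector
        self.conv_head = nn.Linear(960, 1280)
        self.head_act = nn.ReLU()
        self.classifier = nn.Linear(1280, num_classes)
        self.num_classes = num_classes
        self.last_conv_layer = "final_conv"

    def attention_sites(self):
        sites = [("stem", self.stem.out_channels)]
        for bi, block in enumerate(self.blocks):
            sites.append((f"blocks.{bi}", block.out_channels))
        return sites

    def forward(self, x):
        x = self.stage1(self.stage0(self.stem(x)))
        x = self.final_conv(self.blocks(x))
        x = self.head_act(self.conv_head(self.avgpool(x)))
        return self.classifier(x)


class MiniConvNet(nn.Module):
    """Three-stage CNN for desk-scale synthetic experiments."""

    def __init__(self, num_classes: int, widths=(8, 16, 32)):
        super().__init__()
        w0, w1, w2 = widths
        self.stem = ConvBnAct(3, w0, 3)
        self.pool0 = nn.MaxPool2d(2)
        self.block1 = ConvBnAct(w0, w1, 3)
        self.pool1 = nn.MaxPool2d(2)
        self.block2 = ConvBnAct(w1, w2, 3)
        self.pool2 = nn.MaxPool2d(2)
        self.avgpool = nn.GlobalAvgPool2d()
        self.fc = nn.Linear(w2, num_classes)
        self.num_classes = num_classes
        self.last_conv_layer = "block2"

    def attention_sites(self):
        return [("block1", self.block1.out_channels),
                ("block2", self.block2.out_channels)]

    def forward(self, x):
        x = self.pool0(self.stem(x))
        x = self.pool1(self.block1(x))
        x = self.pool2(self.block2(x))
        return self.fc(self.avgpool(x))


def build_backbone(spec: BackboneSpec, seed: int | None = None):
    """Build the bare (attention-free) architecture for a spec."""
    if spec.pretrained:
        raise ValueError("pretrained weights are not distributed with this package; "
                         "load a checkpoint with model.load(path) instead")
    if seed is not None:
        nn.manual_seed(seed)
    if spec.family == "resnet18":
        return ResNet18(spec.num_classes)
    if spec.family == "mobilenetv4":
        return MobileNetV4ConvSmall(spec.num_classes)
    return MiniConvNet(spec.num_classes)


def make_insertion_plan(model, attention_kind: str,
                        config: AttentionConfig | None = None) -> InsertionPlan:
    """Enumerate the model's attention sites for the requested block kind.

    ``attention_kind='none'`` yields a valid empty plan.
    """
    config = config or AttentionConfig()
    if attention_kind == "none":
        return InsertionPlan("none", [], [], config)
    sites = model.attention_sites()
    return InsertionPlan(attention_kind,
                         [name for name, _ in sites],
                         [c for _, c in sites],
                         config)


def apply_plan(model, plan: InsertionPlan, seed: int | None = None):
    """Instantiate and attach one attention block per plan site, in place."""
    if seed is not None:
        nn.manual_seed(seed)
    for name, channels in zip(plan.sites, plan.channels):
        block = model.get_module(name)
        if getattr(block, "out_channels", None) != channels:
            raise ValueError(f"site {name}: expected {channels} channels, "
                             f"model has {getattr(block, 'out_channels', None)}")
        block.attn = make_block(plan.attention_kind, channels, plan.config)
    return model


def build_model(spec: BackboneSpec, attention_kind: str = "none",
                config: AttentionConfig | None = None, seed: int | None = None):
    """Build a backbone and insert attention blocks in one call."""
    model = build_backbone(spec, seed=seed)
    plan = make_insertion_plan(model, attention_kind, config)
    apply_plan(model, plan)
    return model, plan


def model_manifest(spec: BackboneSpec, plan: InsertionPlan) -> dict:
    """JSON-serializable description of a built model."""
    return {
        "family": spec.family,
        "variant": spec.variant or ("conv-small" if spec.family == "mobilenetv4" else ""),
        "num_classes": spec.num_classes,
        "attention_kind": plan.attention_kind,
        "sites": [{"name": n, "channels": int(c)}
                  for n, c in zip(plan.sites, plan.channels)],
        "attention_config": {
            "reduction_ratio": plan.config.reduction_ratio,
            "kernel_size": plan.config.kernel_size,
            "dilation": plan.config.effective_dilation,
            "pooling_mode": plan.config.pooling_mode,
            "conv_mode": plan.config.conv_mode,
            "channel_fusion": plan.config.channel_fusion,
        },
    }
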