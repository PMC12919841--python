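# cogattn

Channel–spatial **cognitive attention blocks** for CNN-based white-blood-cell
(WBC) image classification, with everything needed to study them at desk
scale: backbones to host the blocks, analytic complexity accounting,
stratified data splitting, a training/evaluation protocol, Grad-CAM
explainability, and a synthetic stained-smear image generator so the whole
pipeline runs offline with no dataset download.

## The scientific problem

Classifying leukemic blasts versus healthy white blood cells in stained
microscopy images is a fine-grained recognition task: the discriminative
evidence (cell size, nucleus-to-cytoplasm ratio, nuclear boundary
irregularity, chromatin texture) is concentrated in a small region of the
image. Plain CNNs spread their capacity uniformly; *attention blocks* let the
network reweight feature maps along the channel axis ("what") and the spatial
axes ("where") so that cell-relevant features dominate.

This package implements two such blocks and the protocol to compare them.

## The model

For a feature map `F ∈ R^{C×H×W}`:

**Channel branch** — global average and max pooling over spatial positions
give two length-`C` descriptors, passed through a shared bottleneck MLP with
reduction ratio `R` (hidden width `max(1, C/R)`, default `R = 16`):

    M_C(F) = MLP(GAP(F)) + MLP(GMP(F))          (length C)

**Spatial branch** — average and max pooling across channels give two `H×W`
maps, fused by elementwise sum and passed through a dilated convolution
(kernel `k = 7`, dilation `d = 2`, same padding) and batch normalization:

    M_S(F) = BN(DC(GAP(F) + GMP(F)))            (H×W)

**PCAB** (parallel): one sigmoid over the broadcast sum of the two branches,

    M_CS = σ(M_C + M_S),    PCAB(F) = F + F ⊙ M_CS

**SCAB** (sequential): channel gating first, spatial gating computed from the
channel-refined features,

    F_C = F ⊙ σ(M_C(F)),    SCAB(F) = F + F_C ⊙ σ(M_S(F_C))

Every gate lies in (0, 1), so both blocks are residual with elementwise gain
bounded by 2 and preserve the feature-map shape exactly. The ablation axes
are exposed as configuration: pooling mode (`avg_only` / `max_only` /
`avg_plus_max`), convolution mode (`standard` / `dilated`), and channel
fusion order (`mlp_then_sum` / `sum_then_mlp`).

Blocks are inserted into three hosts: **ResNet18** (after conv2+bn2 of each
basic block, before the shortcut add — 8 sites), **MobileNetV4-Conv-Small**
(stem and the 12 universal-inverted-bottleneck outputs), and a small
**MiniConvNet** for fast 64×64 experiments.

All tensor computation runs on a self-contained numpy reverse-mode
autodifferentiation engine (`cogattn._tensor` / `cogattn.nn`) — the package
has no deep-learning framework dependency.

## Worked example

```python
>>> from cogattn import BackboneSpec, build_backbone, count_parameters
>>> count_parameters(build_backbone(BackboneSpec("resnet18", num_classes=3)))
11178051
>>> count_parameters(build_backbone(BackboneSpec("mobilenetv4", num_classes=3)))
2495587

>>> from cogattn import ConfusionMatrix, binary_metrics
>>> r = binary_metrics(ConfusionMatrix([[48, 1], [2, 49]]), positive=0).rounded()
>>> (r.accuracy, r.precision, r.sensitivity, r.specificity, r.f1)
(97.0, 96.0, 97.96, 96.08, 96.97)

>>> import numpy as np
>>> from cogattn import AttentionConfig, make_block, scab_forward
>>> block = make_block("scab", channels=8, config=AttentionConfig(reduction_ratio=2))
>>> out = scab_forward(np.random.default_rng(0).normal(size=(8, 14, 14)), block)
>>> out.shape
(8, 14, 14)
```

End-to-end from the command line:

```bash
cogattn generate --preset benchmark --per-class 50 --seed 0 --out data/
cogattn train --data data/ --backbone mini --attention scab \
    --epochs 10 --image-size 64 --out runs/scab
cogattn explain --checkpoint runs/scab/checkpoint.npz --backbone mini \
    --attention scab --per-class 4 --index 0 --out runs/scab/explain
cogattn inspect --backbone resnet18 --attention scab --json
```

`cogattn train` writes `metrics.json`, per-epoch `curves.csv`, the exact
`splits.csv`, a `manifest.json` describing the architecture, and a
`checkpoint.npz`.

## Repository layout

| Path | Contents |
| --- | --- |
| `src/cogattn/_tensor.py`, `nn.py` | numpy autodiff engine and layer library |
| `src/cogattn/attention.py` | PCAB / SCAB and the functional oracle surface |
| `src/cogattn/backbones.py` | ResNet18, MobileNetV4-Conv-Small, MiniConvNet, insertion plans |
| `src/cogattn/complexity.py` | parameter / FLOPs / MACs / size accounting |
| `src/cogattn/metrics.py`, `splits.py` | confusion-matrix metrics, stratified splits |
| `src/cogattn/synthetic.py` | stained-smear image generator and augmentation |
| `src/cogattn/training.py` | SGD training protocol and experiment runner |
| `src/cogattn/explain.py` | Grad-CAM and feature-map extraction |
| `docs/methods.md` | modeling assumptions and numerical choices |

See `docs/methods.md` for the modeling assumptions, parameter defaults, and
limitations.
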