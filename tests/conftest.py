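import numpy as np
import pytest

from cogattn import nn
from cogattn._tensor import Tensor
from cogattn.attention import AttentionConfig, PCAB, SCAB


def numeric_grad(f, x, eps=1e-5):
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gflat = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f(x)
        flat[i] = orig - eps
        fm = f(x)
        flat[i] = orig
        gflat[i] = (fp - fm) / (2 * eps)
    return g


def check_grad(op, x0, tol=1e-6, eps=1e-5):
    """Compare analytic input gradient of sum(op(x)) with finite differences.

    ``op`` maps a Tensor to a Tensor; ``x0`` is a float64 array.
    """
    x0 = np.asarray(x0, dtype=np.float64)
    t = Tensor(x0.copy(), requires_grad=True)
    out = op(t)
    out.sum().backward()
    analytic = t.grad.copy()

    def scalar(arr):
        return float(op(Tensor(arr.copy())).data.sum())

    numeric = numeric_grad(scalar, x0.copy(), eps=eps)
    denom = max(np.abs(analytic).max(), np.abs(numeric).max(), 1e-8)
    rel = np.abs(analytic - numeric).max() / denom
    return rel, analytic, numeric


def identity_mlp_block(kind="pcab", channels=2, config=None):
    """A block whose shared MLP is the identity and whose spatial pathway is
    zero, so channel logits equal the pooled descriptors exactly."""
    cls = {"pcab": PCAB, "scab": SCAB}[kind]
    config = config or AttentionConfig(reduction_ratio=1)
    block = cls(channels, config)
    eye = np.eye(channels, dtype=np.float32)
    block.fc1.weight.data = eye.copy()
    block.fc1.bias.data = np.zeros(channels, dtype=np.float32)
    block.fc2.weight.data = eye.copy()
    block.fc2.bias.data = np.zeros(channels, dtype=np.float32)
    block.spatial_conv.weight.data = np.zeros_like(block.spatial_conv.weight.data)
    if block.spatial_conv.bias is not None:
        block.spatial_conv.bias.data = np.zeros(1, dtype=np.float32)
    block.spatial_bn.weight.data = np.zeros(1, dtype=np.float32)
    block.spatial_bn.bias.data = np.zeros(1, dtype=np.float32)
    block.eval()
    return block


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small 2-class synthetic dataset shared across training tests."""
    from cogattn.synthetic import default_benchmark_spec, generate_dataset

    return generate_dataset(default_benchmark_spec(seed=7, per_class=(20, 20)))
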