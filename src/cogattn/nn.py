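"""Neural-network layer library on top of the autodiff engine.

Layers follow the NCHW convention and the familiar module idiom: parameters
and submodules registered by attribute assignment, ``train()``/``eval()``
modes, ``state_dict`` round-trips to plain numpy arrays.  Initialization is
Kaiming fan-in for weights and zeros for biases, drawn from a module-level
generator seeded with :func:`manual_seed` so that model construction is
reproducible bit for bit.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, batch_norm2d, conv2d, maxpool2d

__all__ = [
    "manual_seed", "Parameter", "Module", "Sequential", "Identity",
    "Conv2d", "Linear", "BatchNorm2d", "ReLU", "Sigmoid", "MaxPool2d",
    "GlobalAvgPool2d", "Flatten", "SGD", "profile_scope",
]

_INIT_RNG = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Seed the generator used for all parameter initialization."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


def _kaiming(shape, fan_in, rng=None) -> np.ndarray:
    rng = rng or _INIT_RNG
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


# record list appended to while profiling; see cogattn.complexity
_PROFILE: list | None = None


class profile_scope:
    """Collects (module, input shapes, output shape) for every leaf layer."""

    def __enter__(self):
        global _PROFILE
        _PROFILE = []
        return self

    def __exit__(self, *exc):
        global _PROFILE
        self.records = _PROFILE
        _PROFILE = None
        return False


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name, value):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal --------------------------------------------------------
    def children(self):
        return list(self._modules.values())

    def named_modules(self, prefix=""):
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix=""):
        for name, p in self._params.items():
            yield (f"{prefix}.{name}" if prefix else name), p
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_parameters(sub)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def get_module(self, path: str) -> "Module":
        mod = self
        for part in path.split("."):
            if part:
                mod = mod._modules[part]
        return mod

    # -- modes ------------------------------------------------------------
    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self.children():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- state ------------------------------------------------------------
    def state_dict(self, prefix="", out=None):
        out = {} if out is None else out
        for name, p in self._params.items():
            out[f"{prefix}{name}"] = p.data.copy()
        for name, b in self._buffers.items():
            out[f"{prefix}{name}"] = np.asarray(b).copy()
        for name, mod in self._modules.items():
            mod.state_dict(prefix=f"{prefix}{name}.", out=out)
        return out

    def load_state_dict(self, state, prefix=""):
        for name, p in self._params.items():
            key = f"{prefix}{name}"
            if p.data.shape != state[key].shape:
                raise ValueError(f"shape mismatch for {key}")
            p.data = state[key].astype(p.data.dtype).copy()
        for name in list(self._buffers):
            self._set_buffer(name, state[f"{prefix}{name}"].copy())
        for name, mod in self._modules.items():
            mod.load_state_dict(state, prefix=f"{prefix}{name}.")

    def save(self, path):
        np.savez(path, **self.state_dict())

    def load(self, path):
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})

    # -- execution --------------------------------------------------------
    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        out = self.forward(*args, **kwargs)
        if _PROFILE is not None and not self._modules:
            shapes = tuple(a.shape for a in args if isinstance(a, Tensor))
            _PROFILE.append((self, shapes, out.shape if isinstance(out, Tensor) else None))
        return out


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)

    def forward(self, x):
        for m in self._modules.values():
            x = m(x)
        return x

    def __iter__(self):
        return iter(self._modules.values())

    def __getitem__(self, i):
        return list(self._modules.values())[i]


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, dilation=1, groups=1, bias=True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        ks = kernel_size if isinstance(kernel_size, tuple) else (kernel_size, kernel_size)
        self.kernel_size = ks
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        self.groups = groups
        fan_in = (in_channels // groups) * ks[0] * ks[1]
        self.weight = Parameter(_kaiming((out_channels, in_channels // groups, *ks), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation, groups=self.groups)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_kaiming((out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        out = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel.

    Training mode normalizes with batch statistics and updates exponential
    running estimates (unbiased variance, momentum 0.1); eval mode uses the
    running estimates as constants.
    """

    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def forward(self, x):
        return batch_norm2d(x, self.weight, self.bias,
                            self.running_mean, self.running_var,
                            self.training, self.momentum, self.eps)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class MaxPool2d(Module):
    def __init__(self, kernel_size, stride=None, padding=0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return maxpool2d(x, self.kernel_size, self.stride, self.padding)


class GlobalAvgPool2d(Module):
    """Adaptive average pooling to 1x1, returned as (N, C)."""

    def forward(self, x):
        return x.mean(axis=(2, 3))


class Flatten(Module):
    def forward(self, x):
        return x.reshape(x.shape[0], -1)


class SGD:
    """Stochastic gradient descent with classical momentum and L2 weight decay."""

    def __init__(self, params, lr, momentum=0.0, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._buf = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, buf in zip(self.params, self._buf):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            buf *= self.momentum
            buf += g
            p.data = p.data - self.lr * buf
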