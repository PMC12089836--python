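"""Layer abstractions over the autodiff core: Module, Conv2d, Linear, norms."""

from __future__ import annotations

import math

import numpy as np

from . import tensor as T
from .conv import conv2d, linear, maxpool2d
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Container with parameter registration, train/eval state and hooks."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)
        object.__setattr__(self, "_fwd_hooks", [])

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def __call__(self, *args, **kwargs):
        out = self.forward(*args, **kwargs)
        for hook in self._fwd_hooks:
            hook(self, args, out)
        return out

    def register_forward_hook(self, fn):
        self._fwd_hooks.append(fn)
        return fn

    def clear_forward_hooks(self):
        self._fwd_hooks.clear()

    # -- traversal ----------------------------------------------------------
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

    def num_parameters(self):
        return sum(p.numel() for p in self.parameters())

    def train(self, mode=True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- state --------------------------------------------------------------
    def state_dict(self):
        state = {k: p.data for k, p in self.named_parameters()}
        for name, m in self.named_modules():
            if isinstance(m, BatchNorm2d):
                state[f"{name}.running_mean" if name else "running_mean"] = m.running_mean
                state[f"{name}.running_var" if name else "running_var"] = m.running_var
        return state

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        for k, v in state.items():
            if k in params:
                if params[k].data.shape != v.shape:
                    raise ValueError(f"shape mismatch for {k}: {params[k].data.shape} vs {v.shape}")
                params[k].data = np.asarray(v, dtype=np.float32)
        for name, m in self.named_modules():
            if isinstance(m, BatchNorm2d):
                rm = f"{name}.running_mean" if name else "running_mean"
                rv = f"{name}.running_var" if name else "running_var"
                if rm in state:
                    m.running_mean = np.asarray(state[rm], dtype=np.float32)
                if rv in state:
                    m.running_var = np.asarray(state[rv], dtype=np.float32)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            setattr(self, str(i), m)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.mods)

    def __len__(self):
        return len(self.mods)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(self.mods):
            setattr(self, str(i), m)

    def append(self, m):
        setattr(self, str(len(self.mods)), m)
        self.mods.append(m)

    def __iter__(self):
        return iter(self.mods)

    def __getitem__(self, i):
        return self.mods[i]

    def __len__(self):
        return len(self.mods)


def _kaiming(fan_in, shape, rng, gain=math.sqrt(2.0)):
    std = gain / math.sqrt(fan_in)
    return rng.normal(0.0, std, size=shape)


_INIT_RNG = [np.random.default_rng(0)]


def seed_init(seed: int) -> None:
    """Seed the parameter-initialisation stream (all layers draw from it)."""
    _INIT_RNG[0] = np.random.default_rng(seed)


class Conv2d(Module):
    """Convolution; ``kernel`` may be an int or an (kh, kw) pair."""

    def __init__(self, cin, cout, kernel, stride=1, padding=None, dilation=1,
                 groups=1, bias=True):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        self.cin, self.cout, self.kernel = cin, cout, (kh, kw)
        self.stride, self.dilation, self.groups = stride, dilation, groups
        if padding is None:
            padding = (dilation * (kh - 1) // 2, dilation * (kw - 1) // 2)
        self.padding = padding
        rng = _INIT_RNG[0]
        fan_in = cin // groups * kh * kw
        self.weight = Parameter(_kaiming(fan_in, (cout, cin // groups, kh, kw), rng))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding,
                      self.dilation, self.groups)


class Linear(Module):
    def __init__(self, cin, cout, bias=True):
        super().__init__()
        self.cin, self.cout = cin, cout
        rng = _INIT_RNG[0]
        bound = 1.0 / math.sqrt(cin)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(cout, cin)))
        self.bias = Parameter(rng.uniform(-bound, bound, size=cout)) if bias else None

    def forward(self, x):
        return linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x):
        w = self.weight.reshape(1, self.c, 1, 1)
        b = self.bias.reshape(1, self.c, 1, 1)
        if x.is_meta:
            return x * 1.0
        if self.training:
            m = x.mean(axis=(0, 2, 3), keepdims=True)
            centred = x - m
            v = (centred * centred).mean(axis=(0, 2, 3), keepdims=True)
            n = x.shape[0] * x.shape[2] * x.shape[3]
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * m.data.reshape(-1))
            unbiased = v.data.reshape(-1) * n / max(n - 1, 1)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased)
            xhat = centred * ((v + self.eps) ** -0.5)
        else:
            m = Tensor(self.running_mean.reshape(1, self.c, 1, 1))
            v = Tensor(self.running_var.reshape(1, self.c, 1, 1))
            xhat = (x - m) * ((v + self.eps) ** -0.5)
        return xhat * w + b


class LayerNorm(Module):
    def __init__(self, c, eps=1e-5):
        super().__init__()
        self.c, self.eps = c, eps
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))

    def forward(self, x):
        if x.is_meta:
            return x * 1.0
        m = x.mean(axis=-1, keepdims=True)
        centred = x - m
        v = (centred * centred).mean(axis=-1, keepdims=True)
        return centred * ((v + self.eps) ** -0.5) * self.weight + self.bias


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class SiLU(Module):
    def forward(self, x):
        return T.silu(x)


class Identity(Module):
    def forward(self, x):
        return x


class MaxPool2d(Module):
    def __init__(self, kernel=3, stride=2, padding=1):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return maxpool2d(x, self.kernel, self.stride, self.padding)


class ConvBNAct(Module):
    """conv -> BN -> activation, the standard fused block."""

    def __init__(self, cin, cout, kernel=1, stride=1, padding=None, dilation=1,
                 groups=1, act="relu"):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, stride, padding, dilation, groups, bias=False)
        self.bn = BatchNorm2d(cout)
        self.act = {"relu": ReLU(), "silu": SiLU(), "none": Identity()}[act]

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class MLP(Module):
    """Stack of Linear + ReLU layers (no activation after the last)."""

    def __init__(self, cin, hidden, cout, depth):
        super().__init__()
        dims = [cin] + [hidden] * (depth - 1) + [cout]
        self.layers = ModuleList([Linear(a, b) for a, b in zip(dims[:-1], dims[1:])])

    def forward(self, x):
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = T.relu(x)
        return x
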