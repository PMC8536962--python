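"""Layer modules: thin parameter holders over the functional ops."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor

__all__ = [
    "Module",
    "Conv2d",
    "ConvTranspose2x2",
    "BatchNorm2d",
    "Dropout",
    "gaussian_init_sd",
    "init_conv_kernel",
]


def gaussian_init_sd(kh: int, kw: int, cin: int) -> float:
    """Target standard deviation sqrt(2/eta) of the He-style Gaussian
    initialiser, where eta = kh*kw*cin is the number of incoming nodes
    per neuron."""
    return float(np.sqrt(2.0 / (kh * kw * cin)))


def init_conv_kernel(rng: np.random.Generator, kh, kw, cin, cout) -> np.ndarray:
    """Draw a (kh, kw, cin, cout) kernel from N(0, 2/eta)."""
    return rng.normal(0.0, gaussian_init_sd(kh, kw, cin), size=(kh, kw, cin, cout)).astype(
        np.float32
    )


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    training: bool = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()
            elif isinstance(v, dict):
                for item in v.values():
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix=""):
        for name, v in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield path, v
            elif isinstance(v, Module):
                yield from v.named_parameters(path + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")
            elif isinstance(v, dict):
                for k, item in v.items():
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{k}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bn{i}.running_mean"] = m.running_mean.copy()
                state[f"__bn{i}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=np.float32).copy()
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[f"__bn{i}.running_mean"], dtype=np.float32).copy()
                m.running_var = np.asarray(state[f"__bn{i}.running_var"], dtype=np.float32).copy()


class Conv2d(Module):
    """Size-preserving convolution, odd square kernel, NHWC."""

    def __init__(self, cin, cout, k=3, rng=None):
        self.cin, self.cout, self.k = cin, cout, k
        if rng is None:
            w = np.zeros((k, k, cin, cout), dtype=np.float32)
        else:
            w = init_conv_kernel(rng, k, k, cin, cout)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def reinit(self, rng):
        self.w.data = init_conv_kernel(rng, self.k, self.k, self.cin, self.cout)
        self.b.data = np.zeros(self.cout, dtype=np.float32)

    def __call__(self, x):
        return T.conv2d(x, self.w, self.b)


class ConvTranspose2x2(Module):
    """Stride-2 kernel-2 transposed convolution (2x learned upsampling)."""

    def __init__(self, cin, cout, rng=None):
        self.cin, self.cout = cin, cout
        if rng is None:
            w = np.zeros((2, 2, cin, cout), dtype=np.float32)
        else:
            w = init_conv_kernel(rng, 2, 2, cin, cout)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def reinit(self, rng):
        self.w.data = init_conv_kernel(rng, 2, 2, self.cin, self.cout)
        self.b.data = np.zeros(self.cout, dtype=np.float32)

    def __call__(self, x):
        return T.conv_transpose_2x2(x, self.w, self.b)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def reinit(self, rng):
        c = self.gamma.data.shape[0]
        self.gamma.data = np.ones(c, dtype=np.float32)
        self.beta.data = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def __call__(self, x):
        if self.training:
            out, mu, var = T.batchnorm_train(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.astype(np.float32)
            self.running_var = m * self.running_var + (1 - m) * var.astype(np.float32)
            return out
        inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = T.Tensor(inv_std) * self.gamma
        shift = self.beta - self.gamma * T.Tensor(self.running_mean * inv_std)
        return x * scale + shift


class Dropout(Module):
    def __init__(self, p=0.5):
        self.p = p
        self.rng = np.random.default_rng(0)

    def reseed(self, seed):
        self.rng = np.random.default_rng(seed)

    def __call__(self, x):
        if not self.training or self.p <= 0:
            return T.as_tensor(x)
        return T.dropout(x, self.p, self.rng)
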