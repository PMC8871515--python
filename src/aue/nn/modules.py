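"""Layers built on the autograd tensor: convolutions, instance norm,
spectral normalization, and a ``Module`` container with a flat
name-addressed state dict for checkpointing."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, pad2d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Container tracking sub-modules and parameters by attribute name."""

    def __setattr__(self, name, value):
        if isinstance(value, (Parameter, Module)):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_children", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, child in self.__dict__.get("_children", {}).items():
            full = f"{prefix}{name}"
            if isinstance(child, Parameter):
                yield full, child
            else:
                yield from child.named_parameters(full + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers(link=True))
        for name, arr in state.items():
            if name in params:
                if params[name].data.shape != arr.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: "
                        f"{params[name].data.shape} vs {arr.shape}"
                    )
                params[name].data = np.asarray(arr, dtype=np.float32).copy()
            elif name in bufs:
                owner, attr = bufs[name]
                setattr(owner, attr, np.asarray(arr, dtype=np.float32).copy())
            else:
                raise KeyError(f"unexpected state entry {name}")

    def named_buffers(self, prefix: str = "", link: bool = False):
        """Non-trainable per-module state (e.g. the power-iteration vector)."""
        for attr in getattr(self, "_buffers", ()):  # declared by subclasses
            key = f"{prefix}{attr}"
            yield (key, (self, attr)) if link else (key, getattr(self, attr))
        for name, child in self.__dict__.get("_children", {}).items():
            if isinstance(child, Module):
                yield from child.named_buffers(f"{prefix}{name}.", link)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__setattr__("_children", {})
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """2-D convolution with optional symmetric padding.

    ``pad_mode`` is ``"zeros"`` or ``"reflect"``; weights are He-normal
    initialized from the supplied generator so construction is fully
    deterministic under a seed.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        padding: int = 0,
        pad_mode: str = "zeros",
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.padding = padding
        self.pad_mode = pad_mode

    def forward(self, x: Tensor) -> Tensor:
        x = pad2d(x, self.padding, self.pad_mode)
        return conv2d(x, self.weight, self.bias, self.stride)


class SpectralNormConv2d(Conv2d):
    """Conv2d whose kernel is divided by its largest singular value.

    sigma is estimated with one step of power iteration per forward pass
    on the (out_ch, in_ch*k*k) matricized kernel; the left/right vectors
    persist across calls, so sigma converges during training.  Gradients
    flow through W/sigma with sigma treated as u^T W v for fixed u, v —
    the standard formulation.
    """

    _buffers = ("_u",)

    def __init__(self, *args, n_power_iterations: int = 1, **kwargs):
        super().__init__(*args, **kwargs)
        o = self.weight.data.shape[0]
        self._u = np.random.default_rng(0).normal(size=o).astype(np.float32)
        self._u /= np.linalg.norm(self._u)
        self.n_power_iterations = n_power_iterations
        # warm start so sigma is a usable estimate from the first step;
        # the per-forward iteration keeps it tracking the weights
        for _ in range(20):
            self._power_iterate()

    def _power_iterate(self) -> tuple[np.ndarray, np.ndarray]:
        wm = self.weight.data.reshape(self.weight.data.shape[0], -1)
        u = self._u
        for _ in range(self.n_power_iterations):
            v = wm.T @ u
            v /= np.linalg.norm(v) + 1e-12
            u = wm @ v
            u /= np.linalg.norm(u) + 1e-12
        self._u = u
        return u, v

    def normalized_weight(self) -> Tensor:
        u, v = self._power_iterate()
        o = self.weight.data.shape[0]
        w_flat = self.weight.reshape(o, -1)
        sigma = Tensor(u[None, :]) @ w_flat @ Tensor(v[:, None])  # (1,1)
        return self.weight / sigma.reshape(1, 1, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        x = pad2d(x, self.padding, self.pad_mode)
        return conv2d(x, self.normalized_weight(), self.bias, self.stride)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over spatial positions.

    No learned affine: where modulation is needed it is supplied by the
    spatially-adaptive denormalization head instead.
    """

    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = ((x - mu) ** 2).mean(axis=(2, 3), keepdims=True)
        return (x - mu) / (var + self.eps).sqrt()


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Adam:
    """Adam with the bias-corrected update; state is checkpointable."""

    def __init__(self, params, lr: float, beta1: float = 0.5, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [a.copy() for a in self.m],
            "v": [a.copy() for a in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(a, dtype=np.float32).copy() for a in state["m"]]
        self.v = [np.asarray(a, dtype=np.float32).copy() for a in state["v"]]
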