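"""Minimal module/parameter system over the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

__all__ = ["Module", "Conv2d", "Adam"]


class Module:
    """Base class; parameters are discovered by attribute walk, so attribute
    assignment order fixes the (deterministic) parameter order."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                out.append((full, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(full + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys {sorted(missing)}")
        for k, v in own.items():
            v.data = np.asarray(state[k], dtype=np.float32).reshape(v.data.shape)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """2D convolution with He-normal init from a caller-supplied RNG."""

    def __init__(self, in_ch: int, out_ch: int, kernel, rng: np.random.Generator,
                 stride: int = 1, padding="same", bias: bool = True,
                 pad_mode: str = "zeros"):
        kh, kw = (kernel, kernel) if np.isscalar(kernel) else kernel
        if padding == "same":
            # asymmetric for even kernels so output length is preserved
            padding = ((((kh - 1) // 2), kh // 2), (((kw - 1) // 2), kw // 2))
        fan_in = in_ch * kh * kw
        self.weight = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                        (out_ch, in_ch, kh, kw)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True) if bias else None
        self.stride, self.padding, self.pad_mode = stride, padding, pad_mode

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, pad_mode=self.pad_mode)


class Adam:
    """Adam optimizer (float32 state)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
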