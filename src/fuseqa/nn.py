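"""Neural-network building blocks on the numpy autodiff core.

Convolutions use im2col/col2im; transposed convolutions are realised as the
adjoint of the corresponding convolution, so forward/backward share three
primitives.  All parameters are float32.  Weight initialisation follows the
common GAN recipe: N(0, 0.02) convolution weights, unit batch-norm gain.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from ._autograd import Tensor, is_grad_enabled

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "maxpool2x2",
    "upsample_nearest2x",
    "Adam",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters stay trainable even under no_grad


# --------------------------------------------------------------------------
# conv primitives
# --------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, s: int, p: int):
    """(B,C,H,W) -> (B, OH*OW, C*k*k) patch matrix."""
    B, C, H, W = x.shape
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    Hp, Wp = x.shape[2], x.shape[3]
    OH = (Hp - k) // s + 1
    OW = (Wp - k) // s + 1
    sB, sC, sH, sW = x.strides
    win = np.lib.stride_tricks.as_strided(
        x, (B, C, OH, OW, k, k), (sB, sC, sH * s, sW * s, sH, sW), writeable=False
    )
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(B, OH * OW, C * k * k)
    return cols, OH, OW


def _col2im(dcols: np.ndarray, x_shape, k: int, s: int, p: int, OH: int, OW: int):
    """Adjoint of _im2col: scatter-add patch gradients back to image layout."""
    B, C, H, W = x_shape
    dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float32)
    d6 = dcols.reshape(B, OH, OW, C, k, k).transpose(0, 3, 4, 5, 1, 2)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki : ki + s * OH : s, kj : kj + s * OW : s] += d6[:, :, ki, kj]
    if p:
        return dxp[:, :, p : p + H, p : p + W]
    return dxp


def _conv_fwd(x: np.ndarray, w: np.ndarray, s: int, p: int):
    """y = conv(x, w); w is (Cout, Cin, k, k). Returns (y, cols, OH, OW)."""
    Cout, Cin, k, _ = w.shape
    cols, OH, OW = _im2col(x, k, s, p)
    y = cols @ w.reshape(Cout, Cin * k * k).T  # (B, OH*OW, Cout)
    return y.transpose(0, 2, 1).reshape(x.shape[0], Cout, OH, OW), cols, OH, OW


def _conv_bwd_input(dy: np.ndarray, w: np.ndarray, x_shape, s: int, p: int):
    Cout, Cin, k, _ = w.shape
    B = dy.shape[0]
    OH, OW = dy.shape[2], dy.shape[3]
    dy_flat = dy.reshape(B, Cout, OH * OW).transpose(0, 2, 1)
    dcols = dy_flat @ w.reshape(Cout, Cin * k * k)
    return _col2im(dcols, x_shape, k, s, p, OH, OW)


def _conv_bwd_weight(dy: np.ndarray, cols: np.ndarray, w_shape):
    Cout, Cin, k, _ = w_shape
    B = dy.shape[0]
    dy_flat = dy.reshape(B, Cout, -1)  # (B, Cout, N)
    dw = np.einsum("bon,bnm->om", dy_flat, cols, optimize=True)
    return dw.reshape(w_shape)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int, padding: int) -> Tensor:
    y_data, cols, OH, OW = _conv_fwd(x.data, weight.data, stride, padding)
    if bias is not None:
        y_data = y_data + bias.data.reshape(1, -1, 1, 1)
    out = Tensor(y_data)
    parents = [p for p in (x, weight, bias) if p is not None]
    if is_grad_enabled() and any(p.requires_grad for p in parents):
        x_shape, w_shape = x.data.shape, weight.data.shape

        def backward(g):
            if x.requires_grad:
                x._accum(_conv_bwd_input(g, weight.data, x_shape, stride, padding))
            if weight.requires_grad:
                weight._accum(_conv_bwd_weight(g, cols, w_shape))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))

        out.requires_grad = True
        out._prev = tuple(parents)
        out._backward = backward
    return out


def conv_transpose2d(
    x: Tensor, weight: Tensor, bias: Tensor | None, stride: int, padding: int
) -> Tensor:
    """Transposed convolution; weight is (Cin, Cout, k, k).

    Output side is (H-1)*stride - 2*padding + k; the kernel/stride pairs used
    in this package (k=4,s=2,p=1 and k=3,s=1,p=1) give exact 2x and 1x sides.
    """
    Cin, Cout, k, _ = weight.shape
    B, _, H, W = x.data.shape
    Ho = (H - 1) * stride - 2 * padding + k
    Wo = (W - 1) * stride - 2 * padding + k
    out_shape = (B, Cout, Ho, Wo)
    # forward = adjoint of conv(out -> in) with weight seen as (Cin, Cout, k, k)
    y_data = _conv_bwd_input(x.data, weight.data, out_shape, stride, padding)
    if bias is not None:
        y_data = y_data + bias.data.reshape(1, -1, 1, 1)
    out = Tensor(y_data)
    parents = [p for p in (x, weight, bias) if p is not None]
    if is_grad_enabled() and any(p.requires_grad for p in parents):

        def backward(g):
            cols_g = None
            if x.requires_grad:
                gx, cols_g, _, _ = _conv_fwd(g, weight.data, stride, padding)
                x._accum(gx)
            if weight.requires_grad:
                if cols_g is None:
                    cols_g, _, _ = _im2col(g, k, stride, padding)
                weight._accum(_conv_bwd_weight(x.data, cols_g, weight.data.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))

        out.requires_grad = True
        out._prev = tuple(parents)
        out._backward = backward
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2x2 requires even sides, got {H}x{W}")
    xr = (
        x.data.reshape(B, C, H // 2, 2, W // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(B, C, H // 2, W // 2, 4)
    )
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data)
    if is_grad_enabled() and x.requires_grad:

        def backward(g):
            d4 = np.zeros((B, C, H // 2, W // 2, 4), dtype=np.float32)
            np.put_along_axis(d4, idx[..., None], g[..., None], axis=-1)
            dx = (
                d4.reshape(B, C, H // 2, W // 2, 2, 2)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(B, C, H, W)
            )
            x._accum(dx)

        out.requires_grad = True
        out._prev = (x,)
        out._backward = backward
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    B, C, H, W = x.data.shape
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = Tensor(out_data)
    if is_grad_enabled() and x.requires_grad:

        def backward(g):
            dx = g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5))
            x._accum(dx)

        out.requires_grad = True
        out._prev = (x,)
        out._backward = backward
    return out


# --------------------------------------------------------------------------
# modules
# --------------------------------------------------------------------------

class Module:
    def __init__(self):
        self.training = True
        self._buffers: dict[str, np.ndarray] = {}

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=np.float32)
        object.__setattr__(self, name, self._buffers[name])

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=np.float32)
        object.__setattr__(self, name, self._buffers[name])

    def children(self) -> Iterator["Module"]:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for c in self.children():
            c.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, v in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{full}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield f"{prefix}{name}", self._buffers[name]
        for cname, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v.named_buffers(f"{prefix}{cname}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffer_owners = self._buffer_owners()
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for parameter {name!r}")
                params[name].data = np.asarray(value, dtype=np.float32).copy()
            elif name in buffer_owners:
                owner, local = buffer_owners[name]
                owner._set_buffer(local, value)
            else:
                raise KeyError(f"unknown state entry {name!r}")

    def _buffer_owners(self, prefix: str = "") -> dict[str, tuple["Module", str]]:
        owners = {f"{prefix}{n}": (self, n) for n in self._buffers}
        for cname, v in self.__dict__.items():
            if isinstance(v, Module):
                owners.update(v._buffer_owners(f"{prefix}{cname}."))
        return owners

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        for i, m in enumerate(modules):
            setattr(self, str(i), m)
        self._n = len(tuple(modules))

    def __iter__(self):
        return (getattr(self, str(i)) for i in range(self._n))

    def __len__(self):
        return self._n

    def __getitem__(self, i):
        return getattr(self, str(i))


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, padding=0, bias=True, *, rng, init_std=0.02,
                 bias_init=0.0):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = Parameter(rng.normal(0.0, init_std, size=(cout, cin, k, k)))
        self.bias = Parameter(np.full(cout, bias_init, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, cin, cout, k, stride=1, padding=0, bias=True, *, rng, init_std=0.02):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = Parameter(rng.normal(0.0, init_std, size=(cin, cout, k, k)))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    """Batch normalisation: batch statistics in training, running stats in eval."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self._set_buffer(
                "running_mean", (1 - self.momentum) * self.running_mean + self.momentum * mu
            )
            self._set_buffer(
                "running_var", (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mu, var = self.running_mean, self.running_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat_data = (x.data - mu.reshape(1, -1, 1, 1)) * ivstd.reshape(1, -1, 1, 1)
        y_data = self.gamma.data.reshape(1, -1, 1, 1) * xhat_data + self.beta.data.reshape(
            1, -1, 1, 1
        )
        out = Tensor(y_data)
        parents = (x, self.gamma, self.beta)
        if is_grad_enabled() and any(p.requires_grad for p in parents):
            training = self.training
            gamma, beta = self.gamma, self.beta

            def backward(g):
                if gamma.requires_grad:
                    gamma._accum((g * xhat_data).sum(axis=(0, 2, 3)))
                if beta.requires_grad:
                    beta._accum(g.sum(axis=(0, 2, 3)))
                if x.requires_grad:
                    gk = gamma.data.reshape(1, -1, 1, 1)
                    iv = ivstd.reshape(1, -1, 1, 1)
                    if not training:
                        x._accum(g * gk * iv)
                    else:
                        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                        dxhat = g * gk
                        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
                        s2 = (dxhat * xhat_data).sum(axis=(0, 2, 3), keepdims=True)
                        x._accum(iv * (dxhat - s1 / m - xhat_data * s2 / m))

            out.requires_grad = True
            out._prev = parents
            out._backward = backward
        return out


class Adam:
    """Adaptive-moment optimizer (the conditional-GAN default: lr 2e-4, betas 0.5/0.999)."""

    def __init__(self, params, lr=2e-4, betas=(0.5, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            p.data = p.data - self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(m, dtype=np.float32) for m in state["m"]]
        self.v = [np.asarray(v, dtype=np.float32) for v in state["v"]]
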