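"""Neural-network layers and the Adam optimizer on top of :mod:`pepperseg.autograd`.

Layers follow the (batch, channel, height, width) convention.  Convolutions are
stride 1 with "same" zero padding and are evaluated via im2col + matmul so the
whole network reduces to a handful of BLAS calls per step.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "ConvTranspose2x2",
    "BatchNorm2d",
    "max_pool_2x2",
    "Adam",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal container: tracks parameters, buffers and train/eval mode."""

    def __init__(self):
        self.training = True
        self._buffers: dict[str, np.ndarray] = {}

    # -- traversal ---------------------------------------------------------
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Parameter]:
        params = [v for v in vars(self).values() if isinstance(v, Parameter)]
        for _, child in self._children():
            params.extend(child.parameters())
        return params

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- (de)serialization -------------------------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                state[prefix + name] = val.data.copy()
        for name, buf in self._buffers.items():
            state[prefix + name] = buf.copy()
        for name, child in self._children():
            state.update(child.state_dict(prefix + name + "."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                val.data = np.asarray(state[prefix + name], dtype=np.float64).copy()
        for name in list(self._buffers):
            self._buffers[name] = np.asarray(state[prefix + name], dtype=np.float64).copy()
        for name, child in self._children():
            child.load_state_dict(state, prefix + name + ".")

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


def _he_init(shape, fan_in: int, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """k x k convolution, stride 1, zero padding (k - 1) / 2 ("same" output size).

    Bias defaults to off because every conv in the segmentation blocks is
    immediately followed by batch normalization, which absorbs it.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 bias: bool = False, rng: np.random.Generator | None = None):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("Conv2d supports odd kernel sizes only")
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.pad = (kernel - 1) // 2
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_he_init((out_ch, in_ch, kernel, kernel), fan_in, rng))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        xd = x.data
        B, C, H, W = xd.shape
        k, p = self.kernel, self.pad
        xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)))
        # im2col: (B, C*k*k, H*W)
        cols = np.empty((B, C, k * k, H * W))
        for idx in range(k * k):
            i, j = divmod(idx, k)
            cols[:, :, idx, :] = xp[:, :, i:i + H, j:j + W].reshape(B, C, -1)
        cols = cols.reshape(B, C * k * k, H * W)
        w2 = w.data.reshape(self.out_ch, C * k * k)
        out = np.matmul(w2, cols)
        if b is not None:
            out = out + b.data[:, None]
        out = out.reshape(B, self.out_ch, H, W)

        def bwd(g):
            gR = np.asarray(g).reshape(B, self.out_ch, -1)
            if w.requires_grad:
                gw = np.einsum("bop,bcp->oc", gR, cols, optimize=True)
                Tensor._acc(w, gw.reshape(w.data.shape))
            if b is not None and b.requires_grad:
                Tensor._acc(b, gR.sum(axis=(0, 2)))
            if x.requires_grad:
                dcols = np.matmul(w2.T, gR).reshape(B, C, k * k, H, W)
                dxp = np.zeros_like(xp)
                for idx in range(k * k):
                    i, j = divmod(idx, k)
                    dxp[:, :, i:i + H, j:j + W] += dcols[:, :, idx]
                Tensor._acc(x, dxp[:, :, p:p + H, p:p + W])

        parents = (x, w) if b is None else (x, w, b)
        return Tensor._result(out, parents, bwd)


class ConvTranspose2x2(Module):
    """2x2 transposed convolution with stride 2: exact 2x spatial upsampling.

    With stride equal to the kernel size the output blocks do not overlap, so
    the op is a per-pixel channel mix followed by a block reshape.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Parameter(_he_init((in_ch, out_ch, 2, 2), in_ch * 4, rng))

    def forward(self, x: Tensor) -> Tensor:
        w = self.weight
        xd = x.data
        B, C, H, W = xd.shape
        out6 = np.einsum("bihw,iopq->bohpwq", xd, w.data, optimize=True)
        out = out6.reshape(B, self.out_ch, 2 * H, 2 * W)

        def bwd(g):
            g6 = np.asarray(g).reshape(B, self.out_ch, H, 2, W, 2)
            if w.requires_grad:
                Tensor._acc(w, np.einsum("bihw,bohpwq->iopq", xd, g6, optimize=True))
            if x.requires_grad:
                Tensor._acc(x, np.einsum("iopq,bohpwq->bihw", w.data, g6, optimize=True))

        return Tensor._result(out, (x, w), bwd)


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self._buffers["running_mean"] = np.zeros(ch)
        self._buffers["running_var"] = np.ones(ch)

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta = self.gamma, self.beta
        xd = x.data
        if self.training:
            axes = (0, 2, 3)
            m = xd.shape[0] * xd.shape[2] * xd.shape[3]
            mu = xd.mean(axis=axes)
            var = xd.var(axis=axes)
            mom = self.momentum
            self._buffers["running_mean"] = (1 - mom) * self._buffers["running_mean"] + mom * mu
            # unbiased variance in the running estimate, as is conventional
            unbiased = var * m / max(m - 1, 1)
            self._buffers["running_var"] = (1 - mom) * self._buffers["running_var"] + mom * unbiased
        else:
            mu = self._buffers["running_mean"]
            var = self._buffers["running_var"]
            m = None
        mu4 = mu[None, :, None, None]
        std = np.sqrt(var + self.eps)[None, :, None, None]
        xhat = (xd - mu4) / std
        out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

        if self.training:

            def bwd(g):
                g = np.asarray(g)
                if gamma.requires_grad:
                    Tensor._acc(gamma, (g * xhat).sum(axis=(0, 2, 3)))
                if beta.requires_grad:
                    Tensor._acc(beta, g.sum(axis=(0, 2, 3)))
                if x.requires_grad:
                    dxhat = g * gamma.data[None, :, None, None]
                    s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
                    s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    Tensor._acc(x, (dxhat - s1 / m - xhat * s2 / m) / std)

        else:

            def bwd(g):
                g = np.asarray(g)
                if gamma.requires_grad:
                    Tensor._acc(gamma, (g * xhat).sum(axis=(0, 2, 3)))
                if beta.requires_grad:
                    Tensor._acc(beta, g.sum(axis=(0, 2, 3)))
                if x.requires_grad:
                    Tensor._acc(x, g * gamma.data[None, :, None, None] / std)

        return Tensor._result(out, (x, gamma, beta), bwd)


def max_pool_2x2(x: Tensor) -> Tensor:
    """2x2 max pool, stride 2.  Ties route the gradient to the first maximum
    in window scan order (deterministic)."""
    xd = x.data
    B, C, H, W = xd.shape
    r = xd.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(B, C, H // 2, W // 2, 4)
    amax = r.argmax(axis=-1)
    out = np.take_along_axis(r, amax[..., None], axis=-1)[..., 0]

    def bwd(g):
        g = np.asarray(g)
        dr = np.zeros_like(r)
        np.put_along_axis(dr, amax[..., None], g[..., None], axis=-1)
        dx = dr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        Tensor._acc(x, dx.reshape(B, C, H, W))

    return Tensor._result(out, (x,), bwd)


class Adam:
    """Adam with the betas the training protocol uses by default (0.5, 0.999)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.5, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
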