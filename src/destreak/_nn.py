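"""Minimal CNN building blocks in NumPy with explicit backpropagation.

Tensors are channels-last ``(N, H, W, C)`` so that a k x k convolution
reduces to k^2 GEMMs (one per kernel tap) against contiguous slices of the
zero-padded input — no im2col buffer, BLAS does the work.  Only what the
residual artifact network needs is implemented: same-padded stride-1
convolution, per-channel batch norm, ReLU, and Adam.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "BatchNorm2D", "ReLU", "Sequential", "InceptionBlock", "Adam"]


class Layer:
    """Base: forward caches what backward needs; params/grads are dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}  # non-learned state (BN stats)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def named_arrays(self, prefix: str = ""):
        """Yield (name, owning layer, key) for every param and buffer."""
        for k in self.params:
            yield f"{prefix}{k}", self, k
        for k in self.buffers:
            yield f"{prefix}{k}", self, k

    def get_array(self, key: str) -> np.ndarray:
        return self.params[key] if key in self.params else self.buffers[key]

    def set_array(self, key: str, value: np.ndarray) -> None:
        store = self.params if key in self.params else self.buffers
        if store[key].shape != value.shape:
            raise ValueError(f"shape mismatch for {key}")
        store[key] = value.astype(store[key].dtype, copy=True)


def _rolled_kernel_fft(W: np.ndarray, k: int, P1: int, P2: int, dtype):
    """FFT of the (unflipped) kernel placed so taps sit at lags -p..p.

    With the kernel centered this way, ``irfft2(G_hat * K_hat)[0:h, 0:w]``
    is the same-cropped full convolution of the gradient with the kernel —
    the input-gradient of a same-padded correlation — with no per-kernel
    offset, so spectra of branches with different kernel sizes can be summed
    before a single inverse transform.
    """
    from scipy import fft as sfft
    p = k // 2
    pad = np.zeros((P1, P2) + W.shape[2:], dtype=dtype)
    rows = (np.arange(k) - p) % P1
    cols = (np.arange(k) - p) % P2
    pad[np.ix_(rows, cols)] = W
    return sfft.rfft2(pad, axes=(0, 1))


def _dw_from_spectra(X: np.ndarray, G: np.ndarray, k: int, P1: int, P2: int) -> np.ndarray:
    """Weight gradient of a same-padded correlation from input/grad spectra.

    dW[i, j] is the cross-correlation of the (unpadded) input with the output
    gradient at lag (i - p, j - p).  Only k^2 lags are needed, so instead of
    a full inverse FFT the lags are evaluated directly with small DFT
    matrices (the half-spectrum multiplicity handles hermitian symmetry).
    """
    p = k // 2
    # S[q1,q2,c,o] = sum_n X[n,q1,q2,c] * conj(G[n,q1,q2,o])
    S = np.matmul(X.transpose(1, 2, 3, 0), np.conj(G).transpose(1, 2, 0, 3))
    lags = np.arange(k) - p
    E1 = (np.exp(2j * np.pi * np.outer(lags, np.arange(P1)) / P1) / P1).astype(S.dtype)
    P2r = S.shape[1]
    mult = np.full(P2r, 2.0)
    mult[0] = 1.0
    if P2 % 2 == 0:
        mult[-1] = 1.0
    E2 = (np.exp(2j * np.pi * np.outer(lags, np.arange(P2r)) / P2) * (mult / P2)).astype(S.dtype)
    T = np.tensordot(E1, S, axes=(1, 0))          # (k, P2r, Cin, Cout)
    return np.real(np.einsum("iqco,jq->ijco", T, E2))


class Conv2D(Layer):
    """Stride-1, zero-padded (same) 2D convolution; He fan-in init.

    Two numerically equivalent execution paths: a direct tap loop (one GEMM
    per kernel tap) for small kernels, and an FFT path (spectral batched
    matmul) that wins once kernel area x channel products get large.  The
    crossover is a fixed work-ratio heuristic; both paths are exercised by
    the test suite.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32, zero_init: bool = False) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.k = kernel
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        w = np.zeros((kernel, kernel, c_in, c_out)) if zero_init else \
            rng.normal(0.0, std, size=(kernel, kernel, c_in, c_out))
        self.params = {"W": w.astype(dtype), "b": np.zeros(c_out, dtype=dtype)}

    def _use_fft(self, h: int, w: int) -> bool:
        # the spectral path pays one kernel FFT (cin*cout maps) plus data
        # FFTs; it only beats the tap loop once the kernel area is large
        return self.k >= 5 and min(self.c_in, self.c_out) >= 4 and min(h, w) >= 32

    # -- direct tap-loop path ------------------------------------------------
    def _forward_direct(self, x: np.ndarray, training: bool) -> np.ndarray:
        p = self.k // 2
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        self._cache = ("direct", xp if training else None, xp.shape)
        W, b = self.params["W"], self.params["b"]
        out = np.empty((n, h, w, self.c_out), dtype=x.dtype)
        out[:] = b
        flat = out.reshape(-1, self.c_out)
        for i in range(self.k):
            for j in range(self.k):
                xs = xp[:, i:i + h, j:j + w, :].reshape(-1, self.c_in)
                flat += xs @ W[i, j]
        return out

    def _backward_direct(self, grad: np.ndarray) -> np.ndarray:
        _, xp, xp_shape = self._cache
        n, h, w, _ = grad.shape
        p = self.k // 2
        W = self.params["W"]
        gflat = grad.reshape(-1, self.c_out)
        dW = np.empty_like(W)
        dxp = np.zeros(xp_shape, dtype=grad.dtype)
        for i in range(self.k):
            for j in range(self.k):
                xs = xp[:, i:i + h, j:j + w, :].reshape(-1, self.c_in)
                dW[i, j] = xs.T @ gflat
                dxp[:, i:i + h, j:j + w, :] += (gflat @ W[i, j].T).reshape(n, h, w, self.c_in)
        self.grads = {"W": dW, "b": gflat.sum(axis=0)}
        self._cache = None
        return dxp[:, p:p + h, p:p + w, :] if p else dxp

    # -- FFT path ------------------------------------------------------------
    def _fft_shape(self, h: int, w: int) -> tuple[int, int]:
        from scipy.fft import next_fast_len
        return next_fast_len(h + self.k - 1), next_fast_len(w + self.k - 1)

    def _forward_fft(self, x: np.ndarray, training: bool) -> np.ndarray:
        from scipy import fft as sfft
        n, h, w, _ = x.shape
        P1, P2 = self._fft_shape(h, w)
        X = sfft.rfft2(x, s=(P1, P2), axes=(1, 2))  # (N, P1, P2r, Cin)
        # rolled-kernel FFT: conj gives the forward correlation, the plain
        # spectrum gives the backward convolution — one kernel FFT per step
        Kr = _rolled_kernel_fft(
            self.params["W"].astype(x.dtype), self.k, P1, P2, x.dtype
        )
        Y = X.transpose(1, 2, 0, 3) @ np.conj(Kr)  # (P1, P2r, N, Cout)
        y = sfft.irfft2(Y.transpose(2, 0, 1, 3), s=(P1, P2), axes=(1, 2))
        out = y[:, :h, :w, :].astype(x.dtype) + self.params["b"]
        self._cache = (
            "fft",
            (X, Kr) if training else (None, None),
            (n, h, w),
            x.dtype,
        )
        return out

    def _backward_fft(self, grad: np.ndarray) -> np.ndarray:
        from scipy import fft as sfft
        _, (X, Kr), (n, h, w), dtype = self._cache
        P1, P2 = self._fft_shape(h, w)
        G = sfft.rfft2(grad, s=(P1, P2), axes=(1, 2))  # (N, P1, P2r, Cout)
        DX = G.transpose(1, 2, 0, 3) @ Kr.transpose(0, 1, 3, 2)  # (P1, P2r, N, Cin)
        dxf = sfft.irfft2(DX.transpose(2, 0, 1, 3), s=(P1, P2), axes=(1, 2))
        dx = dxf[:, :h, :w, :].astype(dtype)
        dW = _dw_from_spectra(X, G, self.k, P1, P2).astype(dtype)
        self.grads = {"W": dW, "b": grad.sum(axis=(0, 1, 2))}
        self._cache = None
        return dx

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if self._use_fft(x.shape[1], x.shape[2]):
            return self._forward_fft(x, training)
        return self._forward_direct(x, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._cache[0] == "fft":
            return self._backward_fft(grad)
        return self._backward_direct(grad)


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels: int, dtype=np.float32,
                 momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params = {
            "gamma": np.ones(channels, dtype=dtype),
            "beta": np.zeros(channels, dtype=dtype),
        }
        self.buffers = {
            "running_mean": np.zeros(channels, dtype=dtype),
            "running_var": np.ones(channels, dtype=dtype),
        }

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        g, b = self.params["gamma"], self.params["beta"]
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            rb = self.buffers
            rb["running_mean"] = ((1 - m) * rb["running_mean"] + m * mean).astype(rb["running_mean"].dtype)
            rb["running_var"] = ((1 - m) * rb["running_var"] + m * var).astype(rb["running_var"].dtype)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv
            self._cache = (xhat, inv.astype(x.dtype))
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
            xhat = (x - mean) / np.sqrt(var + self.eps)
        return xhat * g + b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        g = self.params["gamma"]
        m = grad.shape[0] * grad.shape[1] * grad.shape[2]
        dgamma = (grad * xhat).sum(axis=(0, 1, 2))
        dbeta = grad.sum(axis=(0, 1, 2))
        self.grads = {"gamma": dgamma, "beta": dbeta}
        # d/dx of batch-normalized activation (training statistics)
        dx = (g * inv / m) * (m * grad - dbeta - xhat * dgamma)
        self._cache = None
        return dx.astype(grad.dtype)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = np.where(self._mask, grad, 0)
        self._mask = None
        return out


class Sequential(Layer):
    def __init__(self, layers) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def named_arrays(self, prefix: str = ""):
        for idx, layer in enumerate(self.layers):
            yield from layer.named_arrays(f"{prefix}{idx}.")

    def iter_layers(self):
        for layer in self.layers:
            if isinstance(layer, (Sequential, InceptionBlock)):
                yield from layer.iter_layers()
            else:
                yield layer


class InceptionBlock(Layer):
    """Parallel conv branches with different kernel sizes, concatenated.

    Each branch is conv(k) -> BN -> ReLU mapping the full input to an equal
    share of the output channels; concatenation restores the trunk width.
    No pooling branch and no striding — the output must stay same-resolution
    for the final residual subtraction.

    On large inputs the branches are executed in a fused spectral form: the
    input is Fourier-transformed once and shared by every conv branch, the
    per-branch input-gradient spectra are summed so the backward pass needs
    a single inverse transform, and 1x1 branches stay in the spatial domain
    as plain GEMMs.  The fused path is numerically identical to running the
    branches independently (up to float rounding) and is covered by the
    same gradient checks.
    """

    def __init__(self, channels: int, kernels, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        kernels = tuple(kernels)
        if channels % len(kernels) != 0:
            raise ValueError(
                f"trunk width {channels} not divisible by {len(kernels)} branches"
            )
        self.kernels = kernels
        self.channels = channels
        self.share = channels // len(kernels)
        self.convs = [Conv2D(channels, self.share, k, rng, dtype=dtype) for k in kernels]
        self.bns = [BatchNorm2D(self.share, dtype=dtype) for _ in kernels]
        self.relus = [ReLU() for _ in kernels]

    def _fused(self, h: int, w: int) -> bool:
        return min(h, w) >= 32 and max(self.kernels) >= 5

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, h, w, c = x.shape
        if not self._fused(h, w):
            self._mode = "plain"
            outs = [
                relu.forward(bn.forward(conv.forward(x, training), training), training)
                for conv, bn, relu in zip(self.convs, self.bns, self.relus)
            ]
            return np.concatenate(outs, axis=-1)
        from scipy import fft as sfft
        self._mode = "fused"
        kmax = max(self.kernels)
        P1 = sfft.next_fast_len(h + kmax - 1)
        P2 = sfft.next_fast_len(w + kmax - 1)
        # one input FFT shared by every large-kernel branch
        X = sfft.rfft2(x, s=(P1, P2), axes=(1, 2))
        self._kr = {}
        outs = []
        for i, (k, conv, bn, relu) in enumerate(
            zip(self.kernels, self.convs, self.bns, self.relus)
        ):
            if k < 5:
                y = conv._forward_direct(x, training)
            else:
                Kr = _rolled_kernel_fft(
                    conv.params["W"].astype(x.dtype), k, P1, P2, x.dtype
                )
                if training:
                    self._kr[i] = Kr
                Y = X.transpose(1, 2, 0, 3) @ np.conj(Kr)
                y = sfft.irfft2(Y.transpose(2, 0, 1, 3), s=(P1, P2), axes=(1, 2))
                y = y[:, :h, :w, :].astype(x.dtype) + conv.params["b"]
            outs.append(relu.forward(bn.forward(y, training), training))
        self._cache = (X if training else None, (n, h, w, c), P1, P2)
        return np.concatenate(outs, axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mode == "plain":
            dx = None
            for i, (conv, bn, relu) in enumerate(zip(self.convs, self.bns, self.relus)):
                g = np.ascontiguousarray(grad[..., i * self.share:(i + 1) * self.share])
                piece = conv.backward(bn.backward(relu.backward(g)))
                dx = piece if dx is None else dx + piece
            return dx
        from scipy import fft as sfft
        X, (n, h, w, c), P1, P2 = self._cache
        dx_spatial = None
        DX = None
        for i, (k, conv, bn, relu) in enumerate(
            zip(self.kernels, self.convs, self.bns, self.relus)
        ):
            g = np.ascontiguousarray(grad[..., i * self.share:(i + 1) * self.share])
            g = bn.backward(relu.backward(g))
            if k < 5:
                piece = conv.backward(g)
                dx_spatial = piece if dx_spatial is None else dx_spatial + piece
            else:
                G = sfft.rfft2(g, s=(P1, P2), axes=(1, 2))
                # summed input-gradient spectra: one inverse FFT for all branches
                piece = G.transpose(1, 2, 0, 3) @ self._kr[i].transpose(0, 1, 3, 2)
                DX = piece if DX is None else DX + piece
                conv.grads = {
                    "W": _dw_from_spectra(X, G, k, P1, P2).astype(conv.params["W"].dtype),
                    "b": g.sum(axis=(0, 1, 2)),
                }
        self._cache = None
        self._kr = {}
        if DX is None:
            return dx_spatial
        dxf = sfft.irfft2(DX.transpose(2, 0, 1, 3), s=(P1, P2), axes=(1, 2))
        dx = dxf[:, :h, :w, :].astype(grad.dtype)
        return dx if dx_spatial is None else dx + dx_spatial

    def named_arrays(self, prefix: str = ""):
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            yield from conv.named_arrays(f"{prefix}br{i}.0.")
            yield from bn.named_arrays(f"{prefix}br{i}.1.")

    def iter_layers(self):
        for conv, bn in zip(self.convs, self.bns):
            yield conv
            yield bn


class Adam:
    """Adam with bias correction, applied to every learnable array of a model."""

    def __init__(self, root: Sequential, lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8) -> None:
        self.root = root
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m: dict[int, dict[str, np.ndarray]] = {}
        self.v: dict[int, dict[str, np.ndarray]] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for layer in self.root.iter_layers():
            if not layer.params:
                continue
            lid = id(layer)
            ms = self.m.setdefault(lid, {})
            vs = self.v.setdefault(lid, {})
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                g = g.astype(np.float64)
                m = ms.get(name)
                if m is None:
                    m = np.zeros_like(g)
                    vs[name] = np.zeros_like(g)
                v = vs[name]
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                ms[name], vs[name] = m, v
                update = self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
                layer.params[name] = (p - update).astype(p.dtype)
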