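"""Layers with explicit forward/backward passes.

Convolutions follow the usual cross-correlation convention.  ``Conv2d`` uses
an im2col matmul; its input-gradient is scattered back with one strided add
per kernel offset.  ``ConvTranspose2d`` avoids the (potentially huge) column
matrix altogether and runs one ``tensordot`` per kernel offset, which keeps
memory bounded by the activation size even for wide generators.  Padding on
the transposed convolution is the usual output crop, so arbitrarily large
values are legal (they just crop more).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .module import Module, Parameter


def _pair(v):
    if isinstance(v, (tuple, list)):
        return tuple(int(x) for x in v)
    return (int(v), int(v))


def _uniform(rng, scale, shape, dtype):
    """Uniform(-scale, scale) drawn natively in ``dtype`` (no float64 detour,
    which matters for the widest layers)."""
    dtype = np.dtype(dtype)
    if dtype == np.float32:
        out = rng.random(shape, dtype=np.float32)
    else:
        out = rng.random(shape).astype(dtype)
    out *= 2 * scale
    out -= scale
    return out


class Linear(Module):
    def __init__(self, in_features, out_features, rng, dtype=np.float32, bias=True):
        super().__init__()
        scale = 1.0 / np.sqrt(in_features)
        self.W = Parameter(_uniform(rng, scale, (in_features, out_features), dtype))
        self.b = Parameter(np.zeros(out_features, dtype=dtype)) if bias else None

    def forward(self, x):
        self._x = x
        out = x @ self.W.data
        if self.b is not None:
            out += self.b.data
        return out

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        if self.b is not None:
            self.b.grad += grad.sum(axis=0)
        return grad @ self.W.data.T


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel, stride=(1, 1), rng=None,
                 dtype=np.float32, bias=True):
        super().__init__()
        self.kh, self.kw = _pair(kernel)
        self.sh, self.sw = _pair(stride)
        fan_in = in_channels * self.kh * self.kw
        scale = 1.0 / np.sqrt(fan_in)
        self.W = Parameter(
            _uniform(rng, scale, (out_channels, in_channels, self.kh, self.kw), dtype))
        self.b = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def out_shape(self, h, w):
        if h < self.kh or w < self.kw:
            raise ValueError(
                f"conv kernel ({self.kh},{self.kw}) does not fit input ({h},{w})")
        return ((h - self.kh) // self.sh + 1, (w - self.kw) // self.sw + 1)

    def forward(self, x):
        B, C, H, Wd = x.shape
        Ho, Wo = self.out_shape(H, Wd)
        win = sliding_window_view(x, (self.kh, self.kw), axis=(2, 3))[:, :, ::self.sh, ::self.sw]
        # (B, C, Ho, Wo, kh, kw) -> (B, Ho*Wo, C*kh*kw)
        col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B, Ho * Wo, C * self.kh * self.kw)
        Wmat = self.W.data.reshape(self.W.data.shape[0], -1)
        out = col @ Wmat.T
        if self.b is not None:
            out += self.b.data
        self._cache = (col, x.shape, (Ho, Wo))
        return out.transpose(0, 2, 1).reshape(B, -1, Ho, Wo)

    def backward(self, grad):
        col, xshape, (Ho, Wo) = self._cache
        B, C, H, Wd = xshape
        Co = grad.shape[1]
        g = grad.reshape(B, Co, Ho * Wo).transpose(0, 2, 1)  # (B, HoWo, Co)
        Wmat = self.W.data.reshape(Co, -1)
        self.W.grad += (
            g.reshape(-1, Co).T @ col.reshape(-1, col.shape[-1])
        ).reshape(self.W.data.shape)
        if self.b is not None:
            self.b.grad += grad.sum(axis=(0, 2, 3))
        gcol = (g @ Wmat).reshape(B, Ho, Wo, C, self.kh, self.kw)
        gx = np.zeros(xshape, dtype=grad.dtype)
        for i in range(self.kh):
            he = i + self.sh * (Ho - 1) + 1
            for j in range(self.kw):
                we = j + self.sw * (Wo - 1) + 1
                gx[:, :, i:he:self.sh, j:we:self.sw] += gcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return gx


class ConvTranspose2d(Module):
    def __init__(self, in_channels, out_channels, kernel, stride=(1, 1), padding=(0, 0),
                 output_padding=(0, 0), rng=None, dtype=np.float32, bias=True):
        super().__init__()
        self.kh, self.kw = _pair(kernel)
        self.sh, self.sw = _pair(stride)
        self.ph, self.pw = _pair(padding)
        self.oph, self.opw = _pair(output_padding)
        fan_in = in_channels * self.kh * self.kw
        scale = 1.0 / np.sqrt(fan_in)
        self.W = Parameter(
            _uniform(rng, scale, (in_channels, out_channels, self.kh, self.kw), dtype))
        self.b = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def out_shape(self, h, w):
        ho = (h - 1) * self.sh + self.kh - 2 * self.ph + self.oph
        wo = (w - 1) * self.sw + self.kw - 2 * self.pw + self.opw
        if ho <= 0 or wo <= 0:
            raise ValueError(
                f"transposed conv collapses input ({h},{w}) to ({ho},{wo})")
        return ho, wo

    def _full_shape(self, h, w):
        return (h - 1) * self.sh + self.kh, (w - 1) * self.sw + self.kw

    def forward(self, x):
        B, C, H, Wd = x.shape
        Hf, Wf = self._full_shape(H, Wd)
        Ho, Wo = self.out_shape(H, Wd)
        Co = self.W.data.shape[1]
        full = np.zeros((B, Co, Hf, Wf), dtype=x.dtype)
        for i in range(self.kh):
            he = i + self.sh * (H - 1) + 1
            for j in range(self.kw):
                we = j + self.sw * (Wd - 1) + 1
                contrib = np.tensordot(x, self.W.data[:, :, i, j], axes=(1, 0))
                full[:, :, i:he:self.sh, j:we:self.sw] += contrib.transpose(0, 3, 1, 2)
        out = np.zeros((B, Co, Ho, Wo), dtype=x.dtype)
        hi = min(Ho, Hf - 2 * self.ph)
        wi = min(Wo, Wf - 2 * self.pw)
        out[:, :, :hi, :wi] = full[:, :, self.ph:self.ph + hi, self.pw:self.pw + wi]
        if self.b is not None:
            out += self.b.data[None, :, None, None]
        self._cache = (x, (Hf, Wf), (hi, wi))
        return out

    def backward(self, grad):
        x, (Hf, Wf), (hi, wi) = self._cache
        B, C, H, Wd = x.shape
        Co = grad.shape[1]
        if self.b is not None:
            self.b.grad += grad.sum(axis=(0, 2, 3))
        gfull = np.zeros((B, Co, Hf, Wf), dtype=grad.dtype)
        gfull[:, :, self.ph:self.ph + hi, self.pw:self.pw + wi] = grad[:, :, :hi, :wi]
        gx = np.zeros_like(x)
        for i in range(self.kh):
            he = i + self.sh * (H - 1) + 1
            for j in range(self.kw):
                we = j + self.sw * (Wd - 1) + 1
                gslice = gfull[:, :, i:he:self.sh, j:we:self.sw]  # (B, Co, H, Wd)
                gx += np.tensordot(gslice, self.W.data[:, :, i, j], axes=(1, 1)).transpose(0, 3, 1, 2)
                self.W.grad[:, :, i, j] += np.einsum("bchw,bohw->co", x, gslice)
        return gx


class BatchNorm2d(Module):
    def __init__(self, num_features, dtype=np.float32, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features, dtype=dtype))
        self.beta = Parameter(np.zeros(num_features, dtype=dtype))
        self.buf_running_mean = np.zeros(num_features, dtype=dtype)
        self.buf_running_var = np.ones(num_features, dtype=dtype)

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.buf_running_mean[...] = ((1 - self.momentum) * self.buf_running_mean
                                          + self.momentum * mean)
            self.buf_running_var[...] = ((1 - self.momentum) * self.buf_running_var
                                         + self.momentum * var)
        else:
            mean, var = self.buf_running_mean, self.buf_running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, grad):
        xhat, inv = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.data[None, :, None, None]
        if not self.training:
            return g * inv[None, :, None, None]
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        gmean = g.mean(axis=(0, 2, 3))
        gxhat_mean = (g * xhat).mean(axis=(0, 2, 3))
        return (inv[None, :, None, None]
                * (g - gmean[None, :, None, None] - xhat * gxhat_mean[None, :, None, None]))


class LeakyReLU(Module):
    def __init__(self, negative_slope=0.2):
        super().__init__()
        self.slope = negative_slope

    def forward(self, x):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Tanh(Module):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1 - self._y ** 2)


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p, rng):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x):
        if not self.training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask.astype(grad.dtype)


class MaxPool2d(Module):
    """Max pooling with a (1, k) window over the last axis (time)."""

    def __init__(self, kernel, stride):
        super().__init__()
        kh, self.kw = _pair(kernel)
        sh, self.sw = _pair(stride)
        if kh != 1 or sh != 1:
            raise ValueError("only (1, k) pooling windows are supported")

    def forward(self, x):
        B, C, H, Wd = x.shape
        Wo = (Wd - self.kw) // self.sw + 1
        win = sliding_window_view(x, self.kw, axis=3)[:, :, :, ::self.sw]  # (B,C,H,Wo,kw)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape, Wo)
        return out

    def backward(self, grad):
        idx, xshape, Wo = self._cache
        B, C, H, Wd = xshape
        gx = np.zeros((B * C * H, Wd), dtype=grad.dtype)
        cols = idx.reshape(-1, Wo) + np.arange(Wo) * self.sw
        rows = np.repeat(np.arange(B * C * H)[:, None], Wo, axis=1)
        np.add.at(gx, (rows, cols), grad.reshape(-1, Wo))
        return gx.reshape(xshape)


class Reshape(Module):
    def __init__(self, shape):
        super().__init__()
        self.shape = tuple(shape)

    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Flatten(Module):
    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTM(Module):
    """Stacked LSTM over (batch, time, features); returns the full output
    sequence of the last layer.  Dropout is applied between layers (per time
    step), matching the usual stacked-LSTM convention."""

    def __init__(self, input_size, hidden_size, num_layers, rng, dropout=0.0,
                 dtype=np.float32):
        super().__init__()
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.dropout_p = dropout
        self.rng = rng
        self.Wx, self.Wh, self.b = [], [], []
        for layer in range(num_layers):
            d_in = input_size if layer == 0 else hidden_size
            scale = 1.0 / np.sqrt(hidden_size)
            self.Wx.append(Parameter(_uniform(rng, scale, (d_in, 4 * hidden_size), dtype)))
            self.Wh.append(Parameter(_uniform(rng, scale, (hidden_size, 4 * hidden_size), dtype)))
            self.b.append(Parameter(np.zeros(4 * hidden_size, dtype=dtype)))

    def named_parameters(self, prefix=""):
        for name, plist in (("Wx", self.Wx), ("Wh", self.Wh), ("b", self.b)):
            for i, p in enumerate(plist):
                yield f"{prefix}{name}.{i}", p

    def forward(self, x):
        B, L, _ = x.shape
        H = self.hidden_size
        self._caches = []
        inp = x
        for layer in range(self.num_layers):
            h = np.zeros((B, H), dtype=x.dtype)
            c = np.zeros((B, H), dtype=x.dtype)
            steps = []
            outs = np.empty((B, L, H), dtype=x.dtype)
            for t in range(L):
                xt = inp[:, t, :]
                z = xt @ self.Wx[layer].data + h @ self.Wh[layer].data + self.b[layer].data
                i_g = _sigmoid(z[:, :H])
                f_g = _sigmoid(z[:, H:2 * H])
                g_g = np.tanh(z[:, 2 * H:3 * H])
                o_g = _sigmoid(z[:, 3 * H:])
                c_new = f_g * c + i_g * g_g
                tanh_c = np.tanh(c_new)
                h_new = o_g * tanh_c
                steps.append((xt, h, c, i_g, f_g, g_g, o_g, tanh_c))
                h, c = h_new, c_new
                outs[:, t, :] = h
            mask = None
            layer_out = outs
            if self.training and self.dropout_p > 0 and layer < self.num_layers - 1:
                mask = (self.rng.random(outs.shape) >= self.dropout_p) / (1 - self.dropout_p)
                layer_out = outs * mask.astype(outs.dtype)
            self._caches.append((inp, steps, mask))
            inp = layer_out
        return inp

    def backward(self, grad_seq):
        H = self.hidden_size
        g_out = grad_seq
        for layer in reversed(range(self.num_layers)):
            inp, steps, mask = self._caches[layer]
            if mask is not None:
                g_out = g_out * mask.astype(g_out.dtype)
            B, L, _ = inp.shape
            gx = np.zeros_like(inp)
            dh = np.zeros((B, H), dtype=g_out.dtype)
            dc = np.zeros((B, H), dtype=g_out.dtype)
            for t in reversed(range(L)):
                xt, h_prev, c_prev, i_g, f_g, g_g, o_g, tanh_c = steps[t]
                dh = dh + g_out[:, t, :]
                do = dh * tanh_c
                dc = dc + dh * o_g * (1 - tanh_c ** 2)
                di = dc * g_g
                df = dc * c_prev
                dg = dc * i_g
                dz = np.concatenate([
                    di * i_g * (1 - i_g),
                    df * f_g * (1 - f_g),
                    dg * (1 - g_g ** 2),
                    do * o_g * (1 - o_g),
                ], axis=1)
                self.Wx[layer].grad += xt.T @ dz
                self.Wh[layer].grad += h_prev.T @ dz
                self.b[layer].grad += dz.sum(axis=0)
                gx[:, t, :] = dz @ self.Wx[layer].data.T
                dh = dz @ self.Wh[layer].data.T
                dc = dc * f_g
            g_out = gx
        return g_out
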