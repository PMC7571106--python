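"""Compact NumPy neural-network engine for the gait classifier.

Implements exactly the layer set the multi-channel CNN+BiLSTM architectures
need: 1-D same-padding convolution, batch normalization, ReLU, max pooling,
bidirectional LSTM, dropout, dense layers and a softmax cross-entropy head,
with hand-derived backward passes and an Adam optimizer.

Two performance ideas shape the implementation.  First, the architecture
processes every sensor signal in an identical parallel branch, so all
branch weights carry a leading stack axis ``P`` and each layer runs one
batched BLAS call for all branches at once (the BiLSTM folds its two
directions in as well, giving ``2P`` stacked recurrences, with the
per-timestep input projections hoisted out of the loop and a batch-last
memory layout that keeps every per-step slice contiguous).  Second, all
large intermediates live in per-layer buffer pools that are reused across
training steps — repeated hundred-MB allocations otherwise spend more time
in page faults than in arithmetic.

Gradients are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import ctypes
import ctypes.util

import numpy as np


def _tune_allocator():
    """Keep large numpy buffers on the heap instead of mmap/munmap cycles.

    With glibc defaults every large buffer freed goes back to the kernel
    and its next use page-faults the whole region in again.  Raising the
    mmap threshold (and disabling trim) makes those buffers reusable at
    full speed.  Best effort: silently skipped off glibc.
    """
    try:
        path = ctypes.util.find_library("c")
        libc = ctypes.CDLL(path) if path else ctypes.CDLL("libc.so.6")
        m_mmap_threshold, m_trim_threshold = -3, -1
        libc.mallopt(m_mmap_threshold, 1 << 30)
        libc.mallopt(m_trim_threshold, 1 << 30)
    except (OSError, AttributeError):
        pass


_tune_allocator()


class _BufferPool:
    """Shape-keyed scratch buffers, reused across steps to avoid re-faulting."""

    def __init__(self):
        self._store = {}

    def get(self, name, shape, dtype):
        a = self._store.get(name)
        if a is None or a.shape != tuple(shape) or a.dtype != dtype:
            a = np.empty(shape, dtype)
            self._store[name] = a
        return a

    def zeros(self, name, shape, dtype):
        a = self.get(name, shape, dtype)
        a[...] = 0
        return a


class Layer:
    """Base layer: subclasses fill ``params``/``grads`` (aligned lists)."""

    params: list
    grads: list

    buffers: list

    def __init__(self):
        self.params = []
        self.grads = []
        self.buffers = []          # non-trainable state (e.g. BN statistics)
        self.pool = _BufferPool()

    def forward(self, x, training):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class Sequential(Layer):
    def __init__(self, layers):
        super().__init__()
        self.layers = layers

    def forward(self, x, training):
        for lay in self.layers:
            x = lay.forward(x, training)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy

    def iter_params(self):
        for lay in self.layers:
            if isinstance(lay, (Sequential, Parallel)):
                yield from lay.iter_params()
            else:
                yield from zip(lay.params, lay.grads)

    def iter_buffers(self):
        for lay in self.layers:
            if isinstance(lay, (Sequential, Parallel)):
                yield from lay.iter_buffers()
            else:
                yield from lay.buffers


class Parallel(Layer):
    """Run paths on the same input; concatenate outputs on the last axis."""

    def __init__(self, paths):
        super().__init__()
        self.paths = paths
        self._widths = None

    def forward(self, x, training):
        outs = [p.forward(x, training) for p in self.paths]
        self._widths = [o.shape[-1] for o in outs]
        return np.concatenate(outs, axis=-1)

    def backward(self, dy):
        dx = None
        start = 0
        for p, w in zip(self.paths, self._widths):
            d = p.backward(dy[..., start:start + w])
            dx = d.copy() if dx is None else dx.__iadd__(d)
            start += w
        return dx

    def iter_params(self):
        for p in self.paths:
            yield from p.iter_params()

    def iter_buffers(self):
        for p in self.paths:
            yield from p.iter_buffers()


def _glorot(rng, shape, fan_in, fan_out, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Conv1DSame(Layer):
    """Stacked 1-D convolution with 'same' zero padding.

    Input ``(P, B, T, d)`` -> output ``(P, B, T, F)``.  Computed as a sum of
    shifted matmuls (one per kernel tap), which avoids materializing an
    im2col tensor ``k`` times the input size.
    """

    def __init__(self, rng, n_branches, d_in, n_filters, kernel_size, dtype):
        super().__init__()
        self.k = kernel_size
        self.d = d_in
        self.f = n_filters
        # W[:, j] is the weight matrix of kernel tap j
        self.W = _glorot(rng, (n_branches, kernel_size, d_in, n_filters),
                         kernel_size * d_in, n_filters, dtype)
        self.b = np.zeros((n_branches, 1, 1, n_filters), dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training):
        P, B, T, d = x.shape
        pl = self.k // 2
        Tp = T + self.k - 1
        xpad = self.pool.get("xpad", (P, B, Tp, d), x.dtype)
        xpad[:, :, :pl] = 0
        xpad[:, :, pl + T:] = 0
        xpad[:, :, pl:pl + T] = x
        self._shape = x.shape
        y = self.pool.get("y", (P, B, T, self.f), x.dtype)
        yf = y.reshape(P, B * T, self.f)
        part = self.pool.get("part", (P, B * T, self.f), x.dtype)
        for j in range(self.k):
            xj = xpad[:, :, j:j + T].reshape(P, B * T, d)
            if d == 1:
                # K=1 gemms degenerate in BLAS; broadcast the outer product
                np.multiply(xj, self.W[:, j], out=part)
            else:
                np.matmul(xj, self.W[:, j], out=part)
            if j == 0:
                yf[...] = part
            else:
                yf += part
        y += self.b
        return y

    def backward(self, dy):
        P, B, T, d = self._shape
        pl = self.k // 2
        xpad = self.pool.get("xpad", (P, B, T + self.k - 1, d), dy.dtype)
        dyf = dy.reshape(P, B * T, self.f)
        dW, db = self.grads
        db[...] = dy.sum(axis=(1, 2), keepdims=True)
        dxpad = self.pool.zeros("dxpad", xpad.shape, dy.dtype)
        dpart = self.pool.get("dpart", (P, B * T, d), dy.dtype)
        WT = np.ascontiguousarray(self.W.transpose(0, 1, 3, 2))
        for j in range(self.k):
            xj = xpad[:, :, j:j + T].reshape(P, B * T, d)
            dW[:, j] = xj.transpose(0, 2, 1) @ dyf
            np.matmul(dyf, WT[:, j], out=dpart)
            dxpad[:, :, j:j + T] += dpart.reshape(P, B, T, d)
        return dxpad[:, :, pl:pl + T]


class BatchNorm(Layer):
    """Per-filter batch normalization over the (batch, time) axes."""

    def __init__(self, n_branches, n_filters, dtype, momentum=0.9, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones((n_branches, 1, 1, n_filters), dtype=dtype)
        self.beta = np.zeros((n_branches, 1, 1, n_filters), dtype=dtype)
        self.run_mean = np.zeros((n_branches, 1, 1, n_filters), dtype=dtype)
        self.run_var = np.ones((n_branches, 1, 1, n_filters), dtype=dtype)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.buffers = [self.run_mean, self.run_var]

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(1, 2), keepdims=True)
            var = x.var(axis=(1, 2), keepdims=True)
            self.run_mean *= self.momentum
            self.run_mean += (1 - self.momentum) * mean
            self.run_var *= self.momentum
            self.run_var += (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = self.pool.get("xhat", x.shape, x.dtype)
        np.subtract(x, mean, out=xhat)
        xhat *= self._ivstd
        self._xhat = xhat
        self._n = x.shape[1] * x.shape[2]
        self._training = training
        y = self.pool.get("y", x.shape, x.dtype)
        np.multiply(self.gamma, xhat, out=y)
        y += self.beta
        return y

    def backward(self, dy):
        xhat = self._xhat
        scratch = self.pool.get("scratch", dy.shape, dy.dtype)
        np.multiply(dy, xhat, out=scratch)
        self.grads[0][...] = scratch.sum(axis=(1, 2), keepdims=True)
        self.grads[1][...] = dy.sum(axis=(1, 2), keepdims=True)
        if not self._training:
            np.multiply(dy, self.gamma * self._ivstd, out=scratch)
            return scratch
        dxhat = self.pool.get("dxhat", dy.shape, dy.dtype)
        np.multiply(dy, self.gamma, out=dxhat)
        m1 = dxhat.mean(axis=(1, 2), keepdims=True)
        np.multiply(dxhat, xhat, out=scratch)
        m2 = scratch.mean(axis=(1, 2), keepdims=True)
        np.multiply(xhat, m2, out=scratch)
        dxhat -= m1
        dxhat -= scratch
        dxhat *= self._ivstd
        return dxhat


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        y = self.pool.get("y", x.shape, x.dtype)
        np.multiply(x, self._mask, out=y)
        return y

    def backward(self, dy):
        dx = self.pool.get("dx", dy.shape, dy.dtype)
        np.multiply(dy, self._mask, out=dx)
        return dx


class MaxPool1D(Layer):
    """Non-overlapping temporal max pooling; trailing remainder dropped."""

    def __init__(self, pool_size):
        super().__init__()
        self.size = pool_size

    def forward(self, x, training):
        P, B, T, F = x.shape
        tp = T // self.size
        self._in_T = T
        xr = x[:, :, :tp * self.size].reshape(P, B, tp, self.size, F)
        self._arg = xr.argmax(axis=3)
        return np.take_along_axis(xr, self._arg[:, :, :, None], axis=3)[:, :, :, 0]

    def backward(self, dy):
        P, B, tp, F = dy.shape
        dxr = self.pool.zeros("dxr", (P, B, tp, self.size, F), dy.dtype)
        np.put_along_axis(dxr, self._arg[:, :, :, None], dy[:, :, :, None], axis=3)
        dx = self.pool.zeros("dx", (P, B, self._in_T, F), dy.dtype)
        dx[:, :, :tp * self.size] = dxr.reshape(P, B, tp * self.size, F)
        return dx


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        P, B = x.shape[:2]
        return x.reshape(P, B, -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    """Stacked affine layer on ``(P, B, d)`` inputs, optional ReLU."""

    def __init__(self, rng, n_branches, d_in, d_out, dtype, relu=False):
        super().__init__()
        self.relu = relu
        self.W = _glorot(rng, (n_branches, d_in, d_out), d_in, d_out, dtype)
        self.b = np.zeros((n_branches, 1, d_out), dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training):
        self._x = x
        y = x @ self.W + self.b
        if self.relu:
            self._mask = y > 0
            y *= self._mask
        return y

    def backward(self, dy):
        if self.relu:
            dy = dy * self._mask
        self.grads[0][...] = self._x.transpose(0, 2, 1) @ dy
        self.grads[1][...] = dy.sum(axis=1, keepdims=True)
        dx = dy @ self.W.transpose(0, 2, 1)
        self._x = None
        return dx


class Dropout(Layer):
    def __init__(self, rate, rng):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class BiLSTM(Layer):
    """Stacked bidirectional LSTM.

    The two directions are folded into the stack axis (``2P`` recurrences
    run together); gate order is [i, f, o, g] and the forget-gate bias
    starts at 1.  Internals are branch-major and batch-last,
    ``(2P, T, features, B)``: every per-timestep slice is a strided view
    with large contiguous chunks, each direction's gate block is one
    contiguous half, and the hoisted input projections become single
    batched BLAS calls.  Axis-permuting copies are kept off the hot path
    (they run near memory-latency speed on one core).

    ``input_layout``/sequence output layouts: ``"btd"`` = ``(P, B, T, d)``
    (the external convention) or ``"ptdb"`` = ``(P, T, d, B)`` (used to
    chain two layers without transposing the sequence tensor).  With
    ``return_sequences=False`` the output is always ``(P, B, 2H)`` — the
    concatenated final hidden state of each direction's own pass.
    """

    def __init__(self, rng, n_branches, d_in, hidden, dtype, return_sequences,
                 input_layout="btd", output_layout=None):
        super().__init__()
        self.h = hidden
        self.d = d_in
        self.P = n_branches
        self.return_sequences = return_sequences
        self.input_layout = input_layout
        self.output_layout = output_layout or ("ptdb" if return_sequences else "btd")
        q = 2 * n_branches
        H = hidden
        self.Wx = _glorot(rng, (q, 4 * H, d_in), d_in + H, 4 * H, dtype)
        self.Wh = _glorot(rng, (q, 4 * H, H), d_in + H, 4 * H, dtype)
        self.b = np.zeros((q, 4 * H, 1), dtype=dtype)
        self.b[:, H:2 * H] = 1.0  # forget gate
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(self.Wx), np.zeros_like(self.Wh),
                      np.zeros_like(self.b)]

    def forward(self, x, training):
        P, H = self.P, self.h
        q = 2 * P
        pool = self.pool
        if self.input_layout == "btd":
            _, B, T, d = x.shape
            xT = pool.get("xT", (P, T, d, B), x.dtype)
            xT[...] = x.transpose(0, 2, 3, 1)
        else:
            _, T, d, B = x.shape
            xT = x
        self._xT = xT
        dt = xT.dtype
        gates = pool.get("gates", (q, T, 4 * H, B), dt)
        # hoisted input projections; the reversed direction reads
        # time-reversed input, realized as a chunk-reversed write.  The
        # buffer is overwritten in place with the activated gates as the
        # recurrence runs.  BLAS degenerates on inner dimension 1, so very
        # narrow inputs use broadcast outer products instead.
        if d <= 2:
            for j in range(d):
                xj = xT[:, :, j][:, :, None, :]           # (P, T, 1, B)
                wf = self.Wx[:P, None, :, j, None]        # (P, 1, 4H, 1)
                wb = self.Wx[P:, None, :, j, None]
                if j == 0:
                    np.multiply(wf, xj, out=gates[:P])
                    np.multiply(wb, xj, out=gates[P:, ::-1])
                else:
                    gates[:P] += wf * xj
                    gates[P:, ::-1] += wb * xj
        else:
            np.matmul(self.Wx[:P, None], xT, out=gates[:P])
            np.matmul(self.Wx[P:, None], xT, out=gates[P:, ::-1])
        gates += self.b[:, None]
        C = pool.get("C", (q, T, H, B), dt)
        Hall = pool.get("Hall", (q, T, H, B), dt)
        zeros = pool.zeros("zeros", (q, H, B), dt)
        tmp = pool.get("tmp", (q, H, B), dt)
        hw = pool.get("hw", (q, 4 * H, B), dt)
        h, c = zeros, zeros
        for t in range(T):
            g = gates[:, t]
            np.matmul(self.Wh, h, out=hw)
            g += hw
            gs = g[:, :3 * H]
            np.negative(gs, out=gs)
            np.exp(gs, out=gs)
            gs += 1.0
            np.reciprocal(gs, out=gs)
            gg = g[:, 3 * H:]
            np.tanh(gg, out=gg)
            cn = C[:, t]
            np.multiply(g[:, H:2 * H], c, out=cn)   # f * c_prev
            np.multiply(g[:, :H], gg, out=tmp)      # i * g
            cn += tmp
            hn = Hall[:, t]
            np.tanh(cn, out=tmp)
            np.multiply(g[:, 2 * H:3 * H], tmp, out=hn)  # o * tanh(c)
            h, c = hn, cn
        self._dims = (T, B)
        if self.return_sequences:
            out = pool.get("out", (P, T, 2 * H, B), dt)
            out[:, :, :H] = Hall[:P]
            out[:, :, H:] = Hall[P:, ::-1]
            if self.output_layout == "ptdb":
                return out
            out_b = pool.get("out_b", (P, B, T, 2 * H), dt)
            out_b[...] = out.transpose(0, 3, 1, 2)
            return out_b
        hf = Hall[:, -1]                            # (q, H, B)
        out = pool.get("out", (P, B, 2 * H), dt)
        out[..., :H] = hf[:P].transpose(0, 2, 1)
        out[..., H:] = hf[P:].transpose(0, 2, 1)
        return out

    def backward(self, dy):
        T, B = self._dims
        P, H, q = self.P, self.h, 2 * self.P
        pool = self.pool
        dt = dy.dtype
        gates = pool.get("gates", (q, T, 4 * H, B), dt)
        C = pool.get("C", (q, T, H, B), dt)
        Hall = pool.get("Hall", (q, T, H, B), dt)
        if self.return_sequences:
            if self.output_layout == "btd":
                dy_t = pool.get("dy_t", (P, T, 2 * H, B), dt)
                dy_t[...] = dy.transpose(0, 2, 3, 1)
                dy = dy_t
            # (P, T, 2H, B): split directions, re-reverse the backward one
            dseq = pool.get("dseq", (q, T, H, B), dt)
            dseq[:P] = dy[:, :, :H]
            dseq[P:] = dy[:, ::-1, H:]
            dh = pool.get("dh", (q, H, B), dt)
            dh[...] = dseq[:, T - 1]
        else:
            dseq = None
            dh = pool.get("dh", (q, H, B), dt)
            dh[:P] = dy[..., :H].transpose(0, 2, 1)
            dh[P:] = dy[..., H:].transpose(0, 2, 1)
        WhT = np.ascontiguousarray(self.Wh.transpose(0, 2, 1))
        dWh = self.grads[1]
        dWh[...] = 0.0
        dc = pool.zeros("dc", (q, H, B), dt)
        tc = pool.get("tc", (q, H, B), dt)
        tmp = pool.get("tmp2", (q, H, B), dt)
        keep_i = pool.get("keep_i", (q, H, B), dt)
        keep_o = pool.get("keep_o", (q, H, B), dt)
        dh_next = pool.get("dh_next", (q, H, B), dt)
        zeros = pool.zeros("zeros", (q, H, B), dt)
        # gate buffers are consumed in place: activations are overwritten
        # with the pre-activation gradients step by step
        for t in range(T - 1, -1, -1):
            g = gates[:, t]
            i = g[:, :H]; f = g[:, H:2 * H]
            o = g[:, 2 * H:3 * H]; gg = g[:, 3 * H:]
            np.tanh(C[:, t], out=tc)
            np.multiply(tc, tc, out=tmp)         # dc += dh * o * (1 - tc^2)
            np.subtract(1.0, tmp, out=tmp)
            tmp *= o
            tmp *= dh
            dc += tmp
            c_prev = C[:, t - 1] if t > 0 else zeros
            h_prev = Hall[:, t - 1] if t > 0 else zeros
            np.multiply(dh, tc, out=tmp)         # do
            np.subtract(1.0, o, out=tc)          # tc freed; reuse as scratch
            tmp *= o
            tmp *= tc
            keep_o[...] = tmp
            np.multiply(dc, gg, out=tmp)         # di
            np.subtract(1.0, i, out=tc)
            tmp *= i
            tmp *= tc
            keep_i[...] = tmp
            np.multiply(dc, i, out=tmp)          # dg
            np.multiply(gg, gg, out=tc)
            np.subtract(1.0, tc, out=tc)
            tmp *= tc
            gg[...] = tmp
            np.multiply(dc, c_prev, out=tmp)     # df
            np.subtract(1.0, f, out=tc)
            tmp *= f
            tmp *= tc
            dc *= f                              # carry while f still intact
            f[...] = tmp
            i[...] = keep_i
            o[...] = keep_o
            dWh += g @ h_prev.transpose(0, 2, 1)
            np.matmul(WhT, g, out=dh_next)
            if t > 0 and dseq is not None:
                dh_next += dseq[:, t - 1]
            dh, dh_next = dh_next, dh
        xT = self._xT
        d = self.d
        xTt = xT.transpose(0, 1, 3, 2)           # (P, T, B, d) view
        dwx_a = pool.get("dwx_a", (P, T, 4 * H, d), dt)
        np.matmul(gates[:P], xTt, out=dwx_a)
        self.grads[0][:P] = dwx_a.sum(axis=1)
        np.matmul(gates[P:, ::-1], xTt, out=dwx_a)
        self.grads[0][P:] = dwx_a.sum(axis=1)
        self.grads[2][...] = gates.sum(axis=(1, 3))[..., None]
        WxT = np.ascontiguousarray(self.Wx.transpose(0, 2, 1))
        dxT = pool.get("dxT", (P, T, d, B), dt)
        dxT_b = pool.get("dxT_b", (P, T, d, B), dt)
        np.matmul(WxT[:P, None], gates[:P], out=dxT)
        np.matmul(WxT[P:, None], gates[P:], out=dxT_b)
        dxT[:, ::-1] += dxT_b
        self._xT = None
        if self.input_layout == "btd":
            dx = pool.get("dx", (P, B, T, d), dt)
            dx[...] = dxT.transpose(0, 3, 1, 2)
            return dx
        return dxT



class ConcatBranches(Layer):
    """(P, B, D) -> (1, B, P*D): merge branch outputs for the fusion stage."""

    def forward(self, x, training):
        P, B, D = x.shape
        self._shape = x.shape
        return x.transpose(1, 0, 2).reshape(B, P * D)[None]

    def backward(self, dy):
        P, B, D = self._shape
        return dy[0].reshape(B, P, D).transpose(1, 0, 2)


def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits, onehot):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    eps = np.finfo(p.dtype).tiny
    loss = float(-(onehot * np.log(p + eps)).sum(axis=-1).mean())
    dlogits = (p - onehot) / logits.shape[0]
    return loss, dlogits.astype(logits.dtype)


class Adam:
    def __init__(self, net, learning_rate=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net = net
        self.lr = learning_rate
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.state = [(np.zeros_like(p), np.zeros_like(p))
                      for p, _ in net.iter_params()]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for (p, g), (m, v) in zip(self.net.iter_params(), self.state):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class BranchedNet:
    """Parallel per-signal branches feeding a fusion head.

    ``groups`` lists, per branch, the input-channel indices it consumes.
    The branch stage runs stacked over all branches; the fusion stage runs
    on the concatenated branch outputs (stack axis of size 1).
    """

    def __init__(self, branch: Sequential, fusion: Sequential, groups, dtype):
        self.branch = branch
        self.fusion = fusion
        self.groups = groups
        self.dtype = dtype
        self._pool = _BufferPool()

    def _split(self, x):
        # x: (B, T, C) -> (P, B, T, d)
        B, T, _ = x.shape
        P = len(self.groups)
        d = len(self.groups[0])
        out = self._pool.get("split", (P, B, T, d), self.dtype)
        for p, grp in enumerate(self.groups):
            out[p] = x[:, :, grp]
        return out

    def forward(self, x, training):
        z = self.branch.forward(self._split(x), training)
        return self.fusion.forward(z, training)[0]  # (B, n_classes)

    def backward(self, dlogits):
        dz = self.fusion.backward(dlogits[None])
        self.branch.backward(dz)

    def iter_params(self):
        yield from self.branch.iter_params()
        yield from self.fusion.iter_params()

    def n_params(self) -> int:
        return sum(p.size for p, _ in self.iter_params())

    def branch_n_params(self) -> int:
        return sum(p.size for p, _ in self.branch.iter_params())

    def iter_buffers(self):
        yield from self.branch.iter_buffers()
        yield from self.fusion.iter_buffers()

    def get_weights(self):
        """Trainable parameters followed by non-trainable state buffers."""
        return ([p.copy() for p, _ in self.iter_params()]
                + [b.copy() for b in self.iter_buffers()])

    def set_weights(self, weights):
        n_params = sum(1 for _ in self.iter_params())
        for (p, _), w in zip(self.iter_params(), weights[:n_params]):
            p[...] = w
        for b, w in zip(self.iter_buffers(), weights[n_params:]):
            b[...] = w
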