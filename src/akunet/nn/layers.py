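"""Layer modules: convolutions, batch norm, and the convolutional LSTM cell."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor

__all__ = ["Module", "Conv2D", "ConvTranspose2D", "BatchNorm2D", "ConvLSTMCell"]


class Module:
    """Minimal parameter container with named-state (de)serialisation."""

    def parameters(self):
        params = []
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def state_dict(self, prefix=""):
        state = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                state[key] = value.data
            elif isinstance(value, np.ndarray):  # running statistics
                state[key] = value
            elif isinstance(value, Module):
                state.update(value.state_dict(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        state.update(item.state_dict(f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        state[f"{key}.{i}"] = item.data
        return state

    def load_state_dict(self, state, prefix=""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                value.data = np.asarray(state[key], dtype=np.float32).reshape(value.data.shape)
            elif isinstance(value, np.ndarray):
                value[...] = np.asarray(state[key]).reshape(value.shape)
            elif isinstance(value, Module):
                value.load_state_dict(state, f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state_dict(state, f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        item.data = np.asarray(state[f"{key}.{i}"], dtype=np.float32).reshape(item.data.shape)


def _he_normal(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


def _glorot_uniform(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2D(Module):
    def __init__(self, cin, cout, k=3, rng=None):
        rng = rng or np.random.default_rng()
        self.w = Parameter(_he_normal(rng, (k, k, cin, cout), k * k * cin))
        self.b = Parameter(np.zeros(cout, dtype=np.float32))

    def __call__(self, x):
        return F.conv2d(x, self.w, self.b)


class ConvTranspose2D(Module):
    """Kernel-2 stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, cin, cout, rng=None):
        rng = rng or np.random.default_rng()
        self.w = Parameter(_glorot_uniform(rng, (cin, 2, 2, cout), cin, 4 * cout))
        self.b = Parameter(np.zeros(cout, dtype=np.float32))

    def __call__(self, x):
        return F.conv_transpose2d_2x2(x, self.w, self.b)


class BatchNorm2D(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x, training=False):
        return F.batch_norm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, training, self.momentum, self.eps)


class ConvLSTMCell(Module):
    """Convolutional LSTM with peephole connections.

    Gate pre-activations come from two convolutions (input-to-state and
    hidden-to-state) whose output channels stack the four gate paths
    [input, forget, candidate, output]; peephole weights act on the cell
    state elementwise (Hadamard), with the output gate reading the *new*
    cell state:

        i_t = sigma(Wxi * P_t + Whi * H_{t-1} + Wci . c_{t-1} + b_i)
        f_t = sigma(Wxf * P_t + Whf * H_{t-1} + Wcf . c_{t-1} + b_f)
        c_t = f_t . c_{t-1} + i_t . tanh(Wxc * P_t + Whc * H_{t-1} + b_c)
        o_t = sigma(Wxo * P_t + Who * H_{t-1} + Wco . c_t + b_o)
        H_t = o_t . tanh(c_t)

    ``spatial`` fixes the patch height/width the cell operates on, since
    peephole weights have the full shape of the state.
    """

    def __init__(self, cin, hidden, spatial, k=3, rng=None, forget_bias=1.0):
        rng = rng or np.random.default_rng()
        hp, wp = spatial
        self.hidden = hidden
        self.spatial = (hp, wp)
        self.wx = Parameter(_glorot_uniform(rng, (k, k, cin, 4 * hidden),
                                            k * k * cin, k * k * 4 * hidden))
        self.wh = Parameter(_glorot_uniform(rng, (k, k, hidden, 4 * hidden),
                                            k * k * hidden, k * k * 4 * hidden))
        self.wci = Parameter(np.zeros((hp, wp, hidden), dtype=np.float32))
        self.wcf = Parameter(np.zeros((hp, wp, hidden), dtype=np.float32))
        self.wco = Parameter(np.zeros((hp, wp, hidden), dtype=np.float32))
        bias = np.zeros(4 * hidden, dtype=np.float32)
        bias[hidden:2 * hidden] = forget_bias  # open forget gate at init
        self.b = Parameter(bias)

    def init_state(self, batch):
        hp, wp = self.spatial
        shape = (batch, hp, wp, self.hidden)
        return (Tensor(np.zeros(shape, dtype=np.float32)),
                Tensor(np.zeros(shape, dtype=np.float32)))

    def step(self, p: Tensor, state):
        h_prev, c_prev = state
        if p.data.shape[1:3] != self.spatial:
            raise ValueError(
                f"patch spatial shape {p.data.shape[1:3]} does not match "
                f"cell spatial shape {self.spatial}")
        k = self.hidden
        z = F.add(F.conv2d(p, self.wx, self.b), F.conv2d(h_prev, self.wh))
        zi = F.slice_channels(z, 0, k)
        zf = F.slice_channels(z, k, 2 * k)
        zg = F.slice_channels(z, 2 * k, 3 * k)
        zo = F.slice_channels(z, 3 * k, 4 * k)
        i = F.sigmoid(F.add(zi, F.mul(self.wci, c_prev)))
        f = F.sigmoid(F.add(zf, F.mul(self.wcf, c_prev)))
        g = F.tanh(zg)
        c = F.add(F.mul(f, c_prev), F.mul(i, g))
        o = F.sigmoid(F.add(zo, F.mul(self.wco, c)))
        h = F.mul(o, F.tanh(c))
        return h, c
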