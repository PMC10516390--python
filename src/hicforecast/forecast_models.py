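"""Forecasting networks assembled from the recurrent cells.

Four families:

* ``convlstm`` — a stack of ConvLSTM layers (variant 1/2/3) with a 1x1
  linear output projection; next-frame scheme.
* ``resconvlstm`` (and ``resconvgru``/``resconvmut``) — a 3x3 2D
  convolution lifting 1 -> hidden channels, a chain of residual blocks
  (each two recurrent cells with an additive skip: H_out = H_in + H^{i2}),
  and a 3x3 convolution reducing hidden -> 1; next-frame scheme.  The
  default depth of 25 blocks gives a 52-layer census (2 convs + 25 x 2
  cell layers).
* ``resconvlstm2`` — as above, but the output convolution consumes the
  channel concatenation of every ``concat_every``-th block's output.
* ``naivenet`` — the three-step-ahead 3D-convolutional baseline: three
  convolutions with 7x7 spatial and 1 temporal extent (implemented as a
  shared 2D convolution applied to each frame, which is exactly a 3D
  convolution with temporal kernel 1), the first two followed by group
  normalization (2 groups) and LeakyReLU (slope 0.2).
* ``stlstm`` — a stack of ST-LSTM layers with the zigzag spatiotemporal
  memory flow: M rises through the layers within a time-step and returns
  from the top layer to the bottom at the next time-step.

Output projections are linear; clamping to [0, 1] happens only at
genome reassembly time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import recurrent_cells as rc
from .autodiff import Tensor

__all__ = ["ModelConfig", "Forecaster", "build_network", "resblock_step", "persistence_forecast"]

ARCHITECTURES = (
    "convlstm",
    "resconvlstm",
    "resconvlstm2",
    "resconvgru",
    "resconvmut",
    "stlstm",
    "naivenet",
)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the benchmarked configurations: 4 layers for the
    ConvLSTM/ST-LSTM stacks, 25 blocks and hidden width 32 for the
    residual networks (128 elsewhere), 3x3 recurrent kernels, 7x7
    NaiveNet kernels, 50x50 windows.
    """

    architecture: str = "resconvlstm"
    n_layers: int = 4
    n_blocks: int = 25
    hidden_channels: int = 0  # 0 -> architecture default (32 residual, 128 other)
    kernel_size: int = 3
    convlstm_variant: int = 1
    concat_every: int = 5
    naive_kernel: int = 7
    window: int = 50
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}"
            )
        if min(self.n_layers, self.kernel_size, self.concat_every, self.window) < 1:
            raise ValueError("n_layers, kernel_size, concat_every and window must be positive")
        if self.n_blocks < 0:
            raise ValueError("n_blocks must be nonnegative")
        if self.hidden_channels == 0:
            default = 32 if self.architecture.startswith("res") else 128
            object.__setattr__(self, "hidden_channels", default)
        if self.hidden_channels < 1:
            raise ValueError("hidden_channels must be positive")

    @property
    def scheme(self) -> str:
        return "three_step" if self.architecture == "naivenet" else "next_frame"

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


def resblock_step(h_in, states, weights, step_fn=rc.convlstm_step):
    """One residual block: two recurrent cells plus an additive skip.

    Returns (H_out, [state1, state2]) with H_out = h_in + H of the second
    cell after feeding h_in through both cells.
    """
    s1 = step_fn(h_in, states[0], weights[0])
    s2 = step_fn(s1.H, states[1], weights[1])
    return ad.add(h_in, s2.H), [s1, s2]


class Forecaster:
    """Common surface: parameters(), init_state(), step()/forward3()."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self._params = []

    @property
    def scheme(self) -> str:
        return self.config.scheme

    def parameters(self):
        return list(self._params)

    def layer_census(self) -> int:
        raise NotImplementedError

    def init_state(self, batch: int):
        raise NotImplementedError

    def step(self, x: Tensor, state):
        raise NotImplementedError

    # checkpoint plumbing -------------------------------------------------
    def state_dict(self):
        return {f"p{i}": p.data for i, p in enumerate(self._params)}

    def load_state_dict(self, d):
        for i, p in enumerate(self._params):
            arr = np.asarray(d[f"p{i}"], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"checkpoint parameter p{i} has shape {arr.shape}, "
                                 f"model expects {p.data.shape}")
            p.data = arr

    def _conv_params(self, rng, out_ch, in_ch, k, dtype):
        fan_in = in_ch * k * k
        bound = 1.0 / np.sqrt(fan_in)
        w = Tensor(rng.uniform(-bound, bound, (out_ch, in_ch, k, k)).astype(dtype),
                   requires_grad=True)
        b = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)
        self._params.extend([w, b])
        return w, b


class _ConvLSTMStack(Forecaster):
    """n_layers ConvLSTM (or ST-LSTM) cells + 1x1 linear output projection."""

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        rng = np.random.default_rng(config.seed)
        dtype = config.np_dtype
        h, k = config.hidden_channels, config.kernel_size
        self.cells = []
        for l in range(config.n_layers):
            in_ch = 1 if l == 0 else h
            if config.architecture == "stlstm":
                w = rc.init_stlstm_weights(in_ch, h, k, rng=rng, dtype=dtype)
            else:
                w = rc.init_convlstm_weights(
                    in_ch, h, k, variant=config.convlstm_variant,
                    spatial=(config.window, config.window), rng=rng, dtype=dtype,
                )
            self.cells.append(w)
            self._params.extend(w.parameters())
        self.w_out, self.b_out = self._conv_params(rng, 1, h, 1, dtype)

    def layer_census(self) -> int:
        return len(self.cells) + 1

    def init_state(self, batch: int):
        sp = (self.config.window, self.config.window)
        states = [rc.zero_state(w, batch, sp) for w in self.cells]
        if self.config.architecture == "stlstm":
            # M entering the bottom layer at the next time-step (zigzag return)
            m_shape = (batch, *sp, self.config.hidden_channels)
            return {"layers": states,
                    "m_top": Tensor(np.zeros(m_shape, dtype=self.config.np_dtype))}
        return {"layers": states}

    def step(self, x: Tensor, state):
        layers = state["layers"]
        new_layers = []
        if self.config.architecture == "stlstm":
            m = state["m_top"]
            h = x
            for w, st in zip(self.cells, layers):
                new = rc.stlstm_step(h, rc.RecurrentState(H=st.H, C=st.C, M=m), w)
                m = new.M
                h = new.H
                new_layers.append(new)
            out = ad.conv2d(h, self.w_out, self.b_out)
            return out, {"layers": new_layers, "m_top": m}
        h = x
        for w, st in zip(self.cells, layers):
            new = rc.convlstm_step(h, st, w)
            h = new.H
            new_layers.append(new)
        out = ad.conv2d(h, self.w_out, self.b_out)
        return out, {"layers": new_layers}


_RES_CELLS = {
    "resconvlstm": ("convlstm", rc.convlstm_step),
    "resconvlstm2": ("convlstm", rc.convlstm_step),
    "resconvgru": ("convgru", rc.convgru_step),
    "resconvmut": ("convmut", rc.convmut_step),
}


class _ResidualNet(Forecaster):
    """conv_in -> residual recurrent blocks -> conv_out (optionally concat)."""

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        rng = np.random.default_rng(config.seed)
        dtype = config.np_dtype
        h, k = config.hidden_channels, config.kernel_size
        cell_family, self._step_fn = _RES_CELLS[config.architecture]
        self.w_in, self.b_in = self._conv_params(rng, h, 1, k, dtype)
        self.blocks = []
        for _ in range(config.n_blocks):
            pair = []
            for _ in range(2):
                if cell_family == "convlstm":
                    w = rc.init_convlstm_weights(
                        h, h, k, variant=config.convlstm_variant,
                        spatial=(config.window, config.window), rng=rng, dtype=dtype,
                    )
                elif cell_family == "convgru":
                    w = rc.init_convgru_weights(h, h, k, rng=rng, dtype=dtype)
                else:
                    w = rc.init_convmut_weights(h, h, k, rng=rng, dtype=dtype)
                pair.append(w)
                self._params.extend(w.parameters())
            self.blocks.append(pair)
        if config.architecture == "resconvlstm2":
            self._tap_indices = [
                i for i in range(config.concat_every, config.n_blocks + 1, config.concat_every)
            ]
            if not self._tap_indices:
                raise ValueError("resconvlstm2 needs n_blocks >= concat_every")
            out_in = h * len(self._tap_indices)
        else:
            self._tap_indices = None
            out_in = h
        self.w_out, self.b_out = self._conv_params(rng, 1, out_in, k, dtype)

    def layer_census(self) -> int:
        """Two 2D convolutions plus the two recurrent layers of every block."""
        return 2 + 2 * len(self.blocks)

    def init_state(self, batch: int):
        sp = (self.config.window, self.config.window)
        return {"blocks": [[rc.zero_state(w, batch, sp) for w in pair] for pair in self.blocks]}

    def step(self, x: Tensor, state):
        h = ad.conv2d(x, self.w_in, self.b_in)
        new_blocks = []
        taps = []
        for i, (pair, sts) in enumerate(zip(self.blocks, state["blocks"]), start=1):
            h, new = resblock_step(h, sts, pair, self._step_fn)
            new_blocks.append(new)
            if self._tap_indices and i in self._tap_indices:
                taps.append(h)
        feed = ad.concat(taps, axis=3) if self._tap_indices else h
        out = ad.conv2d(feed, self.w_out, self.b_out)
        return out, {"blocks": new_blocks}


class _NaiveNet(Forecaster):
    """Three-step-ahead 3D-conv baseline with temporal kernel 1.

    Because the temporal extent of every kernel is 1, the network maps
    each input frame to its output slice independently with shared
    weights; there is no temporal mixing.
    """

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        rng = np.random.default_rng(config.seed)
        dtype = config.np_dtype
        h, k = config.hidden_channels, config.naive_kernel
        if h % 2:
            raise ValueError("naivenet hidden_channels must be even (2 norm groups)")
        self.w1, self.b1 = self._conv_params(rng, h, 1, k, dtype)
        self.g1 = Tensor(np.ones(h, dtype=dtype), requires_grad=True)
        self.be1 = Tensor(np.zeros(h, dtype=dtype), requires_grad=True)
        self.w2, self.b2 = self._conv_params(rng, h, h, k, dtype)
        self.g2 = Tensor(np.ones(h, dtype=dtype), requires_grad=True)
        self.be2 = Tensor(np.zeros(h, dtype=dtype), requires_grad=True)
        self.w3, self.b3 = self._conv_params(rng, 1, h, k, dtype)
        self._params.extend([self.g1, self.be1, self.g2, self.be2])

    def layer_census(self) -> int:
        return 3

    def init_state(self, batch: int):
        return None

    def forward3(self, x: Tensor) -> Tensor:
        """(n, 3, 1, w, w) observed frames -> (n, 3, 1, w, w) future frames."""
        if x.data.ndim != 5 or x.data.shape[1] != 3 or x.data.shape[2] != 1:
            raise ValueError(f"naivenet expects (n, 3, 1, w, w) input, got {x.data.shape}")
        n, t = x.data.shape[0], x.data.shape[1]
        frames = []
        for j in range(t):
            f = ad.permute(_squeeze_time(ad.narrow(x, 1, j, 1)), (0, 2, 3, 1))
            h = ad.leaky_relu(
                ad.group_norm(ad.conv2d(f, self.w1, self.b1), 2, self.g1, self.be1), 0.2
            )
            h = ad.leaky_relu(
                ad.group_norm(ad.conv2d(h, self.w2, self.b2), 2, self.g2, self.be2), 0.2
            )
            out = ad.permute(ad.conv2d(h, self.w3, self.b3), (0, 3, 1, 2))
            frames.append(_unsqueeze_time(out))
        return ad.concat(frames, axis=1)


def _squeeze_time(t: Tensor) -> Tensor:
    data = t.data[:, 0]
    out = ad.Tensor(data)
    if t.requires_grad or t._backward is not None:
        out._parents = (t,)

        def backward(g):
            ad._accumulate(t, g[:, None])

        out._backward = backward
    return out


def _unsqueeze_time(t: Tensor) -> Tensor:
    data = t.data[:, None]
    out = ad.Tensor(data)
    if t.requires_grad or t._backward is not None:
        out._parents = (t,)

        def backward(g):
            ad._accumulate(t, g[:, 0])

        out._backward = backward
    return out


def build_network(config: ModelConfig) -> Forecaster:
    """Instantiate the architecture named in the config (seeded init)."""
    if config.architecture == "convlstm" or config.architecture == "stlstm":
        return _ConvLSTMStack(config)
    if config.architecture in _RES_CELLS:
        return _ResidualNet(config)
    if config.architecture == "naivenet":
        return _NaiveNet(config)
    raise ValueError(f"unknown architecture {config.architecture!r}")


def persistence_forecast(samples: np.ndarray, n_future: int = 3) -> np.ndarray:
    """Baseline: repeat the last observed frame for every future step."""
    last = samples[:, -1:]
    return np.repeat(last, n_future, axis=1)
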