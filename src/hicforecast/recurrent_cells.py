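"""Per-time-step recurrences: ConvLSTM variants, convolutional GRU/MUT1, ST-LSTM.

All cells operate on channels-last (N, H, W, C) grids with stride-1
same-padding convolutions, so the spatial extent (the 50x50 window by
default) is preserved through every layer.  Each step is a pure function
of (input, state, weights): no hidden mutation, bit-identical on repeat.
For speed, the input and hidden convolutions of all gates are fused into
a single convolution over the [X, H] channel concatenation (an exact
rewrite of the per-gate sums, since convolution is linear in channels).

ConvLSTM-1 is the classic formulation with Hadamard "peephole" couplings
of the gates to the cell memory:

    i_t = sigma(W_xi * X_t + W_hi * H_{t-1} + W_ci o C_{t-1} + b_i)
    f_t = sigma(W_xf * X_t + W_hf * H_{t-1} + W_cf o C_{t-1} + b_f)
    C_t = f_t o C_{t-1} + i_t o tanh(W_xc * X_t + W_hc * H_{t-1} + b_c)
    o_t = sigma(W_xo * X_t + W_ho * H_{t-1} + W_co o C_t + b_o)
    H_t = o_t o tanh(C_t)

ConvLSTM-2 drops the three peephole terms; ConvLSTM-3 replaces each
Hadamard peephole with a convolution.  The ST-LSTM cell adds a second,
spatiotemporal memory M that flows through layers within a time-step
(and from the top layer back to the bottom at the next step), with the
output gate reading both memories and a 1x1 convolution W_1 reducing the
[C, M] concatenation back to the hidden width.

Peephole Hadamard weights are full (H x W x channels) grids, matching
the elementwise product of the original formulation; they are therefore
tied to a fixed spatial shape chosen at initialization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "RecurrentState",
    "CellWeights",
    "init_convlstm_weights",
    "init_convgru_weights",
    "init_convmut_weights",
    "init_stlstm_weights",
    "convlstm1_step",
    "convlstm2_step",
    "convlstm3_step",
    "convgru_step",
    "convmut_step",
    "stlstm_step",
    "zero_state",
]


@dataclass
class RecurrentState:
    """Hidden grid H, cell memory C and (ST-LSTM only) spatiotemporal memory M."""

    H: Tensor
    C: Optional[Tensor] = None
    M: Optional[Tensor] = None


class CellWeights:
    """Named per-gate convolution kernels, Hadamard grids and biases.

    ``kind`` is one of convlstm1/convlstm2/convlstm3/convgru/convmut/stlstm.
    Parameters are autodiff tensors; per-gate kernels are fused with a
    channel concatenation at step time so one convolution serves all gates.
    """

    def __init__(self, kind, in_channels, hidden_channels, kernel_size, params):
        self.kind = kind
        self.in_channels = in_channels
        self.hidden_channels = hidden_channels
        self.kernel_size = kernel_size
        self.params = params  # dict name -> Tensor

    def __getitem__(self, name) -> Tensor:
        return self.params[name]

    def parameters(self):
        return list(self.params.values())

    def set_(self, name, value):
        """Overwrite one parameter array in place (shape-checked)."""
        p = self.params[name]
        value = np.asarray(value, dtype=p.data.dtype)
        if value.shape != p.data.shape:
            raise ValueError(f"{name}: shape {value.shape} != {p.data.shape}")
        p.data = value


def _kernel(rng, shape, dtype):
    fan_in = int(np.prod(shape[1:]))
    bound = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-bound, bound, size=shape).astype(dtype), requires_grad=True)


def _zeros(shape, dtype):
    return Tensor(np.zeros(shape, dtype=dtype), requires_grad=True)


def init_convlstm_weights(
    in_channels,
    hidden_channels,
    kernel_size=3,
    variant=1,
    spatial=(50, 50),
    rng=None,
    dtype=np.float32,
) -> CellWeights:
    """Weights for ConvLSTM-1/2/3 (variant selects the peephole treatment)."""
    if variant not in (1, 2, 3):
        raise ValueError("ConvLSTM variant must be 1, 2 or 3")
    rng = rng or np.random.default_rng(0)
    k, h, c = kernel_size, hidden_channels, in_channels
    p = {}
    for g in "ifco":
        p[f"W_x{g}"] = _kernel(rng, (h, c, k, k), dtype)
        p[f"W_h{g}"] = _kernel(rng, (h, h, k, k), dtype)
        p[f"b_{g}"] = _zeros((h,), dtype)
    if variant == 1:
        for g in ("ci", "cf", "co"):
            p[f"W_{g}"] = _zeros((*spatial, h), dtype)
    elif variant == 3:
        for g in ("ci", "cf", "co"):
            p[f"W_{g}"] = _kernel(rng, (h, h, k, k), dtype)
    return CellWeights(f"convlstm{variant}", c, h, k, p)


def init_convgru_weights(
    in_channels, hidden_channels, kernel_size=3, rng=None, dtype=np.float32
) -> CellWeights:
    rng = rng or np.random.default_rng(0)
    k, h, c = kernel_size, hidden_channels, in_channels
    p = {}
    for g in ("z", "r", "n"):
        p[f"W_x{g}"] = _kernel(rng, (h, c, k, k), dtype)
        p[f"W_h{g}"] = _kernel(rng, (h, h, k, k), dtype)
        p[f"b_{g}"] = _zeros((h,), dtype)
    return CellWeights("convgru", c, h, k, p)


def init_convmut_weights(
    in_channels, hidden_channels, kernel_size=3, rng=None, dtype=np.float32
) -> CellWeights:
    """MUT1-style cell (experimental convolutional adaptation).

    z depends on the input only; the candidate adds a tanh-squashed input
    projection to the reset-gated hidden convolution.
    """
    rng = rng or np.random.default_rng(0)
    k, h, c = kernel_size, hidden_channels, in_channels
    p = {
        "W_xz": _kernel(rng, (h, c, k, k), dtype),
        "b_z": _zeros((h,), dtype),
        "W_xr": _kernel(rng, (h, c, k, k), dtype),
        "W_hr": _kernel(rng, (h, h, k, k), dtype),
        "b_r": _zeros((h,), dtype),
        "W_xn": _kernel(rng, (h, c, k, k), dtype),
        "W_hn": _kernel(rng, (h, h, k, k), dtype),
        "b_n": _zeros((h,), dtype),
    }
    return CellWeights("convmut", c, h, k, p)


def init_stlstm_weights(
    in_channels, hidden_channels, kernel_size=3, rng=None, dtype=np.float32
) -> CellWeights:
    rng = rng or np.random.default_rng(0)
    k, h, c = kernel_size, hidden_channels, in_channels
    p = {}
    # temporal (C) branch + output gate input/hidden kernels
    for g in "ifco":
        p[f"W_x{g}"] = _kernel(rng, (h, c, k, k), dtype)
        p[f"W_h{g}"] = _kernel(rng, (h, h, k, k), dtype)
        p[f"b_{g}"] = _zeros((h,), dtype)
    # spatiotemporal (M) branch: primed gates
    p["W_xi_p"] = _kernel(rng, (h, c, k, k), dtype)
    p["W_mi"] = _kernel(rng, (h, h, k, k), dtype)
    p["b_i_p"] = _zeros((h,), dtype)
    p["W_xf_p"] = _kernel(rng, (h, c, k, k), dtype)
    p["W_mf"] = _kernel(rng, (h, h, k, k), dtype)
    p["b_f_p"] = _zeros((h,), dtype)
    p["W_xm"] = _kernel(rng, (h, c, k, k), dtype)
    p["W_mm"] = _kernel(rng, (h, h, k, k), dtype)
    p["b_m"] = _zeros((h,), dtype)
    # output gate reads both memories through convolutions
    p["W_co"] = _kernel(rng, (h, h, k, k), dtype)
    p["W_mo"] = _kernel(rng, (h, h, k, k), dtype)
    # 1x1 channel-reducing mix of [C, M]
    p["W_1"] = _kernel(rng, (h, 2 * h, 1, 1), dtype)
    return CellWeights("stlstm", c, h, k, p)


def zero_state(
    weights: CellWeights, batch: int, spatial, dtype=None, with_m: bool = False
) -> RecurrentState:
    """All-zero initial state matching a cell's hidden width."""
    dtype = dtype or weights.params[next(iter(weights.params))].data.dtype
    shape = (batch, *spatial, weights.hidden_channels)
    z = lambda: Tensor(np.zeros(shape, dtype=dtype))
    if weights.kind in ("convgru", "convmut"):
        return RecurrentState(H=z())
    return RecurrentState(H=z(), C=z(), M=z() if with_m or weights.kind == "stlstm" else None)


def _fused(w: CellWeights, prefix, gates):
    return ad.concat([w[f"W_{prefix}{g}"] for g in gates], axis=0)


def _fused_bias(w: CellWeights, gates, prefix="b_"):
    return ad.concat([w[f"{prefix}{g}"] for g in gates], axis=0)


def _split4(t, h):
    return [ad.narrow(t, 3, k * h, h) for k in range(4)]


def _check_cell_shapes(x: Tensor, state: RecurrentState, weights: CellWeights):
    if x.data.ndim != 4:
        raise ValueError(f"cell input must be (N, H, W, C), got shape {x.data.shape}")
    if x.data.shape[3] != weights.in_channels:
        raise ValueError(
            f"cell input has {x.data.shape[3]} channels, weights expect {weights.in_channels}"
        )
    if state.H.data.shape[3] != weights.hidden_channels:
        raise ValueError("hidden state channel count inconsistent with weights")
    if state.H.data.shape[1:3] != x.data.shape[1:3]:
        raise ValueError("hidden state and input spatial shapes differ")


def _convlstm_step(x, state, weights, variant) -> RecurrentState:
    _check_cell_shapes(x, state, weights)
    h = weights.hidden_channels
    gates = ad.conv2d(
        ad.concat([x, state.H], axis=3),
        ad.concat([_fused(weights, "x", "ifco"), _fused(weights, "h", "ifco")], axis=1),
        _fused_bias(weights, "ifco"),
    )
    if variant == 3:
        # convolutional peepholes on i/f enter the pre-activations; the
        # o-peephole reads C_t, so this variant stays on the primitive ops
        g_i, g_f, g_c, g_o = _split4(gates, h)
        g_i = ad.add(g_i, ad.conv2d(state.C, weights["W_ci"]))
        g_f = ad.add(g_f, ad.conv2d(state.C, weights["W_cf"]))
        i = ad.sigmoid(g_i)
        f = ad.sigmoid(g_f)
        c_new = ad.add(ad.mul(f, state.C), ad.mul(i, ad.tanh(g_c)))
        g_o = ad.add(g_o, ad.conv2d(c_new, weights["W_co"]))
        o = ad.sigmoid(g_o)
        return RecurrentState(H=ad.mul(o, ad.tanh(c_new)), C=c_new)
    peeps = (weights["W_ci"], weights["W_cf"], weights["W_co"]) if variant == 1 else (None,) * 3
    h_new, c_new = ad.lstm_cell(gates, state.C, *peeps)
    return RecurrentState(H=h_new, C=c_new)


def convlstm1_step(x: Tensor, state: RecurrentState, weights: CellWeights) -> RecurrentState:
    """ConvLSTM with Hadamard peephole couplings (the classic formulation)."""
    if weights.kind != "convlstm1":
        raise ValueError(f"expected convlstm1 weights, got {weights.kind}")
    return _convlstm_step(x, state, weights, 1)


def convlstm2_step(x: Tensor, state: RecurrentState, weights: CellWeights) -> RecurrentState:
    """ConvLSTM without peephole terms."""
    if weights.kind != "convlstm2":
        raise ValueError(f"expected convlstm2 weights, got {weights.kind}")
    return _convlstm_step(x, state, weights, 2)


def convlstm3_step(x: Tensor, state: RecurrentState, weights: CellWeights) -> RecurrentState:
    """ConvLSTM with the peephole Hadamard products replaced by convolutions."""
    if weights.kind != "convlstm3":
        raise ValueError(f"expected convlstm3 weights, got {weights.kind}")
    return _convlstm_step(x, state, weights, 3)


def convlstm_step(x, state, weights) -> RecurrentState:
    """Dispatch on the weight kind (convlstm1/2/3)."""
    variant = int(weights.kind[-1])
    return _convlstm_step(x, state, weights, variant)


def convgru_step(x: Tensor, state: RecurrentState, weights: CellWeights) -> RecurrentState:
    """Convolutional GRU: H_t = (1 - z) o H_{t-1} + z o candidate."""
    if weights.kind != "convgru":
        raise ValueError(f"expected convgru weights, got {weights.kind}")
    _check_cell_shapes(x, state, weights)
    h = weights.hidden_channels
    zr = ad.conv2d(
        ad.concat([x, state.H], axis=3),
        ad.concat([_fused(weights, "x", "zr"), _fused(weights, "h", "zr")], axis=1),
        _fused_bias(weights, "zr"),
    )
    z = ad.sigmoid(ad.narrow(zr, 3, 0, h))
    r = ad.sigmoid(ad.narrow(zr, 3, h, h))
    cand = ad.tanh(
        ad.add(
            ad.conv2d(x, weights["W_xn"], weights["b_n"]),
            ad.conv2d(ad.mul(r, state.H), weights["W_hn"]),
        )
    )
    h_new = ad.add(ad.mul(ad.sub(1.0, z), state.H), ad.mul(z, cand))
    return RecurrentState(H=h_new)


def convmut_step(x: Tensor, state: RecurrentState, weights: CellWeights) -> RecurrentState:
    """Convolutional MUT1 (experimental): input-only update gate."""
    if weights.kind != "convmut":
        raise ValueError(f"expected convmut weights, got {weights.kind}")
    _check_cell_shapes(x, state, weights)
    z = ad.sigmoid(ad.conv2d(x, weights["W_xz"], weights["b_z"]))
    r = ad.sigmoid(
        ad.add(
            ad.conv2d(x, weights["W_xr"], weights["b_r"]),
            ad.conv2d(state.H, weights["W_hr"]),
        )
    )
    cand = ad.tanh(
        ad.add(
            ad.conv2d(ad.mul(r, state.H), weights["W_hn"], weights["b_n"]),
            ad.tanh(ad.conv2d(x, weights["W_xn"])),
        )
    )
    h_new = ad.add(ad.mul(z, cand), ad.mul(ad.sub(1.0, z), state.H))
    return RecurrentState(H=h_new)


def stlstm_step(x: Tensor, state: RecurrentState, weights: CellWeights) -> RecurrentState:
    """ST-LSTM step; ``state.M`` carries the incoming spatiotemporal memory.

    For layer l at time t, state.H/state.C are this layer's previous-time
    states while state.M is M from layer l-1 at time t (or, for the bottom
    layer, the top layer's M from time t-1).
    """
    if weights.kind != "stlstm":
        raise ValueError(f"expected stlstm weights, got {weights.kind}")
    if state.M is None:
        raise ValueError("stlstm_step requires the incoming spatiotemporal memory M")
    _check_cell_shapes(x, state, weights)
    h = weights.hidden_channels

    gx = ad.conv2d(
        x,
        ad.concat(
            [weights["W_xi"], weights["W_xf"], weights["W_xc"],
             weights["W_xi_p"], weights["W_xf_p"], weights["W_xm"], weights["W_xo"]],
            axis=0,
        ),
        ad.concat(
            [weights["b_i"], weights["b_f"], weights["b_c"],
             weights["b_i_p"], weights["b_f_p"], weights["b_m"], weights["b_o"]],
            axis=0,
        ),
    )
    gh = ad.conv2d(
        state.H,
        ad.concat([weights["W_hi"], weights["W_hf"], weights["W_hc"], weights["W_ho"]], axis=0),
    )
    gm = ad.conv2d(
        state.M,
        ad.concat([weights["W_mi"], weights["W_mf"], weights["W_mm"]], axis=0),
    )
    gx_i, gx_f, gx_c, gx_ip, gx_fp, gx_m, gx_o = (
        ad.narrow(gx, 3, k * h, h) for k in range(7)
    )
    gh_i, gh_f, gh_c, gh_o = _split4(gh, h)
    gm_i, gm_f, gm_m = (ad.narrow(gm, 3, k * h, h) for k in range(3))

    i = ad.sigmoid(ad.add(gx_i, gh_i))
    f = ad.sigmoid(ad.add(gx_f, gh_f))
    c_new = ad.add(ad.mul(f, state.C), ad.mul(i, ad.tanh(ad.add(gx_c, gh_c))))

    i_p = ad.sigmoid(ad.add(gx_ip, gm_i))
    f_p = ad.sigmoid(ad.add(gx_fp, gm_f))
    m_new = ad.add(ad.mul(f_p, state.M), ad.mul(i_p, ad.tanh(ad.add(gx_m, gm_m))))

    o = ad.sigmoid(
        ad.add(
            ad.add(ad.add(gx_o, gh_o), ad.conv2d(c_new, weights["W_co"])),
            ad.conv2d(m_new, weights["W_mo"]),
        )
    )
    mixed = ad.conv2d(ad.concat([c_new, m_new], axis=3), weights["W_1"])
    return RecurrentState(H=ad.mul(o, ad.tanh(mixed)), C=c_new, M=m_new)


STEP_FUNCTIONS = {
    "convlstm1": convlstm1_step,
    "convlstm2": convlstm2_step,
    "convlstm3": convlstm3_step,
    "convgru": convgru_step,
    "convmut": convmut_step,
    "stlstm": stlstm_step,
}
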