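"""Cell recurrences against hand-derived fixed points and scalar oracles.

The scalar oracles re-derive each recurrence with plain floats on a 1x1
grid with 1x1 kernels, where every convolution collapses to a scalar
multiplication, giving an implementation-independent check of the gate
equations.
"""

import math

import numpy as np
import pytest

from hicforecast import autodiff as ad
from hicforecast import recurrent_cells as rc


def _zero_weights(weights):
    for name in weights.params:
        weights.set_(name, np.zeros_like(weights.params[name].data))
    return weights


def _scalar_state(weights, h0=0.0, c0=0.0, m0=None):
    st = rc.zero_state(weights, 1, (1, 1), dtype=np.float64)
    st.H.data[:] = h0
    if st.C is not None:
        st.C.data[:] = c0
    if m0 is not None:
        st.M = ad.Tensor(np.full((1, 1, 1, 1), m0))
    return st


def _x(value, dtype=np.float64):
    return ad.Tensor(np.full((1, 1, 1, 1), value, dtype=dtype))


def _sig(v):
    return 1.0 / (1.0 + math.exp(-v))


def scalar_lstm_peephole(x, h, c, w):
    """Plain-float LSTM with Hadamard peepholes (independent oracle)."""
    i = _sig(w["xi"] * x + w["hi"] * h + w["ci"] * c + w["bi"])
    f = _sig(w["xf"] * x + w["hf"] * h + w["cf"] * c + w["bf"])
    c_new = f * c + i * math.tanh(w["xc"] * x + w["hc"] * h + w["bc"])
    o = _sig(w["xo"] * x + w["ho"] * h + w["co"] * c_new + w["bo"])
    return o * math.tanh(c_new), c_new


def scalar_gru(x, h, w):
    """Plain-float GRU; H' = (1 - z) * H + z * candidate."""
    z = _sig(w["xz"] * x + w["hz"] * h + w["bz"])
    r = _sig(w["xr"] * x + w["hr"] * h + w["br"])
    n = math.tanh(w["xn"] * x + w["hn"] * (r * h) + w["bn"])
    return (1 - z) * h + z * n


class TestZeroWeightFixedPoints:
    """With all weights and states zero: gates 0.5, tanh(0) = 0, outputs 0."""

    @pytest.mark.parametrize("variant", [1, 2, 3])
    def test_convlstm_zero_fixed_point(self, variant, rng):
        w = _zero_weights(rc.init_convlstm_weights(1, 4, 3, variant, spatial=(6, 6)))
        st = rc.zero_state(w, 2, (6, 6))
        x = ad.Tensor(rng.normal(size=(2, 6, 6, 1)).astype(np.float32))
        step = rc.STEP_FUNCTIONS[f"convlstm{variant}"]
        new = step(x, st, w)
        assert np.array_equal(new.C.data, np.zeros_like(new.C.data))
        assert np.array_equal(new.H.data, np.zeros_like(new.H.data))

    def test_convgru_zero_fixed_point(self, rng):
        w = _zero_weights(rc.init_convgru_weights(1, 4, 3))
        st = rc.zero_state(w, 2, (6, 6))
        new = rc.convgru_step(ad.Tensor(rng.normal(size=(2, 6, 6, 1))), st, w)
        assert np.array_equal(new.H.data, np.zeros_like(new.H.data))

    def test_stlstm_zero_fixed_point(self, rng):
        w = _zero_weights(rc.init_stlstm_weights(1, 4, 3))
        st = rc.zero_state(w, 2, (6, 6))
        new = rc.stlstm_step(ad.Tensor(rng.normal(size=(2, 6, 6, 1))), st, w)
        for grid in (new.H, new.C, new.M):
            assert np.array_equal(grid.data, np.zeros_like(grid.data))

    def test_gate_value_is_half_at_zero_preactivation(self):
        # the sigma(0) = 0.5 part of the fixed-point derivation, via C_t:
        # with b_c-only weights, C_t = 0.5 * tanh(b_c)
        w = _zero_weights(rc.init_convlstm_weights(1, 1, 1, 2))
        w.set_("b_c", np.array([2.0]))
        st = rc.zero_state(w, 1, (1, 1), dtype=np.float64)
        new = rc.convlstm2_step(_x(0.0), st, w)
        assert new.C.data.item() == pytest.approx(0.5 * math.tanh(2.0), abs=1e-12)


class TestScalarOracles:
    def _random_scalar_weights(self, rng, names):
        return {n: float(rng.normal()) for n in names}

    def test_convlstm1_matches_scalar_lstm_with_peepholes(self, rng):
        names = "xi hi ci bi xf hf cf bf xc hc bc xo ho co bo".split()
        for trial in range(5):
            w = self._random_scalar_weights(rng, names)
            cell = rc.init_convlstm_weights(1, 1, 1, 1, spatial=(1, 1),
                                            dtype=np.float64)
            for g in "ifco":
                cell.set_(f"W_x{g}", np.array(w[f"x{g}"]).reshape(1, 1, 1, 1))
                cell.set_(f"W_h{g}", np.array(w[f"h{g}"]).reshape(1, 1, 1, 1))
                cell.set_(f"b_{g}", np.array([w[f"b{g}"]]))
            for g in ("ci", "cf", "co"):
                cell.set_(f"W_{g}", np.array(w[g]).reshape(1, 1, 1))
            x, h0, c0 = rng.normal(size=3)
            new = rc.convlstm1_step(_x(x), _scalar_state(cell, h0, c0), cell)
            h_ref, c_ref = scalar_lstm_peephole(x, h0, c0, w)
            assert new.H.data.item() == pytest.approx(h_ref, abs=1e-6)
            assert new.C.data.item() == pytest.approx(c_ref, abs=1e-6)

    def test_convlstm2_equals_convlstm1_with_zero_peepholes(self, rng):
        w1 = rc.init_convlstm_weights(1, 3, 3, 1, spatial=(5, 5),
                                      rng=np.random.default_rng(5))
        w2 = rc.init_convlstm_weights(1, 3, 3, 2, rng=np.random.default_rng(5))
        # same rng seed gives identical gate kernels; peepholes of w1 are zero
        x = ad.Tensor(rng.normal(size=(2, 5, 5, 1)).astype(np.float32))
        st1 = rc.zero_state(w1, 2, (5, 5))
        st2 = rc.zero_state(w2, 2, (5, 5))
        a = rc.convlstm1_step(x, st1, w1)
        b = rc.convlstm2_step(x, st2, w2)
        assert np.array_equal(a.H.data, b.H.data)
        assert np.array_equal(a.C.data, b.C.data)

    def test_convlstm3_with_identity_peephole_kernels_matches_convlstm1(self, rng):
        """A 1x1 conv peephole with scalar kernel equals the Hadamard product."""
        scal = {g: float(rng.normal()) for g in ("ci", "cf", "co")}
        w1 = rc.init_convlstm_weights(1, 1, 1, 1, spatial=(4, 4),
                                      rng=np.random.default_rng(8), dtype=np.float64)
        w3 = rc.init_convlstm_weights(1, 1, 1, 3,
                                      rng=np.random.default_rng(8), dtype=np.float64)
        for g, v in scal.items():
            w1.set_(f"W_{g}", np.full((4, 4, 1), v))
            w3.set_(f"W_{g}", np.array(v).reshape(1, 1, 1, 1))
        x = ad.Tensor(rng.normal(size=(2, 4, 4, 1)))
        st1 = rc.zero_state(w1, 2, (4, 4))
        st3 = rc.zero_state(w3, 2, (4, 4))
        st1.C.data[:] = st3.C.data[:] = rng.normal(size=(2, 4, 4, 1))
        a = rc.convlstm1_step(x, st1, w1)
        b = rc.convlstm3_step(x, st3, w3)
        assert np.allclose(a.H.data, b.H.data, atol=1e-12)

    def test_convgru_matches_scalar_gru(self, rng):
        names = "xz hz bz xr hr br xn hn bn".split()
        for trial in range(5):
            w = self._random_scalar_weights(rng, names)
            cell = rc.init_convgru_weights(1, 1, 1, dtype=np.float64)
            for g in ("z", "r", "n"):
                cell.set_(f"W_x{g}", np.array(w[f"x{g}"]).reshape(1, 1, 1, 1))
                cell.set_(f"W_h{g}", np.array(w[f"h{g}"]).reshape(1, 1, 1, 1))
                cell.set_(f"b_{g}", np.array([w[f"b{g}"]]))
            x, h0 = rng.normal(size=2)
            new = rc.convgru_step(_x(x), _scalar_state(cell, h0), cell)
            assert new.H.data.item() == pytest.approx(scalar_gru(x, h0, w), abs=1e-6)

    def test_gru_update_gate_saturated_off_preserves_hidden(self):
        w = _zero_weights(rc.init_convgru_weights(1, 1, 1, dtype=np.float64))
        w.set_("b_z", np.array([-20.0]))  # z ~ 0 -> H_t ~ H_{t-1}
        st = _scalar_state(w, h0=0.73)
        new = rc.convgru_step(_x(5.0), st, w)
        assert new.H.data.item() == pytest.approx(0.73, abs=1e-6)

    def test_forget_bias_saturation_carries_memory(self):
        w = _zero_weights(rc.init_convlstm_weights(1, 1, 1, 1, spatial=(1, 1),
                                                   dtype=np.float64))
        w.set_("b_f", np.array([20.0]))  # f ~ 1
        st = _scalar_state(w, h0=0.0, c0=0.42)
        new = rc.convlstm1_step(_x(3.0), st, w)
        assert abs(new.C.data.item() - 0.42) < 1e-6


class TestSTLSTM:
    def test_missing_memory_is_structural_error(self, rng):
        w = rc.init_stlstm_weights(1, 2, 3)
        st = rc.zero_state(w, 1, (4, 4))
        st.M = None
        with pytest.raises(ValueError, match="M"):
            rc.stlstm_step(ad.Tensor(rng.normal(size=(1, 4, 4, 1))), st, w)

    def test_reduces_to_peephole_free_convlstm_when_m_branch_silenced(self, rng):
        """W_m* = 0 and W_1 selecting the C half make ST-LSTM a ConvLSTM-2."""
        seed_rng = np.random.default_rng(3)
        w = rc.init_stlstm_weights(1, 2, 3, rng=seed_rng, dtype=np.float64)
        ref = rc.init_convlstm_weights(1, 2, 3, 2, dtype=np.float64)
        for g in "ifc":
            ref.set_(f"W_x{g}", w[f"W_x{g}"].data)
            ref.set_(f"W_h{g}", w[f"W_h{g}"].data)
            ref.set_(f"b_{g}", w[f"b_{g}"].data)
        ref.set_("W_xo", w["W_xo"].data)
        ref.set_("W_ho", w["W_ho"].data)
        ref.set_("b_o", w["b_o"].data)
        # silence every M pathway and the o-gate C convolution
        for name in ("W_mi", "W_mf", "W_mm", "W_xi_p", "W_xf_p", "W_xm",
                     "b_i_p", "b_f_p", "b_m", "W_co", "W_mo"):
            w.set_(name, np.zeros_like(w[name].data))
        # W_1 = [I, 0]: H_t = o * tanh(C_t)
        w1 = np.zeros((2, 4, 1, 1))
        w1[0, 0, 0, 0] = w1[1, 1, 0, 0] = 1.0
        w.set_("W_1", w1)
        x = ad.Tensor(rng.normal(size=(2, 5, 5, 1)))
        st = rc.zero_state(w, 2, (5, 5), dtype=np.float64)
        st.C.data[:] = rng.normal(size=st.C.data.shape)
        st.H.data[:] = rng.normal(size=st.H.data.shape)
        ref_st = rc.RecurrentState(H=ad.Tensor(st.H.data.copy()),
                                   C=ad.Tensor(st.C.data.copy()))
        a = rc.stlstm_step(x, st, w)
        b = rc.convlstm2_step(x, ref_st, ref)
        assert np.allclose(a.H.data, b.H.data, atol=1e-6)
        assert np.allclose(a.C.data, b.C.data, atol=1e-6)

    def test_output_channel_count_despite_concatenation(self, rng):
        w = rc.init_stlstm_weights(1, 4, 3)
        st = rc.zero_state(w, 2, (6, 6))
        new = rc.stlstm_step(ad.Tensor(rng.normal(size=(2, 6, 6, 1)).astype(np.float32)),
                             st, w)
        assert new.H.data.shape == (2, 6, 6, 4)


class TestCellProperties:
    def test_bounded_memory_update_and_purity(self, rng):
        """|C_t| <= |C_{t-1}| + 1 elementwise, and repeat calls are identical."""
        w = rc.init_convlstm_weights(2, 3, 3, 1, spatial=(6, 6),
                                     rng=np.random.default_rng(11))
        st = rc.zero_state(w, 2, (6, 6))
        st.C.data[:] = rng.normal(size=st.C.data.shape).astype(np.float32)
        x = ad.Tensor(rng.normal(size=(2, 6, 6, 2)).astype(np.float32))
        a = rc.convlstm1_step(x, st, w)
        b = rc.convlstm1_step(x, st, w)
        assert np.array_equal(a.H.data, b.H.data)
        assert np.array_equal(a.C.data, b.C.data)
        assert (np.abs(a.C.data) <= np.abs(st.C.data) + 1.0 + 1e-6).all()

    def test_spatial_shape_preserved_for_odd_kernels(self, rng):
        for k in (1, 3, 5):
            w = rc.init_convlstm_weights(1, 2, k, 2)
            st = rc.zero_state(w, 1, (9, 9))
            new = rc.convlstm2_step(ad.Tensor(rng.normal(size=(1, 9, 9, 1)).astype(np.float32)), st, w)
            assert new.H.data.shape == (1, 9, 9, 2)

    def test_shape_mismatch_raises(self, rng):
        w = rc.init_convlstm_weights(1, 2, 3, 2)
        st = rc.zero_state(w, 1, (6, 6))
        with pytest.raises(ValueError, match="channels"):
            rc.convlstm2_step(ad.Tensor(rng.normal(size=(1, 6, 6, 3))), st, w)
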