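"""Rollout semantics, loss definitions, training loop and genome prediction."""

from types import SimpleNamespace

import numpy as np
import pytest

from hicforecast import autodiff as ad
from hicforecast import recurrent_cells as rc
from hicforecast.engine import (
    TrainConfig,
    evaluate_loss,
    load_checkpoint,
    loss_next_frame,
    loss_three_step,
    predict_genome,
    rollout_next_frame,
    save_checkpoint,
    train,
)
from hicforecast.forecast_models import ModelConfig, build_network
from hicforecast.hic_io import ContactMatrix, SpatioTemporalStack
from hicforecast.windowing import SampleTensor, coverage_count, extract_windows


class _ConstantModel:
    """Stub next-frame model emitting a fixed function of its input."""

    scheme = "next_frame"
    config = SimpleNamespace(np_dtype=np.dtype("float32"))

    def __init__(self, fn):
        self._fn = fn

    def init_state(self, batch):
        return None

    def step(self, x, state):
        return self._fn(x), state


def _samples(rng, n=4, t=6, w=8):
    data = rng.random((n, t, 1, w, w)).astype(np.float32)
    data = 0.5 * (data + data.transpose(0, 1, 2, 4, 3))
    return data


class TestRollout:
    def test_identity_model_is_persistence(self, rng):
        x = _samples(rng)
        result = rollout_next_frame(_ConstantModel(lambda t: t), x[:, :3])
        preds = result.predictions_array()
        for k in range(3):  # X3 repeated for t4..t6
            assert np.array_equal(preds[:, k], x[:, 2])
        # reconstructions of steps 2 and 3 echo the true frames 1 and 2
        assert np.array_equal(result.reconstructions[0].data[..., 0],
                              x[:, 0, 0])

    def test_zero_model_predicts_zero(self, rng):
        x = _samples(rng)
        result = rollout_next_frame(_ConstantModel(lambda t: ad.mul(t, 0.0)), x[:, :3])
        assert np.abs(result.predictions_array()).max() == 0

    def test_matches_hand_unrolled_cell_loop(self, rng):
        """Rollout equals an explicit per-step loop over the same cells."""
        model = build_network(ModelConfig(architecture="convlstm", n_layers=2,
                                          hidden_channels=2, window=8, seed=5))
        x = _samples(rng, n=3, w=8)
        result = rollout_next_frame(model, x[:, :3])

        states = [rc.zero_state(w, 3, (8, 8)) for w in model.cells]
        outs = []
        current = ad.Tensor(np.ascontiguousarray(x[:, 0].transpose(0, 2, 3, 1)))
        for t in range(1, 6):
            h = current
            for li, w in enumerate(model.cells):
                states[li] = rc.convlstm1_step(h, states[li], w)
                h = states[li].H
            out = ad.conv2d(h, model.w_out, model.b_out)
            outs.append(out)
            if t < 3:
                current = ad.Tensor(np.ascontiguousarray(x[:, t].transpose(0, 2, 3, 1)))
            else:
                current = out
        for a, b in zip(result.reconstructions, outs):
            assert np.array_equal(a.data, b.data)

    def test_scheme_mismatch_rejected(self, rng):
        model = build_network(ModelConfig(architecture="naivenet", hidden_channels=2,
                                          naive_kernel=3, window=8))
        with pytest.raises(ValueError, match="next-frame"):
            rollout_next_frame(model, _samples(rng)[:, :3])

    def test_rollout_blind_to_future_frames(self, rng):
        """Predictions depend only on frames t1..t3 (the blindness contract)."""
        model = build_network(ModelConfig(architecture="resconvlstm", n_blocks=1,
                                          hidden_channels=2, window=8, seed=2))
        x = _samples(rng)
        y = x.copy()
        y[:, 3:] += rng.random(y[:, 3:].shape).astype(np.float32)
        a = rollout_next_frame(model, x[:, :3]).predictions_array()
        b = rollout_next_frame(model, y[:, :3]).predictions_array()
        assert np.array_equal(a, b)


class TestLosses:
    def test_perfect_reconstruction_is_zero(self, rng):
        x = _samples(rng)
        result = rollout_next_frame(_ConstantModel(lambda t: t), x[:, :3])
        truth = x.copy()
        truth[:, 1:3] = x[:, 0:2]  # identity echoes the previous frame
        truth[:, 3:] = x[:, 2:3]
        assert float(loss_next_frame(result, truth[:, 1:]).data) == 0.0

    def test_constant_offset_gives_squared_delta(self, rng):
        x = _samples(rng)
        delta = 0.25
        result = rollout_next_frame(_ConstantModel(lambda t: t), x[:, :3])
        truth = np.stack([r.data[..., 0] for r in result.reconstructions], axis=1)
        truth = truth[:, :, None] + delta
        assert float(loss_next_frame(result, truth).data) == pytest.approx(
            delta**2, rel=1e-5
        )

    def test_next_frame_loss_matches_bruteforce_mse(self, rng):
        x = _samples(rng)
        model = build_network(ModelConfig(architecture="convlstm", n_layers=1,
                                          hidden_channels=2, window=8, seed=1))
        result = rollout_next_frame(model, x[:, :3])
        loss = float(loss_next_frame(result, x[:, 1:]).data)
        recon = np.stack([r.data[..., 0] for r in result.reconstructions], axis=1)
        brute = np.mean((recon[:, :, None] - x[:, 1:]) ** 2)
        assert loss == pytest.approx(brute, rel=1e-6)

    def test_three_step_loss_matches_bruteforce_mse(self, rng):
        pred = rng.random((4, 3, 1, 8, 8))
        truth = rng.random((4, 3, 1, 8, 8))
        assert float(loss_three_step(pred, truth).data) == pytest.approx(
            np.mean((pred - truth) ** 2)
        )
        assert float(loss_three_step(truth, truth).data) == 0.0

    def test_losses_live_on_different_supports(self, rng):
        """Next-frame pools steps 2..6; three-step pools 4..6 — the two
        training objectives are not comparable and no ordering is assumed."""
        x = _samples(rng)
        result = rollout_next_frame(_ConstantModel(lambda t: t), x[:, :3])
        nf = loss_next_frame(result, x[:, 1:])
        ts = loss_three_step(x[:, 3:], x[:, 3:])
        assert np.isfinite(nf.data) and float(ts.data) == 0.0
        with pytest.raises(ValueError):
            loss_next_frame(result, x[:, 3:])  # wrong support is an error


class TestTrain:
    def _tensor(self, rng, n_bins=30, w=10):
        mats = []
        for _ in range(6):
            v = rng.random((n_bins, n_bins))
            mats.append(ContactMatrix("chrT", 40000, 0.5 * (v + v.T)))
        return extract_windows(SpatioTemporalStack(mats), window=w, step=5)

    def _model(self, seed=0):
        return build_network(ModelConfig(architecture="resconvlstm", n_blocks=1,
                                         hidden_channels=2, window=10, seed=seed))

    def test_zero_learning_rate_freezes_loss(self, rng):
        tensor = self._tensor(rng)
        res = train(self._model(), tensor,
                    TrainConfig(epochs=3, learning_rate=0.0, seed=0))
        # constant up to summation order (shuffling permutes the batch)
        assert np.allclose(res.history["train"], res.history["train"][0],
                           rtol=1e-6)

    def test_seeded_history_is_reproducible(self, rng):
        tensor = self._tensor(rng)
        r1 = train(self._model(3), tensor, TrainConfig(epochs=3, seed=9, batch_size=2))
        r2 = train(self._model(3), tensor, TrainConfig(epochs=3, seed=9, batch_size=2))
        assert r1.history["train"] == r2.history["train"]

    def test_best_validation_checkpoint_retained(self, rng):
        tensor = self._tensor(rng)
        val = self._tensor(np.random.default_rng(77))
        cfg = TrainConfig(epochs=4, learning_rate=3e-3, seed=1, batch_size=4)
        res = train(self._model(1), tensor, cfg, validation=val)
        assert res.best_epoch == int(np.argmin(res.history["val"]))
        # the retained weights reproduce the best validation loss
        reval = evaluate_loss(res.model, val, cfg)
        assert reval == pytest.approx(res.history["val"][res.best_epoch], abs=1e-6)

    def test_checkpoint_roundtrip_reproduces_loss(self, rng, tmp_path):
        tensor = self._tensor(rng)
        cfg = TrainConfig(epochs=2, seed=0, batch_size=4)
        res = train(self._model(2), tensor, cfg)
        path = tmp_path / "model.npz"
        save_checkpoint(res.model, path)
        back = load_checkpoint(path)
        assert back.config == res.model.config
        assert evaluate_loss(back, tensor, cfg) == pytest.approx(
            evaluate_loss(res.model, tensor, cfg), abs=1e-7
        )

    def test_too_few_time_steps_rejected(self, rng):
        tensor = self._tensor(rng)
        short = SampleTensor(tensor.data[:, :3], tensor.offsets, tensor.window,
                             tensor.step, tensor.n_bins)
        with pytest.raises(ValueError, match="time-steps"):
            train(self._model(), short, TrainConfig(epochs=1))

    def test_non_finite_loss_aborts_with_diagnostics(self, rng):
        tensor = self._tensor(rng)
        model = self._model()
        bad = _ConstantModel(lambda t: ad.mul(t, np.float32(np.inf)))
        bad.config = model.config
        bad.parameters = model.parameters
        with pytest.raises(RuntimeError, match="non-finite"):
            train(bad, tensor, TrainConfig(epochs=1))

    def test_three_step_scheme_trains_naivenet(self, rng):
        tensor = self._tensor(rng)
        model = build_network(ModelConfig(architecture="naivenet", hidden_channels=2,
                                          naive_kernel=3, window=10, seed=0))
        res = train(model, tensor,
                    TrainConfig(scheme="three_step", epochs=2, learning_rate=1e-2,
                                seed=0, batch_size=4))
        assert res.history["train"][-1] < res.history["train"][0]

    def test_stlstm_decouple_regularizer_runs(self, rng):
        tensor = self._tensor(rng)
        model = build_network(ModelConfig(architecture="stlstm", n_layers=2,
                                          hidden_channels=2, window=10, seed=0))
        res = train(model, tensor,
                    TrainConfig(epochs=1, seed=0, batch_size=4, decouple_weight=0.1))
        assert np.isfinite(res.history["train"][0])


class TestPredictGenome:
    def test_identity_model_gives_persistence_band(self, rng):
        mats = []
        for _ in range(3):
            v = rng.random((30, 30))
            mats.append(ContactMatrix("chrP", 40000, 0.5 * (v + v.T)))
        stack = SpatioTemporalStack(mats)
        preds = predict_genome(_ConstantModel(lambda t: t), stack, window=10, step=4)
        cov = coverage_count(30, 10, 4) > 0
        for m in preds:
            assert np.allclose(m.values[cov], stack[2].values[cov], atol=1e-7)
            assert np.isnan(m.values[~cov]).all()

    def test_outputs_symmetric_and_in_unit_range(self, rng):
        model = build_network(ModelConfig(architecture="resconvlstm", n_blocks=1,
                                          hidden_channels=2, window=10, seed=6))
        mats = []
        for _ in range(3):
            v = rng.random((30, 30))
            mats.append(ContactMatrix("chrP", 40000, 0.5 * (v + v.T)))
        preds = predict_genome(model, SpatioTemporalStack(mats), window=10, step=4)
        for m in preds:
            vals = np.nan_to_num(m.values)
            assert np.allclose(vals, vals.T, atol=1e-9)
            assert (vals >= 0).all() and (vals <= 1).all()
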