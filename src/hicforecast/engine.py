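"""Training, autoregressive rollout and genome-scale prediction.

Two supervision schemes mirror the two model families:

* next-frame — the network reconstructs each frame from its predecessor;
  the first three frames are fed from the data, from the fourth step on
  the model's own output is fed back (autoregressive rollout), and the
  MSE loss pools the reconstructions of steps 2..6 against the truth.
* three-step — a single forward pass maps the three observed frames to
  the three future frames; the MSE loss covers only steps 4..6.

Optimization is Adam (lr 1e-4, batch 32 by default) with global-norm
gradient clipping; the checkpoint with the best validation loss is the
one retained.  All randomness (shuffling, initialization) is seeded, so
single-threaded runs are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .forecast_models import Forecaster, ModelConfig, build_network
from .hic_io import SpatioTemporalStack
from .windowing import SampleTensor, extract_windows, reassemble

__all__ = [
    "TrainConfig",
    "RolloutResult",
    "TrainResult",
    "rollout_next_frame",
    "loss_next_frame",
    "loss_three_step",
    "train",
    "predict_genome",
    "save_checkpoint",
    "load_checkpoint",
]

N_INPUT_STEPS = 3


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults: Adam, lr 1e-4, batch 32, MSE)."""

    scheme: str = "next_frame"
    batch_size: int = 32
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    loss: str = "mse"
    epochs: int = 30
    seed: int = 0
    clip_norm: float = 1.0
    decouple_weight: float = 0.0  # optional ST-LSTM memory-decoupling penalty

    def __post_init__(self):
        if self.scheme not in ("next_frame", "three_step"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be nonnegative")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")
        if self.optimizer != "adam" or self.loss != "mse":
            raise ValueError("supported: optimizer 'adam', loss 'mse'")


@dataclass
class RolloutResult:
    """Reconstructions of frames 2..T; the last three are the forecasts."""

    reconstructions: list  # Tensors, one per reconstructed frame (steps 2..T)
    states: list = field(default_factory=list)

    @property
    def predictions(self):
        """Forecast frames t4..t6 (model output fed back autoregressively)."""
        return self.reconstructions[N_INPUT_STEPS - 1:]

    def predictions_array(self) -> np.ndarray:
        """(n, 3, 1, w, w) numpy array of the forecast frames."""
        return np.stack(
            [t.data.transpose(0, 3, 1, 2) for t in self.predictions], axis=1
        )


@dataclass
class TrainResult:
    model: Forecaster
    history: dict
    best_epoch: int


def _nhwc_frame(data: np.ndarray, t: int) -> Tensor:
    """Constant (n, w, w, 1) channels-last tensor for time-step t of (n, T, 1, w, w)."""
    return Tensor(np.ascontiguousarray(data[:, t].transpose(0, 2, 3, 1)))


def rollout_next_frame(
    model: Forecaster, inputs, n_total_steps: int = 6, collect_states: bool = False
) -> RolloutResult:
    """Autoregressive next-frame rollout from the three observed frames.

    ``inputs`` is (n, 3, 1, w, w): the frames of steps t1..t3, treated as
    constants (no gradient flows into them).  Steps 2 and 3 are
    reconstructed from true predecessors; from step 4 on the model
    consumes its own previous output.  Returns reconstructions of steps
    2..n_total_steps as channels-last (n, w, w, 1) tensors.
    """
    if model.scheme != "next_frame":
        raise ValueError(f"rollout_next_frame needs a next-frame model, got {model.scheme}")
    data = inputs.data if isinstance(inputs, Tensor) else np.asarray(inputs)
    if data.ndim != 5 or data.shape[1] != N_INPUT_STEPS:
        raise ValueError(
            f"inputs must be (n, {N_INPUT_STEPS}, 1, w, w), got {data.shape}"
        )
    n = data.shape[0]
    state = model.init_state(n)
    outs = []
    states = []
    current = _nhwc_frame(data, 0)
    for t in range(1, n_total_steps):
        out, state = model.step(current, state)
        outs.append(out)
        if collect_states:
            states.append(state)
        current = _nhwc_frame(data, t) if t < N_INPUT_STEPS else out
    return RolloutResult(reconstructions=outs, states=states)


def loss_next_frame(result: RolloutResult, truth) -> ad.Tensor:
    """MSE pooled over reconstructions of steps 2..T against the truth frames.

    ``truth`` is (n, T-1, 1, w, w): the frames of steps 2..T.
    """
    truth = np.asarray(truth)
    recon = result.reconstructions
    if truth.shape[1] != len(recon):
        raise ValueError(
            f"truth has {truth.shape[1]} frames, rollout produced {len(recon)}"
        )
    terms = [
        ad.mse(r, truth[:, t].transpose(0, 2, 3, 1)) for t, r in enumerate(recon)
    ]
    total = terms[0]
    for t in terms[1:]:
        total = ad.add(total, t)
    return ad.mul(total, 1.0 / len(terms))


def loss_three_step(predictions, truth) -> ad.Tensor:
    """MSE between the three predicted future frames and the truth (steps 4..6)."""
    truth = np.asarray(truth)
    pred = predictions if isinstance(predictions, Tensor) else Tensor(np.asarray(predictions))
    if pred.data.shape != truth.shape:
        raise ValueError(f"prediction shape {pred.data.shape} != truth shape {truth.shape}")
    return ad.mse(pred, truth)


def _decouple_penalty(states) -> ad.Tensor:
    """Mean squared cosine similarity between per-step C and M increments.

    An interpretation of the memory-decoupling regularizer of the
    PredRNN line; off by default (the benchmarked models do not use it).
    """
    terms = []
    prev = None
    for st in states:
        if "layers" not in st:
            continue
        for layer, prev_layer in zip(st["layers"], (prev or {}).get("layers", st["layers"])):
            if layer.C is None or layer.M is None:
                continue
            dc = layer.C if prev is None else ad.sub(layer.C, prev_layer.C)
            dm = layer.M
            axes = (1, 2, 3)
            dot = ad.reduce_sum(ad.mul(dc, dm), axes)
            nc = ad.powc(ad.add(ad.reduce_sum(ad.mul(dc, dc), axes), 1e-8), 0.5)
            nm = ad.powc(ad.add(ad.reduce_sum(ad.mul(dm, dm), axes), 1e-8), 0.5)
            cos = ad.mul(ad.mul(dot, ad.powc(nc, -1.0)), ad.powc(nm, -1.0))
            sq = ad.mul(cos, cos)
            terms.append(ad.mul(ad.reduce_sum(sq, (0,)), 1.0 / sq.data.shape[0]))
        prev = st
    if not terms:
        return Tensor(np.zeros(()))
    total = terms[0]
    for t in terms[1:]:
        total = ad.add(total, t)
    return ad.mul(total, 1.0 / len(terms))


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _clip_gradients(params, max_norm):
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = np.sqrt(total)
    if max_norm and norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm


def _batch_loss(model, batch, config):
    """Forward pass and scheme loss for one (n, T, 1, w, w) batch."""
    if config.scheme == "next_frame":
        collect = config.decouple_weight > 0
        result = rollout_next_frame(
            model, batch[:, :N_INPUT_STEPS], n_total_steps=batch.shape[1],
            collect_states=collect,
        )
        loss = loss_next_frame(result, batch[:, 1:])
        if collect:
            loss = ad.add(loss, ad.mul(_decouple_penalty(result.states),
                                       config.decouple_weight))
        return loss
    pred = model.forward3(Tensor(batch[:, :N_INPUT_STEPS]))
    return loss_three_step(pred, batch[:, N_INPUT_STEPS:N_INPUT_STEPS + 3])


def evaluate_loss(model, samples: SampleTensor, config: TrainConfig) -> float:
    """Scheme loss over a sample tensor without updating weights."""
    data = samples.data.astype(model.config.np_dtype)
    total, n = 0.0, 0
    for start in range(0, data.shape[0], config.batch_size):
        batch = data[start:start + config.batch_size]
        loss = _batch_loss(model, batch, config)
        total += float(loss.data) * batch.shape[0]
        n += batch.shape[0]
    return total / max(n, 1)


def train(
    model: Forecaster,
    samples: SampleTensor,
    config: TrainConfig,
    validation: Optional[SampleTensor] = None,
) -> TrainResult:
    """Minibatch Adam training; retains the best-validation checkpoint.

    Without validation data the final-epoch weights are kept and
    best_epoch refers to the lowest training loss.
    """
    min_steps = N_INPUT_STEPS + 1 if config.scheme == "next_frame" else 2 * N_INPUT_STEPS
    if samples.n_steps < min_steps:
        raise ValueError(
            f"{config.scheme} training needs >= {min_steps} time-steps, "
            f"got {samples.n_steps}"
        )
    if (config.scheme == "next_frame") != (model.scheme == "next_frame"):
        raise ValueError(f"scheme {config.scheme} incompatible with a {model.scheme} model")
    rng = np.random.default_rng(config.seed)
    data = samples.data.astype(model.config.np_dtype)
    params = model.parameters()
    opt = _Adam(params, config.learning_rate)
    history = {"train": [], "val": [], "grad_clipped_epochs": []}
    best_val = np.inf
    best_state = None
    best_epoch = -1

    for epoch in range(config.epochs):
        order = rng.permutation(data.shape[0])
        total, n, clipped = 0.0, 0, False
        for start in range(0, len(order), config.batch_size):
            batch = data[order[start:start + config.batch_size]]
            opt.zero_grad()
            loss = _batch_loss(model, batch, config)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch offset {start}: "
                    f"{float(loss.data)} (lr={config.learning_rate}, "
                    f"batch_size={batch.shape[0]})"
                )
            loss.backward()
            norm = _clip_gradients(params, config.clip_norm)
            if config.clip_norm and norm > config.clip_norm:
                clipped = True
            opt.step()
            total += float(loss.data) * batch.shape[0]
            n += batch.shape[0]
        train_loss = total / max(n, 1)
        history["train"].append(train_loss)
        if clipped:
            history["grad_clipped_epochs"].append(epoch)
        if validation is not None:
            val_loss = evaluate_loss(model, validation, config)
            history["val"].append(val_loss)
            if val_loss < best_val:
                best_val = val_loss
                best_epoch = epoch
                best_state = {k: v.copy() for k, v in model.state_dict().items()}
        elif train_loss < best_val:
            best_val = train_loss
            best_epoch = epoch

    if best_state is not None:
        model.load_state_dict(best_state)
    return TrainResult(model=model, history=history, best_epoch=best_epoch)


def predict_genome(
    model: Forecaster,
    stack: SpatioTemporalStack,
    window: int = 50,
    step: int = 3,
    n_future: int = 3,
):
    """Forecast future contact matrices for a chromosome.

    ``stack`` holds the (rescaled, [0, 1]) matrices of the three observed
    time-steps.  Windows slide along the diagonal, the model rolls out,
    and overlapping window predictions are averaged back into
    genome-band matrices (missing pixels NaN, symmetrized, clamped).
    """
    if stack.n_steps < N_INPUT_STEPS:
        raise ValueError(f"need {N_INPUT_STEPS} observed time-steps, got {stack.n_steps}")
    obs = SpatioTemporalStack(stack.matrices[:N_INPUT_STEPS])
    tensor = extract_windows(obs, window=window, step=step)
    x = tensor.data.astype(model.config.np_dtype)
    if model.scheme == "next_frame":
        result = rollout_next_frame(model, x, n_total_steps=N_INPUT_STEPS + n_future)
        preds = result.predictions_array()
    else:
        preds = model.forward3(Tensor(x)).data[:, :n_future]
    return reassemble(
        preds, tensor.offsets, tensor.n_bins,
        chrom=stack.chrom, resolution=stack.resolution,
    )


def save_checkpoint(model: Forecaster, path) -> None:
    """Single-file checkpoint: weights + architecture config + format version."""
    meta = json.dumps({"version": 1, "model": model.config.__dict__})
    np.savez_compressed(path, __meta__=np.array(meta), **model.state_dict())


def load_checkpoint(path) -> Forecaster:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        model = build_network(ModelConfig(**meta["model"]))
        model.load_state_dict({k: z[k] for k in z.files if k != "__meta__"})
    return model
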