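"""Two-layer deep belief network with a frozen-representation linear readout.

The generative model is a greedy stack of two restricted Boltzmann
machines trained by one-step contrastive divergence (CD-1) on binary
dot-array images.  "Young" and "Mature" models are checkpoints of the
same unsupervised run (1 epoch vs. the terminal epoch).  A softmax
readout is then trained on concatenated top-layer codes of stimulus
pairs to pick the side with more dots; readout training never touches
the DBN weights, and the readout protocol object is shared verbatim
between the conditions it compares.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    DivergenceError,
    InvalidArgumentError,
    InvalidComparisonError,
)
from .trials import ChoiceDataset, TrialPair

__all__ = [
    "RbmHyper",
    "RbmParams",
    "DbnModel",
    "ReadoutProtocol",
    "ReadoutClassifier",
    "cd1_step",
    "train_rbm_cd1",
    "train_dbn",
    "encode",
    "train_readout",
    "train_readout_codes",
    "train_readout_online",
    "run_comparison_task",
    "run_comparison_task_codes",
    "curriculum_order",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass
class RbmHyper:
    """CD-1 hyperparameters (local defaults; freely overridable)."""

    learning_rate: float = 0.1
    momentum_initial: float = 0.5
    momentum_final: float = 0.9
    momentum_switch_epoch: int = 5
    weight_decay: float = 2e-4
    batch_size: int = 125
    init_sigma: float = 0.01
    # hidden-sparsity regularization (0 disables); nudges mean hidden
    # activity toward sparsity_target via a bias/weight penalty
    sparsity_target: float = 0.0
    sparsity_cost: float = 0.0
    # initialize visible biases to the logit of per-pixel mean activity
    init_visible_bias_from_data: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise InvalidArgumentError("hyperparameters must be positive")

    def momentum_at(self, epoch: int) -> float:
        return (
            self.momentum_initial
            if epoch < self.momentum_switch_epoch
            else self.momentum_final
        )


@dataclass
class RbmParams:
    weights: np.ndarray  # (n_visible, n_hidden)
    visible_bias: np.ndarray
    hidden_bias: np.ndarray

    @property
    def n_visible(self) -> int:
        return self.weights.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.weights.shape[1]

    @classmethod
    def initialize(
        cls, n_visible: int, n_hidden: int, rng: np.random.Generator, sigma: float = 0.01
    ) -> "RbmParams":
        return cls(
            weights=sigma * rng.standard_normal((n_visible, n_hidden)),
            visible_bias=np.zeros(n_visible),
            hidden_bias=np.zeros(n_hidden),
        )


@dataclass
class DbnModel:
    layers: list[RbmParams]
    epochs_trained: int
    seed: int
    arch_id: str = ""

    def __post_init__(self) -> None:
        if len(self.layers) != 2:
            raise InvalidArgumentError("model must have exactly two layers")
        if self.layers[0].n_hidden != self.layers[1].n_visible:
            raise InvalidArgumentError(
                "layer-1 hidden size must equal layer-2 visible size"
            )

    @property
    def n_visible(self) -> int:
        return self.layers[0].n_visible

    @property
    def code_size(self) -> int:
        return self.layers[1].n_hidden


@dataclass
class _Velocity:
    w: np.ndarray
    vb: np.ndarray
    hb: np.ndarray

    @classmethod
    def zeros(cls, params: RbmParams) -> "_Velocity":
        return cls(
            np.zeros_like(params.weights),
            np.zeros_like(params.visible_bias),
            np.zeros_like(params.hidden_bias),
        )


def cd1_step(
    params: RbmParams,
    v0: np.ndarray,
    rng: np.random.Generator,
    learning_rate: float,
    momentum: float,
    weight_decay: float,
    velocity: _Velocity,
    sparsity_target: float = 0.0,
    sparsity_cost: float = 0.0,
) -> float:
    """One CD-1 parameter update on a mini-batch; returns reconstruction MSE.

    Positive statistics use hidden activation probabilities; the negative
    phase reconstructs from a binary hidden sample and uses visible
    probabilities (standard CD-1 mean-field reconstruction).
    """
    batch = v0.shape[0]
    h0_prob = sigmoid(v0 @ params.weights + params.hidden_bias)
    h0_sample = (rng.random(h0_prob.shape) < h0_prob).astype(v0.dtype)
    v1_prob = sigmoid(h0_sample @ params.weights.T + params.visible_bias)
    h1_prob = sigmoid(v1_prob @ params.weights + params.hidden_bias)

    dw = (v0.T @ h0_prob - v1_prob.T @ h1_prob) / batch - weight_decay * params.weights
    dvb = (v0 - v1_prob).mean(axis=0)
    dhb = (h0_prob - h1_prob).mean(axis=0)
    if sparsity_cost > 0.0:
        dhb += sparsity_cost * (sparsity_target - h0_prob.mean(axis=0))

    velocity.w = momentum * velocity.w + learning_rate * dw
    velocity.vb = momentum * velocity.vb + learning_rate * dvb
    velocity.hb = momentum * velocity.hb + learning_rate * dhb
    params.weights += velocity.w
    params.visible_bias += velocity.vb
    params.hidden_bias += velocity.hb
    return float(((v0 - v1_prob) ** 2).mean())


def train_rbm_cd1(
    data: np.ndarray,
    n_hidden: int,
    hyper: RbmHyper,
    epochs: int,
    rng: np.random.Generator,
    params: RbmParams | None = None,
    start_epoch: int = 0,
) -> tuple[RbmParams, list[float]]:
    """Train an RBM by CD-1; returns parameters and per-epoch mean loss."""
    data = np.asarray(data)
    if not np.issubdtype(data.dtype, np.floating):
        data = data.astype(float)
    if data.ndim != 2:
        raise InvalidArgumentError("data must be (samples, visible) matrix")
    if data.min() < 0 or data.max() > 1:
        raise InvalidArgumentError("data values must lie in [0, 1]")
    if params is None:
        params = RbmParams.initialize(
            data.shape[1], n_hidden, rng, sigma=hyper.init_sigma
        )
        if hyper.init_visible_bias_from_data:
            p = np.clip(data.mean(axis=0), 1e-3, 1.0 - 1e-3)
            params.visible_bias = np.log(p / (1.0 - p))
        params.weights = params.weights.astype(data.dtype)
        params.visible_bias = params.visible_bias.astype(data.dtype)
        params.hidden_bias = params.hidden_bias.astype(data.dtype)
    velocity = _Velocity.zeros(params)
    losses: list[float] = []
    n = data.shape[0]
    for epoch in range(start_epoch, start_epoch + epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, hyper.batch_size):
            batch = data[order[lo : lo + hyper.batch_size]]
            loss = cd1_step(
                params,
                batch,
                rng,
                hyper.learning_rate,
                hyper.momentum_at(epoch),
                hyper.weight_decay,
                velocity,
                sparsity_target=hyper.sparsity_target,
                sparsity_cost=hyper.sparsity_cost,
            )
            epoch_losses.append(loss)
        if not np.all(np.isfinite(params.weights)):
            raise DivergenceError(f"weights diverged at epoch {epoch}")
        losses.append(float(np.mean(epoch_losses)))
    return params, losses


def train_dbn(
    images: np.ndarray,
    arch: tuple[int, int],
    epochs: int,
    hyper: tuple[RbmHyper, RbmHyper] | None = None,
    rng: np.random.Generator | int | None = None,
    checkpoint_epochs: Sequence[int] = (),
    dtype: np.dtype = np.float64,
) -> dict[int, DbnModel]:
    """Greedy layerwise training; returns checkpoints keyed by epoch.

    The first layer is trained on pixels across all epochs with
    snapshots at the checkpoints; at each checkpoint a second layer is
    then trained (for the same number of epochs) on the snapshot's
    hidden activation probabilities, so an epoch-``e`` checkpoint saw
    ``e`` passes through the data at both layers.  The terminal epoch is
    always checkpointed.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        seed = 0 if rng is None else int(rng)
        rng = np.random.default_rng(seed)
    else:
        seed = -1
    h1, h2 = arch
    if h1 < 1 or h2 < 1:
        raise InvalidArgumentError(f"invalid architecture {arch}")
    if hyper is None:
        hyper = (RbmHyper(learning_rate=0.1), RbmHyper(learning_rate=0.05))
    hyp1, hyp2 = hyper
    images = np.asarray(images, dtype=dtype)
    if images.ndim != 2:
        images = images.reshape(images.shape[0], -1)

    wanted = sorted(set(int(e) for e in checkpoint_epochs) | {epochs})
    if any(e < 1 or e > epochs for e in wanted):
        raise InvalidArgumentError(f"checkpoint epochs {wanted} outside 1..{epochs}")

    layer2_rng = np.random.default_rng(rng.integers(2**63))
    checkpoints: dict[int, DbnModel] = {}
    params1: RbmParams | None = None
    prev = 0
    for e in wanted:
        params1, _ = train_rbm_cd1(
            images, h1, hyp1, epochs=e - prev, rng=rng, params=params1, start_epoch=prev
        )
        prev = e
        snap1 = copy.deepcopy(params1)
        acts = sigmoid(images @ snap1.weights + snap1.hidden_bias)
        l2_rng = np.random.default_rng(layer2_rng.integers(2**63))
        params2, _ = train_rbm_cd1(acts, h2, hyp2, epochs=e, rng=l2_rng)
        checkpoints[e] = DbnModel(
            layers=[snap1, params2],
            epochs_trained=e,
            seed=seed,
            arch_id=f"{h1}x{h2}",
        )
    return checkpoints


def encode(model: DbnModel, images: np.ndarray) -> np.ndarray:
    """Deterministic top-layer code: activation probabilities, no sampling."""
    x = np.asarray(images, dtype=model.layers[0].weights.dtype)
    single = x.ndim == 1 or (x.ndim == 2 and x.size == model.n_visible and x.shape[1] != model.n_visible)
    if x.size % model.n_visible != 0:
        raise InvalidArgumentError(
            f"image size {x.shape} does not match visible layer {model.n_visible}"
        )
    x = x.reshape(-1, model.n_visible)
    h1 = sigmoid(x @ model.layers[0].weights + model.layers[0].hidden_bias)
    h2 = sigmoid(h1 @ model.layers[1].weights + model.layers[1].hidden_bias)
    return h2[0] if single and h2.shape[0] == 1 else h2


@dataclass(frozen=True)
class ReadoutProtocol:
    """Fixed descriptor of the supervised readout training procedure."""

    iterations: int = 200
    learning_rate: float = 0.5
    mode: str = "batch"  # "batch" or "online" (single-pass per-trial updates)


@dataclass
class ReadoutClassifier:
    weights: np.ndarray  # (2*code_size, 2)
    bias: np.ndarray
    protocol: ReadoutProtocol

    def logits(self, pair_codes: np.ndarray) -> np.ndarray:
        return pair_codes @ self.weights + self.bias


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _pair_codes(model: DbnModel, pair_images: Sequence[tuple[np.ndarray, np.ndarray]]):
    left = encode(model, np.stack([np.ravel(l) for l, _ in pair_images]))
    right = encode(model, np.stack([np.ravel(r) for _, r in pair_images]))
    return np.hstack([left, right])


def _labels_to_onehot(labels: Sequence[str]) -> np.ndarray:
    idx = np.array([0 if s == "left" else 1 for s in labels])
    out = np.zeros((len(idx), 2))
    out[np.arange(len(idx)), idx] = 1.0
    return out


def train_readout(
    model: DbnModel,
    pair_images: Sequence[tuple[np.ndarray, np.ndarray]],
    labels: Sequence[str],
    protocol: ReadoutProtocol = ReadoutProtocol(),
) -> ReadoutClassifier:
    """Train the linear decision layer on frozen pair codes.

    Full-batch gradient descent on the softmax cross-entropy, starting
    from zero weights; the DBN is read-only throughout.
    """
    return train_readout_codes(_pair_codes(model, pair_images), labels, protocol)


def train_readout_codes(
    pair_codes: np.ndarray,
    labels: Sequence[str],
    protocol: ReadoutProtocol = ReadoutProtocol(),
) -> ReadoutClassifier:
    """Readout training on precomputed concatenated pair codes."""
    X = np.asarray(pair_codes, dtype=float)
    Y = _labels_to_onehot(labels)
    W = np.zeros((X.shape[1], 2))
    b = np.zeros(2)
    n = X.shape[0]
    if protocol.mode == "batch":
        for _ in range(protocol.iterations):
            G = _softmax(X @ W + b) - Y
            W -= protocol.learning_rate * (X.T @ G) / n
            b -= protocol.learning_rate * G.mean(axis=0)
    elif protocol.mode == "online":
        for _ in range(protocol.iterations):
            for i in range(n):
                g = _softmax((X[i] @ W + b)[None, :]) - Y[i]
                W -= protocol.learning_rate * np.outer(X[i], g[0])
                b -= protocol.learning_rate * g[0]
    else:
        raise InvalidArgumentError(f"unknown readout mode {protocol.mode!r}")
    return ReadoutClassifier(weights=W, bias=b, protocol=protocol)


def train_readout_online(
    model: DbnModel,
    pair_images: Sequence[tuple[np.ndarray, np.ndarray]],
    labels: Sequence[str],
    protocol: ReadoutProtocol | None = None,
) -> ReadoutClassifier:
    """Single-pass, per-trial readout training (order-sensitive).

    Used for curriculum/hysteresis runs where trial ordering matters.
    """
    protocol = protocol or ReadoutProtocol(iterations=1, learning_rate=0.5, mode="online")
    if protocol.mode != "online":
        raise InvalidArgumentError("online training requires an online protocol")
    return train_readout(model, pair_images, labels, protocol)


def assert_same_protocol(a: ReadoutClassifier, b: ReadoutClassifier) -> None:
    if a.protocol != b.protocol:
        raise InvalidComparisonError(
            f"readout protocols differ: {a.protocol} vs {b.protocol}"
        )


def run_comparison_task(
    model: DbnModel,
    classifier: ReadoutClassifier,
    test_pairs: Sequence[TrialPair],
    pair_images: Sequence[tuple[np.ndarray, np.ndarray]],
    rng: np.random.Generator | None = None,
    observer_id: str = "network",
) -> ChoiceDataset:
    """Run the two-alternative task; returns choices ready for GLM fitting."""
    if len(test_pairs) != len(pair_images):
        raise InvalidArgumentError("one image pair per trial required")
    return run_comparison_task_codes(
        classifier,
        test_pairs,
        _pair_codes(model, pair_images),
        rng=rng,
        observer_id=observer_id,
    )


def run_comparison_task_codes(
    classifier: ReadoutClassifier,
    test_pairs: Sequence[TrialPair],
    pair_codes: np.ndarray,
    rng: np.random.Generator | None = None,
    observer_id: str = "network",
) -> ChoiceDataset:
    """Comparison task on precomputed pair codes."""
    rng = np.random.default_rng() if rng is None else rng
    if len(test_pairs) != len(pair_codes):
        raise InvalidArgumentError("one code row per trial required")
    logits = classifier.logits(np.asarray(pair_codes, dtype=float))
    chosen = []
    for row in logits:
        if row[0] == row[1]:
            chosen.append("left" if rng.random() < 0.5 else "right")
        else:
            chosen.append("left" if row[0] > row[1] else "right")
    return ChoiceDataset(
        trials=list(test_pairs), chosen_side=chosen, observer_id=observer_id
    )


def curriculum_order(
    pairs: Sequence[TrialPair],
    mode: str,
    rng: np.random.Generator | None = None,
) -> list[int]:
    """Return trial indices ordered by difficulty.

    ``easy_to_hard`` puts the largest |log2 numerosity ratio| first;
    ``hard_to_easy`` reverses it; ``shuffled`` permutes with the given
    rng.  Ties keep pair-id order (stable).
    """
    idx = list(range(len(pairs)))
    if mode == "shuffled":
        rng = np.random.default_rng() if rng is None else rng
        return list(rng.permutation(len(pairs)))
    key = [abs(math.log2(p.r_num)) for p in pairs]
    if mode == "easy_to_hard":
        return sorted(idx, key=lambda i: (-key[i], pairs[i].pair_id))
    if mode == "hard_to_easy":
        return sorted(idx, key=lambda i: (key[i], pairs[i].pair_id))
    raise InvalidArgumentError(f"unknown curriculum mode {mode!r}")
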