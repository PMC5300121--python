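"""The perturbation-barcode metric-learning network.

A siamese multilayer perceptron maps a 978-gene z-score profile through two
noisy-sigmoid hidden layers (400 then 100 units).  Pairs of profiles enter as
adjacent input rows; the squared Euclidean distance d^2 between the two
second-hidden-layer activation vectors feeds a rectified margin cost

    c = softplus(1 - y * (m - d^2)),   softplus(x) = ln(1 + e^x),

with y = +1 for biological replicates and -1 otherwise and margin m = 5 in
squared-distance units.  Training minimises the mean pair cost plus an L1
penalty on the weight matrices by minibatch RMSprop, with Gaussian
pre-activation noise (variance 0.25) and dropout (p = 0.5) on the hidden
layers.  The noise pushes activations towards saturation, so at inference —
which is noise- and dropout-free and fully deterministic — the second hidden
layer is almost binary; thresholding it at 0.5 yields the 100-bit
"perturbation barcode" of a profile.

The forward, backward and optimiser passes are written directly in NumPy;
gradients are exact (tests verify them against central finite differences).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from .io import ExpressionMatrix
from .pairs import PairSet, pairs_to_stream

__all__ = ["ModelConfig", "BarcodeModel", "noisy_sigmoid_forward",
           "pair_squared_distance", "margin_cost", "train", "encode",
           "to_barcode", "classify_pair", "consensus_barcode",
           "save_model", "load_model"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    # piecewise form avoids overflow in exp for large |z|
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softplus(x: np.ndarray | float) -> np.ndarray | float:
    # ln(1 + e^x) = max(x, 0) + ln(1 + e^-|x|)
    x = np.asarray(x, dtype=float)
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    ``layer_sizes`` is (input, hidden1, hidden2); ``noise_variance`` is the
    variance of the Gaussian added to each pre-activation during training;
    ``margin`` is in squared-distance units; ``batch_size`` counts pairs.
    """

    layer_sizes: tuple[int, int, int] = (978, 400, 100)
    noise_variance: float = 0.25
    dropout_rate: float = 0.5
    l1_weight: float = 1e-6
    margin: float = 5.0
    learning_rate: float = 1e-3
    decay: float = 0.9
    epsilon: float = 1e-8
    batch_size: int = 128
    epochs: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if len(self.layer_sizes) != 3 or any(s < 1 for s in self.layer_sizes):
            raise ValueError("layer_sizes must be three positive integers")


@dataclass
class BarcodeModel:
    """Trained weights plus the config and training history that made them."""

    weights: list[np.ndarray]   # per layer, shape (n_out, n_in)
    biases: list[np.ndarray]    # per layer, shape (n_out,)
    config: ModelConfig
    training_history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        sizes = self.config.layer_sizes
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            if W.shape != (sizes[i + 1], sizes[i]) or b.shape != (sizes[i + 1],):
                raise ValueError(
                    f"layer {i} shapes {W.shape}/{b.shape} inconsistent with "
                    f"layer_sizes {sizes}")

    @property
    def n_input(self) -> int:
        return self.config.layer_sizes[0]

    @property
    def n_output(self) -> int:
        return self.config.layer_sizes[-1]


def _init_params(config: ModelConfig, rng: np.random.Generator):
    """Uniform init scaled by fan-in, fully determined by ``rng``."""
    weights, biases = [], []
    sizes = config.layer_sizes
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        limit = 1.0 / np.sqrt(n_in)
        weights.append(rng.uniform(-limit, limit, size=(n_out, n_in)))
        biases.append(np.zeros(n_out))
    return weights, biases


def noisy_sigmoid_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray,
                          noise_variance: float = 0.25,
                          dropout_rate: float = 0.0,
                          train_mode: bool = False,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """One noisy-sigmoid layer: y = sigma(Wx + b [+ N(0, noise_variance I)]).

    In training mode Gaussian noise is added to the pre-activation and an
    inverted-scaling dropout mask is applied to the output; inference mode is
    deterministic (no noise, no dropout).  ``x`` may be a vector or a
    (samples x features) matrix.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != weight.shape[1]:
        raise ValueError(f"input width {X.shape[1]} does not match layer "
                         f"input size {weight.shape[1]}")
    pre = X @ weight.T + bias
    if train_mode:
        if rng is None:
            raise ValueError("train_mode requires an rng")
        if noise_variance > 0:
            pre = pre + rng.normal(0.0, np.sqrt(noise_variance), size=pre.shape)
    out = sigmoid(pre)
    if train_mode and dropout_rate > 0:
        keep = 1.0 - dropout_rate
        mask = (rng.random(out.shape) < keep) / keep
        out = out * mask
    return out[0] if single else out


def pair_squared_distance(h_a: np.ndarray, h_b: np.ndarray) -> float:
    """Squared Euclidean distance between two representation vectors."""
    h_a = np.asarray(h_a, dtype=float)
    h_b = np.asarray(h_b, dtype=float)
    if h_a.shape != h_b.shape:
        raise ValueError(f"length mismatch: {h_a.shape} vs {h_b.shape}")
    diff = h_a - h_b
    return float(np.dot(diff, diff))


def margin_cost(d_squared, label, margin: float = 5.0):
    """Rectified margin loss softplus(1 - y (m - d^2)).

    Replicate pairs (y = +1) are penalised increasingly as d^2 exceeds the
    margin; non-replicates (y = -1) as d^2 falls below it.  Total and smooth,
    numerically stable for large arguments.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    d_squared = np.asarray(d_squared, dtype=float)
    label = np.asarray(label, dtype=float)
    return softplus(1.0 - label * (margin - d_squared))


def _forward_pairs(weights, biases, X, config: ModelConfig,
                   train_mode: bool, rng: np.random.Generator | None):
    """Forward pass over a batch of adjacent-row pairs.

    Returns (layer inputs, post-sigmoid activations, dropout masks) — the
    caches the backward pass needs.  ``inputs[i]`` feeds layer i;
    ``hidden[i]`` is sigmoid(pre) before dropout.
    """
    inputs = [np.asarray(X, dtype=float)]
    hidden: list[np.ndarray] = []
    masks: list[np.ndarray | None] = []
    a = inputs[0]
    for W, b in zip(weights, biases):
        pre = a @ W.T + b
        if train_mode and config.noise_variance > 0:
            pre = pre + rng.normal(0.0, np.sqrt(config.noise_variance),
                                   size=pre.shape)
        h = sigmoid(pre)
        hidden.append(h)
        if train_mode and config.dropout_rate > 0:
            keep = 1.0 - config.dropout_rate
            # one thinned network per pair: both members share the mask,
            # otherwise mask mismatch alone inflates replicate distances
            half = (rng.random((h.shape[0] // 2, h.shape[1])) < keep) / keep
            mask = np.repeat(half, 2, axis=0)
            a = h * mask
            masks.append(mask)
        else:
            a = h
            masks.append(None)
        inputs.append(a)
    return inputs, hidden, masks


def _cost_and_grads(weights, biases, X, labels, config: ModelConfig,
                    train_mode: bool = False,
                    rng: np.random.Generator | None = None):
    """Mean margin cost + L1 penalty and its exact gradients.

    ``X`` holds pair members as adjacent rows (2P x n_in); ``labels`` has one
    entry per pair.  Dropout masks cancel exactly in the backward pass, so
    the gradient is exact for the sampled noise/mask realisation.
    """
    labels = np.asarray(labels, dtype=float)
    n_pairs = labels.shape[0]
    inputs, hidden, masks = _forward_pairs(weights, biases, X, config, train_mode, rng)
    out = inputs[-1]  # final representation (post-dropout during training)
    diff = out[0::2] - out[1::2]
    d2 = np.sum(diff * diff, axis=1)
    arg = 1.0 - labels * (config.margin - d2)
    cost = float(np.mean(softplus(arg)))
    l1 = config.l1_weight * sum(float(np.sum(np.abs(W))) for W in weights)
    total = cost + l1

    # d cost / d d2 = sigma(arg) * y / P  (softplus' = logistic sigma)
    dcost_dd2 = sigmoid(arg) * labels / n_pairs
    g = np.empty_like(out)
    g[0::2] = (2.0 * dcost_dd2)[:, None] * diff
    g[1::2] = -g[0::2]

    grad_W = [np.zeros_like(W) for W in weights]
    grad_b = [np.zeros_like(b) for b in biases]
    for layer in range(len(weights) - 1, -1, -1):
        h = hidden[layer]
        mask = masks[layer]
        g_h = g * mask if mask is not None else g
        g_pre = g_h * h * (1.0 - h)
        grad_W[layer] = g_pre.T @ inputs[layer] + config.l1_weight * np.sign(weights[layer])
        grad_b[layer] = g_pre.sum(axis=0)
        g = g_pre @ weights[layer]
    return total, grad_W, grad_b


def train(matrix: ExpressionMatrix, train_pairs: PairSet, val_pairs: PairSet,
          config: ModelConfig | None = None, verbose: bool = False) -> BarcodeModel:
    """Fit the network by minibatch RMSprop on the margin cost.

    Records per-epoch mean training cost and validation pair-classification
    accuracy (rule: predict replicate iff d^2 < margin) and returns the
    weights with the best validation accuracy seen.
    """
    config = config or ModelConfig()
    config.validate()
    if len(train_pairs) == 0 or len(val_pairs) == 0:
        raise ValueError("train and validation pair sets must be nonempty")
    root = np.random.SeedSequence(config.seed)
    init_ss, noise_ss, shuffle_ss = root.spawn(3)
    rng_init = np.random.default_rng(init_ss)
    rng_noise = np.random.default_rng(noise_ss)
    shuffle_seeds = np.random.default_rng(shuffle_ss).integers(0, 2**31, size=config.epochs)

    weights, biases = _init_params(config, rng_init)
    cache_W = [np.zeros_like(W) for W in weights]
    cache_b = [np.zeros_like(b) for b in biases]

    best_accuracy = -np.inf
    best_state = None
    history: list[dict] = []
    rows_per_batch = 2 * config.batch_size
    for epoch in range(config.epochs):
        costs = []
        stream = pairs_to_stream(matrix, train_pairs, batch_size=rows_per_batch,
                                 shuffle=True, seed=int(shuffle_seeds[epoch]))
        for batch_idx, (X, labels) in enumerate(stream):
            cost, gW, gb = _cost_and_grads(weights, biases, X, labels, config,
                                           train_mode=True, rng=rng_noise)
            if not np.isfinite(cost):
                raise RuntimeError(
                    f"non-finite training cost at epoch {epoch}, batch {batch_idx}")
            for i in range(len(weights)):
                cache_W[i] = config.decay * cache_W[i] + (1 - config.decay) * gW[i] ** 2
                cache_b[i] = config.decay * cache_b[i] + (1 - config.decay) * gb[i] ** 2
                weights[i] -= config.learning_rate * gW[i] / (np.sqrt(cache_W[i]) + config.epsilon)
                biases[i] -= config.learning_rate * gb[i] / (np.sqrt(cache_b[i]) + config.epsilon)
            costs.append(cost)
        model = BarcodeModel([W.copy() for W in weights], [b.copy() for b in biases],
                             config, history)
        accuracy = pair_accuracy(model, matrix, val_pairs)
        history.append({"epoch": epoch, "train_cost": float(np.mean(costs)),
                        "val_accuracy": accuracy})
        if verbose:
            print(f"epoch {epoch:3d}  cost {np.mean(costs):.4f}  "
                  f"val acc {accuracy:.3f}")
        if accuracy > best_accuracy:
            best_accuracy = accuracy
            best_state = ([W.copy() for W in weights], [b.copy() for b in biases])
    return BarcodeModel(best_state[0], best_state[1], config, history)


def encode(matrix: ExpressionMatrix | np.ndarray, model: BarcodeModel) -> np.ndarray:
    """Second-hidden-layer activations (samples x n_hidden2), deterministic.

    The inference path uses noiseless sigmoids and no dropout, so repeated
    calls are bitwise identical.
    """
    X = matrix.values.T if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_input:
        raise ValueError(f"input width {X.shape[1]} does not match model input "
                         f"size {model.n_input}")
    a = X
    for W, b in zip(model.weights, model.biases):
        a = sigmoid(a @ W.T + b)
    return a


def to_barcode(activations: np.ndarray) -> np.ndarray:
    """Threshold activations at 0.5 (values >= 0.5 become 1) to binary bits."""
    activations = np.asarray(activations, dtype=float)
    if np.any(activations < 0) or np.any(activations > 1):
        raise ValueError("activations must lie in [0, 1]")
    return (activations >= 0.5).astype(np.int8)


def consensus_barcode(activations: np.ndarray) -> np.ndarray:
    """Barcode of a replicate group: mean activation, then threshold."""
    activations = np.asarray(activations, dtype=float)
    if activations.ndim == 1:
        activations = activations[None, :]
    if activations.shape[0] == 0:
        raise ValueError("empty replicate group")
    return to_barcode(activations.mean(axis=0))


def classify_pair(model: BarcodeModel, x_a: np.ndarray, x_b: np.ndarray,
                  threshold: float | None = None) -> int:
    """Predict +1 (replicates) iff d^2 between encodings is strictly below
    the margin (ties classified -1)."""
    threshold = model.config.margin if threshold is None else threshold
    h = encode(np.vstack([np.asarray(x_a), np.asarray(x_b)]), model)
    return 1 if pair_squared_distance(h[0], h[1]) < threshold else -1


def pair_accuracy(model: BarcodeModel, matrix: ExpressionMatrix,
                  pair_set: PairSet, threshold: float | None = None) -> float:
    """Fraction of pairs whose margin-threshold prediction matches the label."""
    threshold = model.config.margin if threshold is None else threshold
    correct = 0
    for X, labels in pairs_to_stream(matrix, pair_set, batch_size=512):
        h = encode(X, model)
        diff = h[0::2] - h[1::2]
        d2 = np.sum(diff * diff, axis=1)
        pred = np.where(d2 < threshold, 1, -1)
        correct += int(np.sum(pred == labels))
    return correct / len(pair_set)


def barcode_frame(matrix: ExpressionMatrix, model: BarcodeModel):
    """Barcodes for every sample as a (samples x bits) int array plus ids."""
    bits = to_barcode(encode(matrix, model))
    return matrix.sample_ids, bits


def barcode_to_hex(bits: np.ndarray) -> str:
    """Pack a bit vector into a hex string (bit 0 is the most significant)."""
    bits = np.asarray(bits).astype(int)
    value = 0
    for b in bits:
        value = (value << 1) | int(b)
    width = (len(bits) + 3) // 4
    return f"{value:0{width}x}"


# ---------------------------------------------------------------------------
# Checkpointing: one .npz archive with weights, config and history
# ---------------------------------------------------------------------------


def save_model(model: BarcodeModel, path: str) -> None:
    arrays = {}
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    meta = {"config": asdict(model.config), "training_history": model.training_history}
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path: str) -> BarcodeModel:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["meta_json"]).decode())
        cfg = meta["config"]
        cfg["layer_sizes"] = tuple(cfg["layer_sizes"])
        config = ModelConfig(**cfg)
        n_layers = len(config.layer_sizes) - 1
        weights = [archive[f"W{i}"] for i in range(n_layers)]
        biases = [archive[f"b{i}"] for i in range(n_layers)]
    return BarcodeModel(weights, biases, config, meta["training_history"])
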