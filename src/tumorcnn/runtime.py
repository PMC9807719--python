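"""Trainable realization of a :class:`~tumorcnn.arch.ModelSpec` in numpy.

The runtime implements exactly the layer set the architecture module can
describe — valid-padding convolutions (via im2col), average pooling,
flatten, dense — with manual backpropagation, the Adam optimizer,
sparse-categorical cross-entropy loss, and early stopping on validation
loss with best-epoch weight restoration.

Weights are stored per layer as ``{"W": ..., "b": ...}`` dicts inside a
:class:`ModelState`, together with the originating spec and an append-only
training lineage (which protocol / iteration / fold produced each training
event) — the unit that transfer-learning protocols pass around.

Determinism: initialization and epoch shuffling are driven by explicit
integer seeds; with a fixed seed and single-threaded BLAS, repeated runs
are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .arch import ModelSpec, TensorShape, audit, infer_output_shape

__all__ = [
    "TrainConfig",
    "ModelState",
    "TrainResult",
    "build_model",
    "relu",
    "sigmoid",
    "tanh_act",
    "softmax",
    "loss",
    "train",
    "predict",
    "evaluate_loss",
    "save_state",
    "load_state",
    "CheckpointError",
]

_EPS = 1e-7  # probability clamp in the loss


class CheckpointError(RuntimeError):
    """A checkpoint is corrupt or inconsistent with its spec."""


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def relu(x):
    return np.maximum(0.0, x)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def tanh_act(x):
    """Standard hyperbolic tangent, (e^x - e^-x)/(e^x + e^-x)."""
    return np.tanh(x)


def softmax(scores):
    """Row-wise softmax; each output row sums to 1."""
    scores = np.asarray(scores, dtype=np.float64)
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


_FORWARD = {"relu": relu, "sigmoid": sigmoid, "tanh": tanh_act,
            "softmax": softmax, "linear": lambda x: x}


def _activation_grad(name: str, out: np.ndarray) -> np.ndarray:
    """d(activation)/d(pre-activation) expressed through the output."""
    if name == "relu":
        return (out > 0).astype(out.dtype)
    if name == "sigmoid":
        return out * (1.0 - out)
    if name == "tanh":
        return 1.0 - out * out
    if name == "linear":
        return np.ones_like(out)
    raise ValueError(f"no elementwise gradient for activation {name!r}")


def loss(true_labels, predicted_probs) -> float:
    """Mean sparse-categorical cross-entropy, -log p(true class).

    Probabilities at the true class are clamped to [1e-7, 1] so a confident
    wrong prediction yields a large finite loss rather than infinity.
    """
    y = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_probs, dtype=np.float64)
    if p.ndim != 2 or len(y) != len(p):
        raise ValueError("predicted_probs must be (n, K) matching labels")
    if y.min(initial=0) < 0 or y.max(initial=0) >= p.shape[1]:
        raise ValueError("labels out of range for the probability matrix")
    rowsum = p.sum(axis=1)
    if not np.allclose(rowsum, 1.0, atol=1e-4):
        raise ValueError("probability rows must sum to 1")
    picked = np.clip(p[np.arange(len(y)), y], _EPS, 1.0)
    return float(-np.log(picked).mean())


# ---------------------------------------------------------------------------
# layer forward/backward kernels (im2col convolution)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N,H,W,C) -> (N,Ho,Wo,kh*kw*C) patches, valid padding."""
    view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    # view: (N, H-kh+1, W-kw+1, C, kh, kw) -> stride subsample, put taps last
    view = view[:, ::stride, ::stride]
    view = view.transpose(0, 1, 2, 4, 5, 3)  # (N,Ho,Wo,kh,kw,C)
    n, ho, wo = view.shape[:3]
    return np.ascontiguousarray(view).reshape(n, ho, wo, kh * kw * x.shape[3])


def _conv_forward(x, W, b, stride):
    kh, kw, c_in, nf = W.shape
    cols = _im2col(x, kh, kw, stride)
    out = cols @ W.reshape(kh * kw * c_in, nf) + b
    return out, cols


def _conv_backward(dout, cols, x_shape, W, stride):
    kh, kw, c_in, nf = W.shape
    n, ho, wo, _ = dout.shape
    Wm = W.reshape(kh * kw * c_in, nf)
    dW = (cols.reshape(-1, kh * kw * c_in).T @ dout.reshape(-1, nf)).reshape(W.shape)
    db = dout.sum(axis=(0, 1, 2))
    dcols = (dout @ Wm.T).reshape(n, ho, wo, kh, kw, c_in)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    for a in range(kh):
        for c in range(kw):
            dx[:, a:a + stride * ho:stride, c:c + stride * wo:stride, :] += dcols[:, :, :, a, c, :]
    return dx, dW, db


def _pool_forward(x, kh, kw, stride):
    view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    view = view[:, ::stride, ::stride]
    return view.mean(axis=(-1, -2))


def _pool_backward(dout, x_shape, kh, kw, stride):
    n, ho, wo, c = dout.shape
    dx = np.zeros(x_shape, dtype=dout.dtype)
    g = dout / (kh * kw)
    for a in range(kh):
        for b in range(kw):
            dx[:, a:a + stride * ho:stride, b:b + stride * wo:stride, :] += g
    return dx


# ---------------------------------------------------------------------------
# model state
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults follow the production recipe for the tumor classifier:
    Adam with initial learning rate 0.01, at most 10 epochs, batch size 25,
    sparse-categorical cross-entropy, early stopping on validation loss.
    The validation-loss patience of 2 epochs (with best-epoch restoration)
    and the within-training stratified 10% validation split are this
    package's conventions; see docs/methods.md.
    """

    learning_rate: float = 0.01
    max_epochs: int = 10
    batch_size: int = 25
    optimizer: str = "adam"
    early_stopping_patience: int = 2
    monitor: str = "val_loss"
    val_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "TrainConfig":
        """Recipe for small synthetic studies (64x64 inputs, a few hundred
        images).

        At that scale an epoch is only ~10 Adam steps (vs ~100 at
        production scale) and the production learning rate of 0.01
        collapses the narrow 10-channel bottleneck layers into dead ReLUs.
        The desk-scale recipe compensates: learning rate 0.001 and up to 30
        epochs with patience 3, keeping the total step budget comparable.
        """
        return cls(learning_rate=0.001, max_epochs=30,
                   early_stopping_patience=3, seed=seed)


@dataclass
class ModelState:
    """Spec + weights + training lineage: the transferable unit.

    ``lineage`` is an append-only list of training-event records
    (protocol, iteration, fold, epochs run); transfer-learning protocols
    carry states between folds/iterations and the lineage makes the data
    each state has seen auditable.
    """

    spec: ModelSpec
    weights: list[dict[str, np.ndarray]]
    lineage: list[dict] = field(default_factory=list)
    rng_seed: int = 0

    def copy(self) -> "ModelState":
        return ModelState(
            spec=self.spec,
            weights=[{k: v.copy() for k, v in w.items()} for w in self.weights],
            lineage=[dict(ev) for ev in self.lineage],
            rng_seed=self.rng_seed,
        )

    def n_parameters(self) -> int:
        return int(sum(v.size for w in self.weights for v in w.values()))


@dataclass
class TrainResult:
    state: ModelState
    history: dict[str, list[float]]
    stopped_epoch: int
    best_epoch: int


def _glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def build_model(spec: ModelSpec, seed: int = 0) -> ModelState:
    """Freshly initialized state; Glorot-uniform weights, zero biases.

    The realized trainable-parameter count always equals
    ``audit(spec).total_params``.
    """
    rng = np.random.default_rng(seed)
    weights: list[dict[str, np.ndarray]] = []
    cur: TensorShape = spec.input_shape
    for layer in spec.layers:
        out = infer_output_shape(layer, cur)
        if layer.kind == "conv2d":
            kh, kw, c_in = layer.kernel_h, layer.kernel_w, cur[2]
            fan_in = kh * kw * c_in
            fan_out = kh * kw * layer.n_filters
            W = _glorot_uniform(rng, (kh, kw, c_in, layer.n_filters), fan_in, fan_out)
            weights.append({"W": W, "b": np.zeros(layer.n_filters, dtype=np.float32)})
        elif layer.kind == "dense":
            W = _glorot_uniform(rng, (cur, layer.n_units), cur, layer.n_units)
            weights.append({"W": W, "b": np.zeros(layer.n_units, dtype=np.float32)})
        else:
            weights.append({})
        cur = out
    return ModelState(spec=spec, weights=weights, lineage=[], rng_seed=seed)


def _check_images(spec: ModelSpec, images: np.ndarray) -> np.ndarray:
    x = np.asarray(images, dtype=np.float32)
    h, w, c = spec.input_shape
    if x.ndim == 3:
        x = x[..., None]
    if x.ndim != 4 or x.shape[1:] != (h, w, c):
        raise ValueError(f"images must be (n, {h}, {w}, {c}), got {x.shape}")
    return x


def _forward(state: ModelState, x: np.ndarray, keep_cache: bool = False):
    """Run the stack; returns (output, cache) where cache holds per-layer
    inputs/patches needed for backprop."""
    cache = []
    cur = x
    for layer, w in zip(state.spec.layers, state.weights):
        entry = {"in_shape": cur.shape}
        if layer.kind == "conv2d":
            pre, cols = _conv_forward(cur, w["W"], w["b"], layer.stride)
            out = _FORWARD[layer.activation](pre)
            if keep_cache:
                entry.update(cols=cols, out=out)
        elif layer.kind == "avgpool2d":
            out = _pool_forward(cur, layer.kernel_h, layer.kernel_w, layer.stride)
        elif layer.kind == "flatten":
            out = cur.reshape(cur.shape[0], -1)
        else:  # dense
            pre = cur @ w["W"] + w["b"]
            out = _FORWARD[layer.activation](pre)
            if keep_cache:
                entry.update(x=cur, out=out)
        if keep_cache:
            cache.append(entry)
        cur = out
    return cur, cache


def _backward(state: ModelState, cache, dout):
    """Gradient of the mean loss w.r.t. every weight.

    ``dout`` is the gradient at the *pre-activation* of the final layer
    (softmax + cross-entropy are fused: p - onehot, divided by batch size).
    """
    grads = [None] * len(state.weights)
    layers = state.spec.layers
    g = dout
    at_preact = True  # g currently sits at the last layer's pre-activation
    for i in range(len(layers) - 1, -1, -1):
        layer, w, entry = layers[i], state.weights[i], cache[i]
        if layer.kind == "conv2d":
            if not at_preact:
                g = g * _activation_grad(layer.activation, entry["out"])
            g, dW, db = _conv_backward(g, entry["cols"], entry["in_shape"],
                                       w["W"], layer.stride)
            grads[i] = {"W": dW, "b": db}
        elif layer.kind == "avgpool2d":
            g = _pool_backward(g, entry["in_shape"], layer.kernel_h,
                               layer.kernel_w, layer.stride)
        elif layer.kind == "flatten":
            g = g.reshape(entry["in_shape"])
        else:  # dense
            if not at_preact:
                g = g * _activation_grad(layer.activation, entry["out"])
            grads[i] = {"W": entry["x"].T @ g, "b": g.sum(axis=0)}
            g = g @ w["W"].T
        at_preact = False
    return grads


class _Adam:
    def __init__(self, weights, lr, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in w.items()} for w in weights]
        self.v = [{k: np.zeros_like(v) for k, v in w.items()} for w in weights]

    def step(self, weights, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for w, g, m, v in zip(weights, grads, self.m, self.v):
            if g is None:
                continue
            for k in w:
                gk = g[k].astype(np.float32)
                m[k] = self.b1 * m[k] + (1 - self.b1) * gk
                v[k] = self.b2 * v[k] + (1 - self.b2) * gk * gk
                w[k] -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)


def predict(state: ModelState, images) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels (lowest index wins ties)."""
    x = _check_images(state.spec, images)
    probs = np.empty((len(x), state.spec.output_shapes()[-1]), dtype=np.float64)
    # chunked to bound im2col memory
    for lo in range(0, len(x), 64):
        out, _ = _forward(state, x[lo:lo + 64])
        probs[lo:lo + len(out)] = out
    labels = probs.argmax(axis=1)
    return probs, labels


def evaluate_loss(state: ModelState, images, labels) -> float:
    """Full-batch mean loss; invariant to sample order."""
    probs, _ = predict(state, images)
    return loss(labels, probs)


def train(state: ModelState, train_set, val_set, config: TrainConfig,
          lineage_event: dict | None = None) -> TrainResult:
    """Mini-batch Adam training with early stopping.

    ``train_set``/``val_set`` are ``(images, labels)`` tuples.  Training
    stops when the monitored validation loss has not improved for
    ``early_stopping_patience`` consecutive epochs (or at ``max_epochs``),
    and the best epoch's weights are restored.  The state is modified in
    place and a lineage event is appended.
    """
    x_tr, y_tr = train_set
    x_va, y_va = val_set
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("train and validation sets must be non-empty")
    x_tr = _check_images(state.spec, x_tr)
    x_va = _check_images(state.spec, x_va)
    y_tr = np.asarray(y_tr, dtype=np.int64)
    y_va = np.asarray(y_va, dtype=np.int64)
    n_classes = state.spec.output_shapes()[-1]
    if state.spec.layers[-1].activation != "softmax":
        raise ValueError("training requires a softmax final layer")

    opt = _Adam(state.weights, config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history: dict[str, list[float]] = {k: [] for k in
                                       ("loss", "accuracy", "val_loss", "val_accuracy")}
    best_val = np.inf
    best_epoch = 0
    best_weights = [{k: v.copy() for k, v in w.items()} for w in state.weights]
    bad_epochs = 0
    stopped_epoch = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(x_tr))
        ep_loss = 0.0
        ep_correct = 0
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            probs, cache = _forward(state, xb, keep_cache=True)
            if not np.isfinite(probs).all():
                raise FloatingPointError(
                    f"non-finite network output at epoch {epoch}; "
                    "lower the learning rate or check the input scaling")
            batch_loss = loss(yb, probs)
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate or check the input scaling")
            onehot = np.zeros((len(yb), n_classes), dtype=np.float64)
            onehot[np.arange(len(yb)), yb] = 1.0
            dout = (probs - onehot) / len(yb)
            grads = _backward(state, cache, dout)
            opt.step(state.weights, grads)
            ep_loss += batch_loss * len(yb)
            ep_correct += int((probs.argmax(axis=1) == yb).sum())

        va_probs, va_labels = predict(state, x_va)
        val_loss = loss(y_va, va_probs)
        history["loss"].append(ep_loss / len(x_tr))
        history["accuracy"].append(ep_correct / len(x_tr))
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(float((va_labels == y_va).mean()))
        stopped_epoch = epoch

        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_weights = [{k: v.copy() for k, v in w.items()} for w in state.weights]
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.early_stopping_patience:
                break

    state.weights = best_weights
    event = dict(lineage_event or {"protocol": "adhoc", "iteration": 1, "fold": 0})
    event.update(epochs_run=stopped_epoch, best_epoch=best_epoch,
                 n_train=len(x_tr), n_val=len(x_va))
    state.lineage.append(event)
    return TrainResult(state=state, history=history,
                       stopped_epoch=stopped_epoch, best_epoch=best_epoch)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def _spec_hash(spec: ModelSpec) -> str:
    return hashlib.sha256(spec.to_json().encode()).hexdigest()


def save_state(state: ModelState, path: str | Path) -> Path:
    """Write ``<path>.npz`` (weights) + ``<path>.json`` (spec, lineage, seed)."""
    path = Path(path)
    arrays = {}
    for i, w in enumerate(state.weights):
        for k, v in w.items():
            arrays[f"layer{i}_{k}"] = v
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "spec": json.loads(state.spec.to_json()),
        "spec_hash": _spec_hash(state.spec),
        "lineage": state.lineage,
        "rng_seed": state.rng_seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path.with_suffix(".npz")


def load_state(path: str | Path) -> ModelState:
    """Load a checkpoint, verifying spec/weight consistency."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    npz_path = path.with_suffix(".npz")
    if not sidecar_path.exists() or not npz_path.exists():
        raise CheckpointError(f"missing checkpoint files for {path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
        spec = ModelSpec.from_json(json.dumps(sidecar["spec"]))
    except (KeyError, ValueError) as e:
        raise CheckpointError(f"corrupt checkpoint sidecar: {e}") from e
    if sidecar.get("spec_hash") != _spec_hash(spec):
        raise CheckpointError("spec hash mismatch in checkpoint sidecar")
    with np.load(npz_path) as data:
        fresh = build_model(spec, seed=int(sidecar.get("rng_seed", 0)))
        weights = []
        for i, w in enumerate(fresh.weights):
            loaded = {}
            for k, v in w.items():
                key = f"layer{i}_{k}"
                if key not in data:
                    raise CheckpointError(f"checkpoint missing array {key}")
                arr = data[key]
                if arr.shape != v.shape:
                    raise CheckpointError(
                        f"array {key} has shape {arr.shape}, spec requires {v.shape}")
                loaded[k] = arr
            weights.append(loaded)
    state = ModelState(spec=spec, weights=weights,
                       lineage=list(sidecar.get("lineage", [])),
                       rng_seed=int(sidecar.get("rng_seed", 0)))
    if state.n_parameters() != audit(spec).total_params:
        raise CheckpointError("checkpoint parameter count inconsistent with spec")
    return state
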