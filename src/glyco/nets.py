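"""Small sequence architectures for short-horizon glucose forecasting.

Every model is a *feature block* (sequence encoder) followed by an *FNN
block* (fully connected head), with all learnable parameters partitioned into
exactly these two named groups; the transfer-learning strategies freeze,
reuse, or reinitialize the groups independently.

Architectures and their defaults:

* ``RNN`` — 2 stacked GRU layers of hidden size 10; FNN width 10, 1 layer.
* ``CNN`` — 4 gated convolutional seq2seq units, 1-D kernel size 4, left
  padding (causal), gated-linear-unit activation with residual connections;
  FNN width 10, 3 layers. A learned additive position embedding is applied
  to the 7 input positions.
* ``SAN`` — 8 single-head scaled dot-product self-attention units (model
  dimension 10, residual + layer norm + position-wise feed-forward
  sublayers); FNN width 10, 4 layers. Position embedding as for the CNN.
* ``FNN`` — baseline: linear embedding of the 7 inputs followed by a
  width-10, 3-layer fully connected block.

Heads: ``regression`` (scalar scaled BG), ``binary`` or ``three_class``
(softmax probabilities). Regression losses: MAE, MSE, and their relative
forms REL_MAE = mean(|e|/y) and REL_MSE = mean(e^2/y^2); classification uses
cross-entropy. Training is plain Adam, fully determined by the seed.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .cgm_data import SegmentSet

__all__ = ["ModelSpec", "TrainConfig", "TrainedModel", "build_model",
           "compute_loss", "train", "predict", "ARCHITECTURES", "LOSSES"]

ARCHITECTURES = ("RNN", "CNN", "SAN", "FNN")
LOSSES = ("MAE", "MSE", "REL_MAE", "REL_MSE", "cross_entropy")
GROUPS = ("feature_block", "fnn_block")

_DEFAULT_FNN_LAYERS = {"RNN": 1, "CNN": 3, "SAN": 4, "FNN": 3}
_HEAD_DIM = {"regression": 1, "binary": 2, "three_class": 3}


@dataclass(frozen=True)
class ModelSpec:
    """Architecture descriptor; defaults reproduce the standard sizes above."""

    architecture: str
    head: str = "regression"
    input_len: int = 7
    gru_size: int = 10          # RNN: hidden size per GRU layer
    n_gru: int = 2              # RNN: stacked GRU layers
    kernel_size: int = 4        # CNN: 1-D kernel
    n_conv: int = 4             # CNN: gated conv seq2seq units
    n_attention: int = 8        # SAN: self-attention units
    model_dim: int = 10         # CNN/SAN: embedding width
    fnn_width: int = 10
    fnn_layers: int = -1        # -1 resolves to the per-architecture default
    position_embedding: bool = True

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.head not in _HEAD_DIM:
            raise ValueError(f"unknown head {self.head!r}")
        if self.fnn_layers < 0:
            object.__setattr__(self, "fnn_layers",
                               _DEFAULT_FNN_LAYERS[self.architecture])
        if self.architecture in ("CNN", "SAN") and not self.position_embedding:
            raise ValueError(
                f"{self.architecture} feeds all positions simultaneously and "
                "requires a position embedding")

    @property
    def feature_dim(self) -> int:
        return {"RNN": self.gru_size, "CNN": self.model_dim,
                "SAN": self.model_dim, "FNN": self.fnn_width}[self.architecture]

    @property
    def output_dim(self) -> int:
        return _HEAD_DIM[self.head]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; the seed fully determines initialization-free
    training randomness (shuffling and per-epoch augmentation substreams)."""

    loss: str | None = None     # None: REL_MAE (regression) / cross_entropy
    lr: float = 3e-3
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    augmentation: object | None = None  # an augment.AugmentationPlan

    def resolved_loss(self, head: str) -> str:
        if self.loss is not None:
            if self.loss not in LOSSES:
                raise ValueError(f"unknown loss {self.loss!r}")
            return self.loss
        return "REL_MAE" if head == "regression" else "cross_entropy"


# ---------------------------------------------------------------------------
# parameter initialization
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _init_feature_block(spec: ModelSpec, rng: np.random.Generator) -> dict:
    p: dict[str, np.ndarray] = {}
    if spec.architecture == "RNN":
        for layer in range(spec.n_gru):
            din = 1 if layer == 0 else spec.gru_size
            h = spec.gru_size
            for gate in ("z", "r", "n"):
                p[f"gru{layer}_W{gate}"] = _glorot(rng, din, h)
                p[f"gru{layer}_U{gate}"] = _glorot(rng, h, h)
                p[f"gru{layer}_b{gate}"] = np.zeros(h)
    elif spec.architecture in ("CNN", "SAN"):
        d = spec.model_dim
        p["embed_W"] = _glorot(rng, 1, d)
        if spec.architecture == "SAN":
            # scalar inputs carry little variance into a deep normalized
            # stack; a stronger input projection keeps the sample signal
            # from being swamped by the position embedding
            p["embed_W"] *= 3.0
        p["embed_b"] = np.zeros(d)
        p["pos_embed"] = 0.1 * rng.standard_normal((spec.input_len, d))
        if spec.architecture == "CNN":
            k = spec.kernel_size
            for u in range(spec.n_conv):
                p[f"conv{u}_Wl"] = _glorot(rng, k * d, d)
                p[f"conv{u}_bl"] = np.zeros(d)
                p[f"conv{u}_Wg"] = _glorot(rng, k * d, d)
                p[f"conv{u}_bg"] = np.zeros(d)
        else:
            for u in range(spec.n_attention):
                for name in ("Wq", "Wk", "Wv", "Wo", "Wf1", "Wf2"):
                    p[f"attn{u}_{name}"] = _glorot(rng, d, d)
                # residual branches start small so the 8-unit stack is
                # near-identity at init and the input signal reaches the head
                p[f"attn{u}_Wo"] *= 0.1
                p[f"attn{u}_Wf2"] *= 0.1
                for name in ("bo", "bf1", "bf2"):
                    p[f"attn{u}_{name}"] = np.zeros(d)
                for ln in ("ln1", "ln2"):
                    p[f"attn{u}_{ln}_g"] = np.ones(d)
                    p[f"attn{u}_{ln}_b"] = np.zeros(d)
            p["final_ln_g"] = np.ones(d)
            p["final_ln_b"] = np.zeros(d)
    else:  # FNN baseline: linear embedding of the raw window
        p["embed_W"] = _glorot(rng, spec.input_len, spec.fnn_width)
        p["embed_b"] = np.zeros(spec.fnn_width)
    return p


def _init_fnn_block(spec: ModelSpec, rng: np.random.Generator) -> dict:
    p: dict[str, np.ndarray] = {}
    din = spec.feature_dim
    for layer in range(spec.fnn_layers):
        p[f"fnn{layer}_W"] = _glorot(rng, din, spec.fnn_width)
        p[f"fnn{layer}_b"] = np.zeros(spec.fnn_width)
        din = spec.fnn_width
    p["head_W"] = _glorot(rng, din, spec.output_dim)
    p["head_b"] = np.zeros(spec.output_dim)
    return p


@dataclass
class TrainedModel:
    """A model spec plus its parameters, partitioned into the two groups,
    with per-epoch training-loss history."""

    spec: ModelSpec
    params: dict[str, dict[str, np.ndarray]]
    history: list[float] = field(default_factory=list)
    trainable_groups: tuple[str, ...] = GROUPS

    def copy(self) -> "TrainedModel":
        return TrainedModel(spec=self.spec, params=copy.deepcopy(self.params),
                            history=list(self.history),
                            trainable_groups=tuple(self.trainable_groups))

    def parameter_names(self) -> dict[str, list[str]]:
        return {g: sorted(self.params[g]) for g in GROUPS}

    def save_history_csv(self, path) -> None:
        """Per-epoch training loss as a two-column CSV."""
        import pandas as pd
        pd.DataFrame({"epoch": range(1, len(self.history) + 1),
                      "loss": self.history}).to_csv(path, index=False)

    def save(self, path) -> None:
        arrays = {f"{g}::{k}": v for g in GROUPS for k, v in self.params[g].items()}
        meta = json.dumps({"spec": self.spec.__dict__, "history": self.history,
                           "trainable_groups": list(self.trainable_groups)})
        np.savez(path, __meta__=np.array(meta), **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            params: dict[str, dict[str, np.ndarray]] = {g: {} for g in GROUPS}
            for key in data.files:
                if key == "__meta__":
                    continue
                group, name = key.split("::", 1)
                params[group][name] = data[key]
        return cls(spec=ModelSpec(**meta["spec"]), params=params,
                   history=meta["history"],
                   trainable_groups=tuple(meta["trainable_groups"]))


def build_model(spec: ModelSpec, seed: int = 0) -> TrainedModel:
    """Initialize an untrained model; identical seeds give identical bits."""
    rng = np.random.default_rng(seed)
    params = {"feature_block": _init_feature_block(spec, rng),
              "fnn_block": _init_fnn_block(spec, rng)}
    return TrainedModel(spec=spec, params=params)


def reinitialize_group(model: TrainedModel, group: str, seed: int) -> None:
    """Replace one parameter group with a fresh random initialization."""
    rng = np.random.default_rng(seed)
    if group == "feature_block":
        model.params[group] = _init_feature_block(model.spec, rng)
    elif group == "fnn_block":
        model.params[group] = _init_fnn_block(model.spec, rng)
    else:
        raise ValueError(f"unknown parameter group {group!r}")


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

def _layer_norm(x: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (var + 1e-5).sqrt() * gamma + beta


def _gru_stack(spec: ModelSpec, t: dict, X: Tensor) -> Tensor:
    n = X.shape[0]
    seq = [X[:, i:i + 1] for i in range(spec.input_len)]
    for layer in range(spec.n_gru):
        h = Tensor(np.zeros((n, spec.gru_size)))
        out = []
        for x in seq:
            z = (x @ t[f"gru{layer}_Wz"] + h @ t[f"gru{layer}_Uz"]
                 + t[f"gru{layer}_bz"]).sigmoid()
            r = (x @ t[f"gru{layer}_Wr"] + h @ t[f"gru{layer}_Ur"]
                 + t[f"gru{layer}_br"]).sigmoid()
            cand = (x @ t[f"gru{layer}_Wn"] + (r * h) @ t[f"gru{layer}_Un"]
                    + t[f"gru{layer}_bn"]).tanh()
            h = (Tensor(1.0) - z) * cand + z * h
            out.append(h)
        seq = out
    return seq[-1]  # last hidden state of the top layer


def _embed_positions(spec: ModelSpec, t: dict, X: Tensor) -> Tensor:
    n = X.shape[0]
    flat = X.reshape(n * spec.input_len, 1)
    emb = (flat @ t["embed_W"] + t["embed_b"]).reshape(n, spec.input_len,
                                                       spec.model_dim)
    return emb + t["pos_embed"]


def _gated_conv_stack(spec: ModelSpec, t: dict, X: Tensor) -> Tensor:
    h = _embed_positions(spec, t, X)
    n, L, d, k = X.shape[0], spec.input_len, spec.model_dim, spec.kernel_size
    for u in range(spec.n_conv):
        pad = Tensor(np.zeros((n, k - 1, d)))
        padded = ad.concatenate([pad, h], axis=1)
        cols = []
        for pos in range(L):
            win = padded[:, pos:pos + k, :].reshape(n, k * d)
            lin = win @ t[f"conv{u}_Wl"] + t[f"conv{u}_bl"]
            gate = (win @ t[f"conv{u}_Wg"] + t[f"conv{u}_bg"]).sigmoid()
            cols.append(lin * gate)
        h = ad.stack(cols, axis=1) + h  # residual
    return h[:, L - 1, :]  # last (causal) position sees the whole window


def _attention_stack(spec: ModelSpec, t: dict, X: Tensor) -> Tensor:
    h = _embed_positions(spec, t, X)
    scale = 1.0 / np.sqrt(spec.model_dim)
    for u in range(spec.n_attention):
        # pre-norm residual stream: normalization feeds each sublayer while
        # the residual path carries the raw signal through all 8 units
        hn = _layer_norm(h, t[f"attn{u}_ln1_g"], t[f"attn{u}_ln1_b"])
        q = hn @ t[f"attn{u}_Wq"]
        k = hn @ t[f"attn{u}_Wk"]
        v = hn @ t[f"attn{u}_Wv"]
        attn = ad.softmax(q @ k.swapaxes(-1, -2) * scale, axis=-1)
        h = h + (attn @ v) @ t[f"attn{u}_Wo"] + t[f"attn{u}_bo"]
        hn = _layer_norm(h, t[f"attn{u}_ln2_g"], t[f"attn{u}_ln2_b"])
        h = h + (hn @ t[f"attn{u}_Wf1"] + t[f"attn{u}_bf1"]).relu() \
            @ t[f"attn{u}_Wf2"] + t[f"attn{u}_bf2"]
    h = _layer_norm(h, t["final_ln_g"], t["final_ln_b"])
    return h.mean(axis=1)


def _forward(spec: ModelSpec, tensors: dict[str, dict[str, Tensor]],
             X: np.ndarray) -> Tensor:
    """Raw head output: (n,) for regression, (n, C) logits for class heads."""
    feat_t, fnn_t = tensors["feature_block"], tensors["fnn_block"]
    Xt = Tensor(X)
    if spec.architecture == "RNN":
        feat = _gru_stack(spec, feat_t, Xt)
    elif spec.architecture == "CNN":
        feat = _gated_conv_stack(spec, feat_t, Xt)
    elif spec.architecture == "SAN":
        feat = _attention_stack(spec, feat_t, Xt)
    else:
        feat = (Xt @ feat_t["embed_W"] + feat_t["embed_b"]).tanh()
    z = feat
    for layer in range(spec.fnn_layers):
        z = (z @ fnn_t[f"fnn{layer}_W"] + fnn_t[f"fnn{layer}_b"]).tanh()
    out = z @ fnn_t["head_W"] + fnn_t["head_b"]
    if spec.head == "regression":
        out = out.reshape(X.shape[0])
    return out


def _as_tensors(model: TrainedModel, trainable: set[str]) -> dict:
    return {g: {k: Tensor(v, requires_grad=(g in trainable))
                for k, v in model.params[g].items()} for g in GROUPS}


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def compute_loss(kind: str, predictions, truths) -> float:
    """Scalar loss value on plain arrays (reporting path, not the graph).

    Regression kinds take value vectors; ``cross_entropy`` takes (n, C)
    class probabilities and integer labels.
    """
    if kind not in LOSSES:
        raise ValueError(f"unknown loss {kind!r}")
    pred = np.asarray(predictions, dtype=np.float64)
    if kind == "cross_entropy":
        labels = np.asarray(truths, dtype=np.int64)
        if pred.ndim != 2 or pred.shape[0] != labels.size:
            raise ValueError("cross_entropy expects (n, C) probabilities")
        p = np.clip(pred[np.arange(labels.size), labels], 1e-12, None)
        return float(-np.mean(np.log(p)))
    true = np.asarray(truths, dtype=np.float64)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth vectors differ in shape")
    if kind in ("REL_MAE", "REL_MSE") and np.any(true <= 0):
        raise ValueError("relative losses require strictly positive truths")
    err = pred - true
    if kind == "MAE":
        return float(np.mean(np.abs(err)))
    if kind == "MSE":
        return float(np.mean(err ** 2))
    if kind == "REL_MAE":
        return float(np.mean(np.abs(err) / true))
    return float(np.mean(err ** 2 / true ** 2))


def _loss_tensor(kind: str, out: Tensor, y: np.ndarray) -> Tensor:
    if kind == "cross_entropy":
        logp = ad.log_softmax(out, axis=-1)
        picked = logp[np.arange(y.size), y.astype(np.int64)]
        return -picked.mean()
    yt = Tensor(y)
    if kind == "MAE":
        return (out - yt).abs().mean()
    if kind == "MSE":
        return ((out - yt) ** 2).mean()
    if kind == "REL_MAE":
        return ((out - yt).abs() / yt).mean()
    if kind == "REL_MSE":
        return (((out - yt) / yt) ** 2).mean()
    raise ValueError(f"unknown loss {kind!r}")


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------

def train(model: TrainedModel, train_segments: SegmentSet,
          config: TrainConfig) -> TrainedModel:
    """Adam-train a copy of ``model``; only trainable groups are updated.

    With an augmentation plan in the config, the augmented training set is
    rebuilt at the start of every epoch (synthetic minority copies are
    redrawn when the plan regenerates per epoch). Deterministic given
    (model, data, config).
    """
    from .augment import build_augmented_training_set  # local: avoids cycle

    if len(train_segments) == 0:
        raise ValueError("training set is empty")
    loss_kind = config.resolved_loss(model.spec.head)
    classification = model.spec.head != "regression"
    if classification and train_segments.labels is None:
        raise ValueError("classification heads need labeled segments")
    if loss_kind in ("REL_MAE", "REL_MSE") and np.any(train_segments.targets <= 0):
        raise ValueError("relative losses require strictly positive targets")

    out = model.copy()
    trainable = set(out.trainable_groups)
    if not trainable:
        return out  # evaluation-only (no fine-tuning) path

    rng = np.random.default_rng(config.seed)
    m_state: dict[tuple[str, str], np.ndarray] = {}
    v_state: dict[tuple[str, str], np.ndarray] = {}
    step = 0
    for epoch in range(config.epochs):
        data = train_segments
        if config.augmentation is not None:
            data = build_augmented_training_set(train_segments,
                                                config.augmentation, epoch)
        X = data.inputs
        y = data.labels if classification else data.targets
        perm = rng.permutation(len(data))
        epoch_loss, seen = 0.0, 0
        for start in range(0, len(data), config.batch_size):
            idx = perm[start:start + config.batch_size]
            tensors = _as_tensors(out, trainable)
            pred = _forward(out.spec, tensors, X[idx])
            loss = _loss_tensor(loss_kind, pred, y[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            step += 1
            bc1 = 1.0 - config.beta1 ** step
            bc2 = 1.0 - config.beta2 ** step
            for g in trainable:
                for name, tensor in tensors[g].items():
                    grad = tensor.grad
                    if grad is None:
                        continue
                    key = (g, name)
                    if key not in m_state:
                        m_state[key] = np.zeros_like(grad)
                        v_state[key] = np.zeros_like(grad)
                    m_state[key] = config.beta1 * m_state[key] + (1 - config.beta1) * grad
                    v_state[key] = config.beta2 * v_state[key] + (1 - config.beta2) * grad ** 2
                    update = (m_state[key] / bc1) / (np.sqrt(v_state[key] / bc2)
                                                     + config.eps)
                    out.params[g][name] = out.params[g][name] - config.lr * update
            epoch_loss += float(loss.data) * len(idx)
            seen += len(idx)
        out.history.append(epoch_loss / seen)
    return out


def predict(model: TrainedModel, segments: SegmentSet) -> np.ndarray:
    """Deterministic forward pass: (n,) scaled BG for regression heads,
    (n, C) class probabilities for classification heads."""
    if len(segments) == 0:
        dim = model.spec.output_dim
        return np.empty((0,) if model.spec.head == "regression" else (0, dim))
    tensors = _as_tensors(model, trainable=set())
    out = _forward(model.spec, tensors, segments.inputs)
    if model.spec.head == "regression":
        return out.data.copy()
    return ad.softmax(out, axis=-1).data.copy()
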