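"""Minority-class-only training-data augmentation for hypoglycemia detection.

Hypoglycemic segments (target BG < 80 mg/dL) are the rare class in CGM data.
The four schemes here enlarge only that class, leaving majority segments
bitwise untouched; ``fold_k`` is the multiplier of the minority count after
augmentation (originals plus k-1 generated copies per original):

* ``repeat`` — exact duplication (k copies total of each minority segment);
* ``noise`` — Gaussian white noise of a given variance (in (mg/dL)^2) added
  to the 7 input values only, target and label unchanged;
* ``mixup`` — convex combination of two minority segments, inputs and target
  alike, with weight lambda ~ Beta(alpha, alpha); because both parents have
  targets below the threshold, every synthetic target does too;
* ``timegan`` — a reduced-scale time-series GAN (embedding/recovery
  reconstruction phase, supervised next-step phase, joint adversarial phase)
  trained on the minority sequences, sampled for synthetic copies.

Augmented sets can be regenerated each epoch from epoch-indexed substreams of
the plan seed, so synthetic minority data is fresh every epoch while the run
remains reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from . import _autodiff as ad
from ._autodiff import Tensor
from .cgm_data import SegmentSet, classify_bg
from .seeds import substream as _substream

__all__ = ["AugmentationPlan", "TimeGANConfig", "TimeGANGenerator",
           "select_minority", "oversample_repeat", "noise_augment",
           "mixup_augment", "timegan_fit", "timegan_validate",
           "build_augmented_training_set"]

METHODS = ("none", "repeat", "noise", "mixup", "timegan")


@dataclass(frozen=True)
class TimeGANConfig:
    """Reduced-scale TimeGAN sizes, small enough for CPU training on short
    univariate glucose sequences."""

    latent_dim: int = 4
    hidden_dim: int = 24
    num_layers: int = 3
    iterations_embedding: int = 500
    iterations_supervised: int = 500
    iterations_joint: int = 500
    batch_size: int = 32
    lr: float = 1e-3
    seed: int = 0


@dataclass
class AugmentationPlan:
    """Declarative description of minority augmentation during training."""

    method: str = "none"
    fold_k: int = 1
    noise_variance: float = 10.0   # (mg/dL)^2
    alpha: float = 2.0             # Beta(alpha, alpha) shape for mixup
    minority_threshold: float = 80.0
    regenerate_each_epoch: bool = True
    seed: int = 0
    timegan: TimeGANConfig = field(default_factory=TimeGANConfig)
    _generator: "TimeGANGenerator | None" = field(default=None, repr=False,
                                                  compare=False)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown augmentation method {self.method!r}")
        if self.fold_k < 1:
            raise ValueError("fold_k must be >= 1")

    def describe(self) -> str:
        if self.method == "none" or self.fold_k == 1:
            return "none"
        extra = {"noise": f", var={self.noise_variance:g}",
                 "mixup": f", alpha={self.alpha:g}"}.get(self.method, "")
        return f"{self.method}(k={self.fold_k}{extra})"


def select_minority(segments: SegmentSet,
                    threshold: float = 80.0) -> tuple[SegmentSet, SegmentSet]:
    """Disjoint exhaustive split into (minority, majority) by target BG."""
    is_minority = segments.targets_mgdl < threshold
    return segments.subset(is_minority), segments.subset(~is_minority)


def oversample_repeat(minority: SegmentSet, k: int) -> SegmentSet:
    """k exact copies of every minority segment (k=1 is the identity)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1 or len(minority) == 0:
        return minority.subset(slice(None))
    return SegmentSet.concat([minority] * k)


def noise_augment(minority: SegmentSet, variance: float, seed: int) -> SegmentSet:
    """One synthetic copy per minority segment with i.i.d. zero-mean Gaussian
    noise of the given variance (mg/dL scale) added to the inputs only."""
    if variance < 0:
        raise ValueError("noise variance must be non-negative")
    rng = np.random.default_rng(seed)
    noise_mgdl = rng.normal(0.0, np.sqrt(variance), size=minority.inputs.shape)
    return replace(minority, inputs=minority.inputs + noise_mgdl * minority.scale,
                   targets=minority.targets.copy())


def mixup_augment(minority: SegmentSet, k: int, alpha: float,
                  seed: int) -> SegmentSet:
    """(k-1)*n synthetic segments by convex interpolation of minority pairs.

    Each synthetic segment draws lambda ~ Beta(alpha, alpha) and a uniform
    pair (i, j), i != j, and forms x = lam*x_i + (1-lam)*x_j elementwise,
    y = lam*y_i + (1-lam)*y_j. Both parents satisfy the minority predicate,
    so the synthetic target does too (convexity preserves the label).
    """
    if len(minority) < 2:
        raise ValueError("mixup needs at least 2 minority segments")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if k < 2:
        raise ValueError("mixup k must be >= 2 (k-1 synthetic copies)")
    rng = np.random.default_rng(seed)
    n = len(minority)
    m = (k - 1) * n
    i = rng.integers(0, n, size=m)
    j = rng.integers(0, n - 1, size=m)
    j[j >= i] += 1  # uniform over pairs with i != j
    lam = rng.beta(alpha, alpha, size=m)
    inputs = lam[:, None] * minority.inputs[i] + (1 - lam[:, None]) * minority.inputs[j]
    targets = lam * minority.targets[i] + (1 - lam) * minority.targets[j]
    labels = None if minority.labels is None else minority.labels[i].copy()
    return SegmentSet(inputs=inputs, targets=targets,
                      horizon_minutes=minority.horizon_minutes,
                      patient_ids=minority.patient_ids[i].copy(),
                      start_indices=minority.start_indices[i].copy(),
                      labels=labels, scheme=minority.scheme, scale=minority.scale)


# ---------------------------------------------------------------------------
# TimeGAN (reduced scale)
# ---------------------------------------------------------------------------

def _gru_params(rng: np.random.Generator, prefix: str, input_dim: int,
                hidden: int, layers: int) -> dict[str, np.ndarray]:
    p = {}
    for layer in range(layers):
        din = input_dim if layer == 0 else hidden
        limit = np.sqrt(6.0 / (din + hidden))
        for gate in ("z", "r", "n"):
            p[f"{prefix}{layer}_W{gate}"] = rng.uniform(-limit, limit, (din, hidden))
            p[f"{prefix}{layer}_U{gate}"] = rng.uniform(
                -np.sqrt(3.0 / hidden), np.sqrt(3.0 / hidden), (hidden, hidden))
            p[f"{prefix}{layer}_b{gate}"] = np.zeros(hidden)
    return p


def _gru_run(t: dict[str, Tensor], prefix: str, X: Tensor, hidden: int,
             layers: int) -> Tensor:
    """Stacked GRU over X (n, L, din); returns all top-layer states (n, L, h)."""
    n, L = X.shape[0], X.shape[1]
    seq = [X[:, step, :] for step in range(L)]
    for layer in range(layers):
        h = Tensor(np.zeros((n, hidden)))
        out = []
        for x in seq:
            z = (x @ t[f"{prefix}{layer}_Wz"] + h @ t[f"{prefix}{layer}_Uz"]
                 + t[f"{prefix}{layer}_bz"]).sigmoid()
            r = (x @ t[f"{prefix}{layer}_Wr"] + h @ t[f"{prefix}{layer}_Ur"]
                 + t[f"{prefix}{layer}_br"]).sigmoid()
            cand = (x @ t[f"{prefix}{layer}_Wn"] + (r * h) @ t[f"{prefix}{layer}_Un"]
                    + t[f"{prefix}{layer}_bn"]).tanh()
            h = (Tensor(1.0) - z) * cand + z * h
            out.append(h)
        seq = out
    return ad.stack(seq, axis=1)


def _linear_params(rng, prefix: str, din: int, dout: int) -> dict[str, np.ndarray]:
    limit = np.sqrt(6.0 / (din + dout))
    return {f"{prefix}_W": rng.uniform(-limit, limit, (din, dout)),
            f"{prefix}_b": np.zeros(dout)}


@dataclass
class TimeGANGenerator:
    """Fitted sampler for synthetic minority sequences (original units)."""

    config: TimeGANConfig
    params: dict[str, np.ndarray]
    seq_len: int
    data_min: float
    data_max: float

    def sample(self, n: int, seed: int) -> np.ndarray:
        """Draw n synthetic sequences; deterministic per seed."""
        cfg = self.config
        rng = np.random.default_rng(seed)
        z = rng.uniform(0.0, 1.0, size=(n, self.seq_len, cfg.latent_dim))
        t = {k: Tensor(v) for k, v in self.params.items()}
        e_hat = _run_block(t, "gen", Tensor(z), cfg)
        h_hat = _run_block(t, "sup", e_hat, cfg)
        x_hat = (h_hat @ t["rec_W"] + t["rec_b"]).sigmoid()
        x = x_hat.data[:, :, 0]
        return x * (self.data_max - self.data_min) + self.data_min


def _run_block(t, prefix: str, X: Tensor, cfg: TimeGANConfig) -> Tensor:
    h = _gru_run(t, prefix, X, cfg.hidden_dim, cfg.num_layers)
    return (h @ t[f"{prefix}_out_W"] + t[f"{prefix}_out_b"]).sigmoid()


def _adam_step(params, grads, state, lr, step, b1=0.9, b2=0.999, eps=1e-8):
    for name, g in grads.items():
        if name not in state:
            state[name] = (np.zeros_like(g), np.zeros_like(g))
        m, v = state[name]
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g ** 2
        state[name] = (m, v)
        mh = m / (1 - b1 ** step)
        vh = v / (1 - b2 ** step)
        params[name] = params[name] - lr * mh / (np.sqrt(vh) + eps)


def _grads_of(tensors: dict[str, Tensor], names) -> dict[str, np.ndarray]:
    return {n: tensors[n].grad for n in names if tensors[n].grad is not None}


def timegan_fit(minority_sequences: np.ndarray,
                config: TimeGANConfig | None = None) -> TimeGANGenerator:
    """Train the three-phase TimeGAN on (n, L) univariate minority sequences.

    Phase 1 trains the embedder/recovery autoencoder (reconstruction MSE);
    phase 2 trains the supervisor to predict the next embedded step on real
    data; phase 3 trains generator + supervisor adversarially against the
    discriminator, with moment matching on the recovered synthetic batch,
    while the autoencoder keeps adapting. Deterministic per config seed.
    """
    cfg = config or TimeGANConfig()
    X = np.asarray(minority_sequences, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("minority sequences must be a (n, length) array")
    if X.shape[0] < 50:
        raise ValueError(
            "TimeGAN needs at least 50 minority sequences; with fewer, prefer "
            "noise or mixup augmentation")
    lo, hi = float(X.min()), float(X.max())
    span = hi - lo if hi > lo else 1.0
    Xn = ((X - lo) / span)[:, :, None]  # (n, L, 1) in [0, 1]
    n, L = X.shape
    rng = np.random.default_rng(cfg.seed)

    params: dict[str, np.ndarray] = {}
    params.update(_gru_params(rng, "emb", 1, cfg.hidden_dim, cfg.num_layers))
    params.update(_linear_params(rng, "emb_out", cfg.hidden_dim, cfg.hidden_dim))
    params.update(_linear_params(rng, "rec", cfg.hidden_dim, 1))
    params.update(_gru_params(rng, "gen", cfg.latent_dim, cfg.hidden_dim,
                              cfg.num_layers))
    params.update(_linear_params(rng, "gen_out", cfg.hidden_dim, cfg.hidden_dim))
    params.update(_gru_params(rng, "sup", cfg.hidden_dim, cfg.hidden_dim,
                              cfg.num_layers))
    params.update(_linear_params(rng, "sup_out", cfg.hidden_dim, cfg.hidden_dim))
    params.update(_gru_params(rng, "dis", cfg.hidden_dim, cfg.hidden_dim,
                              cfg.num_layers))
    params.update(_linear_params(rng, "dis_out", cfg.hidden_dim, 1))

    group = {name: name.split("_")[0][:3] for name in params}
    ae_names = [k for k in params if group[k] in ("emb", "rec")]
    sup_names = [k for k in params if group[k] == "sup"]
    gen_names = [k for k in params if group[k] == "gen"]
    dis_names = [k for k in params if group[k] == "dis"]

    def batch():
        idx = rng.integers(0, n, size=min(cfg.batch_size, n))
        return Xn[idx]

    def tensors(trainable_names):
        return {k: Tensor(v, requires_grad=(k in trainable_names))
                for k, v in params.items()}

    def embed(t, xb):
        return _run_block(t, "emb", Tensor(xb) if isinstance(xb, np.ndarray) else xb,
                          cfg)

    def bce(logits: Tensor, target_is_real: bool) -> Tensor:
        # -log sigmoid(l) for real, -log(1 - sigmoid(l)) for fake
        p = logits.sigmoid()
        return -(p.log().mean() if target_is_real
                 else (Tensor(1.0) - p).log().mean())

    state: dict[str, tuple] = {}
    step = 0
    # phase 1: reconstruction
    for _ in range(cfg.iterations_embedding):
        xb = batch()
        t = tensors(ae_names)
        h = embed(t, xb)
        x_tilde = (h @ t["rec_W"] + t["rec_b"]).sigmoid()
        loss = ((x_tilde - Tensor(xb)) ** 2).mean()
        loss.backward()
        step += 1
        _adam_step(params, _grads_of(t, ae_names), state, cfg.lr, step)

    # phase 2: supervised next-step on real embeddings
    for _ in range(cfg.iterations_supervised):
        xb = batch()
        t = tensors(sup_names)
        h = embed(t, xb)
        h_sup = _run_block(t, "sup", h, cfg)
        loss = ((h_sup[:, :-1, :] - h[:, 1:, :]) ** 2).mean()
        loss.backward()
        step += 1
        _adam_step(params, _grads_of(t, sup_names), state, cfg.lr, step)

    # phase 3: joint adversarial training
    for _ in range(cfg.iterations_joint):
        # generator + supervisor
        xb = batch()
        z = rng.uniform(0.0, 1.0, size=(len(xb), L, cfg.latent_dim))
        t = tensors(set(gen_names) | set(sup_names))
        h_real = embed(t, xb)
        e_hat = _run_block(t, "gen", Tensor(z), cfg)
        h_hat = _run_block(t, "sup", e_hat, cfg)
        logits_fake = _gru_run(t, "dis", h_hat, cfg.hidden_dim, cfg.num_layers) \
            @ t["dis_out_W"] + t["dis_out_b"]
        g_adv = bce(logits_fake, target_is_real=True)
        g_sup = ((_run_block(t, "sup", h_real, cfg)[:, :-1, :]
                  - h_real[:, 1:, :]) ** 2).mean()
        x_hat = (h_hat @ t["rec_W"] + t["rec_b"]).sigmoid()
        mu_g = x_hat.mean(axis=(0, 1))
        mu_r = float(xb.mean())
        var_g = ((x_hat - mu_g) ** 2).mean(axis=(0, 1))
        var_r = float(xb.var())
        g_mom = (mu_g - Tensor(mu_r)).abs().mean() \
            + ((var_g + 1e-6).sqrt() - Tensor(np.sqrt(var_r + 1e-6))).abs().mean()
        loss_g = g_adv + Tensor(10.0) * g_sup + Tensor(10.0) * g_mom
        loss_g.backward()
        step += 1
        _adam_step(params, _grads_of(t, list(gen_names) + list(sup_names)),
                   state, cfg.lr, step)

        # embedder/recovery keeps adapting
        t = tensors(ae_names)
        h = embed(t, xb)
        x_tilde = (h @ t["rec_W"] + t["rec_b"]).sigmoid()
        h_sup = _run_block(t, "sup", h, cfg)
        loss_e = ((x_tilde - Tensor(xb)) ** 2).mean() \
            + Tensor(0.1) * ((h_sup[:, :-1, :] - h[:, 1:, :]) ** 2).mean()
        loss_e.backward()
        step += 1
        _adam_step(params, _grads_of(t, ae_names), state, cfg.lr, step)

        # discriminator
        t = tensors(dis_names)
        h_real = embed(t, xb)
        e_hat = _run_block(t, "gen", Tensor(z), cfg)
        h_hat = _run_block(t, "sup", e_hat, cfg)
        lr_real = _gru_run(t, "dis", h_real, cfg.hidden_dim, cfg.num_layers) \
            @ t["dis_out_W"] + t["dis_out_b"]
        lr_fake = _gru_run(t, "dis", h_hat, cfg.hidden_dim, cfg.num_layers) \
            @ t["dis_out_W"] + t["dis_out_b"]
        loss_d = bce(lr_real, True) + bce(lr_fake, False)
        loss_d.backward()
        step += 1
        _adam_step(params, _grads_of(t, dis_names), state, cfg.lr, step)

    return TimeGANGenerator(config=cfg, params=params, seq_len=L,
                            data_min=lo, data_max=lo + span)


def timegan_validate(real: np.ndarray, synthetic: np.ndarray) -> dict:
    """Quantitative distribution check between real and synthetic sequences.

    Reports per-dimension mean and s.d. gaps standardized by the real s.d.,
    and a two-sample energy-distance statistic normalized by the mean
    within-real pairwise distance. Flags failure when the standardized mean
    gap exceeds 1.0 or the normalized energy distance exceeds 0.5.
    """
    r = np.asarray(real, dtype=np.float64)
    s = np.asarray(synthetic, dtype=np.float64)
    if r.size == 0 or s.size == 0 or r.ndim != 2 or s.shape[1] != r.shape[1]:
        raise ValueError("real and synthetic must be non-empty (n, L) arrays")
    sd_r = r.std(axis=0, ddof=0) + 1e-9
    mean_gap = np.abs(s.mean(axis=0) - r.mean(axis=0)) / sd_r
    sd_gap = np.abs(s.std(axis=0, ddof=0) - r.std(axis=0, ddof=0)) / sd_r
    d_rs = cdist(r, s).mean()
    d_rr = cdist(r, r).mean()
    d_ss = cdist(s, s).mean()
    energy = 2 * d_rs - d_rr - d_ss
    energy_norm = energy / (d_rr + 1e-9)
    ok = bool(mean_gap.max() <= 1.0 and energy_norm <= 0.5)
    return {"mean_gap": mean_gap, "sd_gap": sd_gap,
            "max_mean_gap": float(mean_gap.max()),
            "max_sd_gap": float(sd_gap.max()),
            "energy_distance": float(energy),
            "energy_distance_normalized": float(energy_norm),
            "ok": ok}


# ---------------------------------------------------------------------------
# plan application
# ---------------------------------------------------------------------------

def build_augmented_training_set(train_segments: SegmentSet,
                                 plan: AugmentationPlan,
                                 epoch_index: int = 0) -> SegmentSet:
    """Apply the plan for one epoch: majority untouched, minority count
    multiplied exactly by fold_k (originals kept, k-1 generated copies).

    When the plan regenerates each epoch, synthetic copies are drawn from an
    epoch-indexed substream of the plan seed; otherwise epoch 0's draw is
    reused. TimeGAN is fitted lazily once per plan (on 8-step sequences of
    the 7 inputs followed by the target) and only sampled per epoch.
    """
    if plan.method == "none" or plan.fold_k == 1:
        return train_segments
    minority, majority = select_minority(train_segments, plan.minority_threshold)
    if len(minority) == 0:
        return train_segments
    k = plan.fold_k
    epoch_key = epoch_index if plan.regenerate_each_epoch else 0
    seed = _substream(plan.seed, epoch_key)

    method = plan.method
    # generative methods need enough minority parents; degenerate training
    # sets degrade to exact repetition, which keeps the k-fold arithmetic
    if (method == "mixup" and len(minority) < 2) or \
            (method == "timegan" and plan._generator is None
             and len(minority) < 50):
        method = "repeat"

    if method == "repeat":
        aug = oversample_repeat(minority, k)
    elif method == "noise":
        copies = [noise_augment(minority, plan.noise_variance,
                                _substream(plan.seed, epoch_key, c))
                  for c in range(k - 1)]
        aug = SegmentSet.concat([minority] + copies)
    elif method == "mixup":
        aug = SegmentSet.concat([minority, mixup_augment(minority, k, plan.alpha,
                                                         seed)])
    else:  # timegan
        if plan._generator is None:
            seqs = np.column_stack([minority.inputs, minority.targets]) / minority.scale
            cfg = replace(plan.timegan, seed=_substream(plan.seed, 104729))
            plan._generator = timegan_fit(seqs, cfg)
        m = (k - 1) * len(minority)
        sampled = plan._generator.sample(m, seed)  # mg/dL
        inputs = sampled[:, :-1] * minority.scale
        targets = sampled[:, -1] * minority.scale
        labels = None
        if minority.scheme is not None:
            hyper = 180.0 if minority.scheme == "three_class" else None
            labels = classify_bg(sampled[:, -1], plan.minority_threshold,
                                 hyper if hyper is not None else 180.0,
                                 minority.scheme)
        reps = np.resize(np.arange(len(minority)), m)
        synth = SegmentSet(inputs=inputs, targets=targets,
                           horizon_minutes=minority.horizon_minutes,
                           patient_ids=minority.patient_ids[reps].copy(),
                           start_indices=minority.start_indices[reps].copy(),
                           labels=labels, scheme=minority.scheme,
                           scale=minority.scale)
        aug = SegmentSet.concat([minority, synth])
    return SegmentSet.concat([majority, aug])
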