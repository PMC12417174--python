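"""Skip-GRU classifier: a jump-gate MLP in front of a GRU cell.

Each selected tabular feature is one timestep of a scalar-input sequence.
Before a feature enters the GRU, a small two-layer perceptron (the *skip
network*) computes a keep probability pi_t from [x_t; h_{t-1}]:

    S_t  = ReLU(W1 [x_t; h_{t-1}] + b1)
    pi_t = softmax(W2 S_t + b2)[keep]

At inference (*hard* mode) a feature with pi_t below the skip threshold is
ignored and the hidden state carries over unchanged, h_t = h_{t-1}.  For
training the hard threshold is relaxed (*soft* mode) to the differentiable

    h_t = pi_t * GRU(x_t, h_{t-1}) + (1 - pi_t) * h_{t-1}

so gradients flow through the gate.  The GRU cell is the standard
reset/update-gate recurrence

    r_t = sigma(W_r [h_{t-1}, x_t] + b_r)
    z_t = sigma(W_z [h_{t-1}, x_t] + b_z)
    hc_t = tanh(W [r_t * h_{t-1}, x_t] + b)
    h_t = (1 - z_t) * h_{t-1} + z_t * hc_t

and an affine+softmax head maps h_T to class probabilities.  Training
minimizes cross-entropy with Adam under decoupled weight decay, inverted
dropout on the hidden state between timesteps (training only), and
clip-by-norm gradient clipping: when the global gradient norm exceeds the
threshold eta_c every gradient is scaled by eta_c / norm, preserving the
gradient direction while bounding the update — the guard against
exploding gradients in recurrent training.

All forward/backward passes are plain NumPy with gradients derived by
backpropagation through time; correctness is pinned by finite-difference
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SkipGRUConfig
from .dataset import TabularDataset
from .mpa import FeatureMask
from .reports import register_report

__all__ = [
    "SkipNetworkParams",
    "GRUParams",
    "HeadParams",
    "SkipGRUModel",
    "ForwardTrace",
    "TrainingHistory",
    "init_model",
    "jump_probability",
    "gru_cell",
    "forward",
    "forward_batch",
    "loss_and_grads",
    "clip_gradients",
    "global_norm",
    "train",
    "predict",
    "gate_importance",
]


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------
@register_report
@dataclass
class SkipNetworkParams:
    """Two-layer jump gate: input [x_t; h_prev; onehot(t)] -> 2 logits
    (keep, skip).

    The gate is shared across timesteps; the one-hot feature-position
    input is what lets the shared gate learn *feature-specific* keep
    probabilities — the per-feature relevance read-out requires the gate
    to know which feature it is looking at.  A gate built with
    ``W1`` of width ``1 + hidden`` (no positional block) is also accepted
    and then sees only [x_t; h_prev].
    """

    W1: np.ndarray  # (gate_hidden, 1 + hidden [+ n_positions])
    b1: np.ndarray  # (gate_hidden,)
    W2: np.ndarray  # (2, gate_hidden)
    b2: np.ndarray  # (2,)


@register_report
@dataclass
class GRUParams:
    """Gate and candidate weights over the concatenation [h_prev, x_t]."""

    W_r: np.ndarray  # (hidden, hidden + 1)
    b_r: np.ndarray
    W_z: np.ndarray
    b_z: np.ndarray
    W: np.ndarray
    b: np.ndarray


@register_report
@dataclass
class HeadParams:
    W: np.ndarray  # (n_classes, hidden)
    b: np.ndarray  # (n_classes,)


@register_report
@dataclass
class SkipGRUModel:
    skip: SkipNetworkParams
    gru: GRUParams
    head: HeadParams
    feature_order: tuple[str, ...]
    config: SkipGRUConfig

    def __post_init__(self) -> None:
        self.feature_order = tuple(self.feature_order)

    @property
    def hidden_size(self) -> int:
        return self.gru.b_r.size

    @property
    def n_classes(self) -> int:
        return self.head.b.size

    def params(self) -> dict[str, np.ndarray]:
        """Flat name -> array view of all trainable parameters (shared memory)."""
        return {
            "skip.W1": self.skip.W1, "skip.b1": self.skip.b1,
            "skip.W2": self.skip.W2, "skip.b2": self.skip.b2,
            "gru.W_r": self.gru.W_r, "gru.b_r": self.gru.b_r,
            "gru.W_z": self.gru.W_z, "gru.b_z": self.gru.b_z,
            "gru.W": self.gru.W, "gru.b": self.gru.b,
            "head.W": self.head.W, "head.b": self.head.b,
        }


@dataclass
class ForwardTrace:
    """Per-timestep gate activity and hidden states for one row."""

    keep_probability: np.ndarray  # (T,)
    skipped: np.ndarray           # (T,) bool, hard-mode decision
    hidden: np.ndarray            # (T, hidden)
    class_probabilities: np.ndarray  # (n_classes,)


@register_report
@dataclass
class TrainingHistory:
    loss: list = field(default_factory=list)
    pre_clip_norm: list = field(default_factory=list)
    post_clip_norm: list = field(default_factory=list)
    seed: int = 0


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def init_model(
    input_dim: int,
    n_classes: int,
    config: SkipGRUConfig | None = None,
    seed: int = 0,
    feature_order: tuple[str, ...] | None = None,
) -> SkipGRUModel:
    """Fresh model with scaled-uniform (Glorot) weights, zero biases."""
    config = config or SkipGRUConfig()
    config.validate()
    if input_dim < 1 or n_classes < 2:
        raise ValueError("need input_dim >= 1 and n_classes >= 2")
    H = config.hidden_size
    G = config.gate_hidden or H
    rng = np.random.default_rng(seed)
    skip = SkipNetworkParams(
        W1=_glorot(rng, (G, 1 + H + input_dim)), b1=np.zeros(G),
        W2=_glorot(rng, (2, G)), b2=np.zeros(2),
    )
    gru = GRUParams(
        W_r=_glorot(rng, (H, H + 1)), b_r=np.zeros(H),
        W_z=_glorot(rng, (H, H + 1)), b_z=np.zeros(H),
        W=_glorot(rng, (H, H + 1)), b=np.zeros(H),
    )
    head = HeadParams(W=_glorot(rng, (n_classes, H)), b=np.zeros(n_classes))
    order = feature_order or tuple(f"x{t}" for t in range(input_dim))
    if len(order) != input_dim:
        raise ValueError("feature_order length must equal input_dim")
    return SkipGRUModel(skip=skip, gru=gru, head=head, feature_order=order, config=config)


# --------------------------------------------------------------------------
# cell-level operations
# --------------------------------------------------------------------------
def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def jump_probability(
    x_t: float, h_prev: np.ndarray, skip: SkipNetworkParams, position: int = 0
) -> float:
    """Keep probability pi_t for one timestep of one row.

    ``position`` fills the gate's one-hot feature-position block when the
    gate was built with one (inferred from the width of ``W1``).
    """
    h_prev = np.asarray(h_prev, dtype=float)
    g = np.concatenate(([float(x_t)], h_prev))
    n_pos = skip.W1.shape[1] - g.size
    if n_pos < 0:
        raise ValueError("gate W1 narrower than [x_t; h_prev]")
    if n_pos > 0:
        onehot = np.zeros(n_pos)
        if not 0 <= position < n_pos:
            raise ValueError(f"position {position} outside [0, {n_pos})")
        onehot[position] = 1.0
        g = np.concatenate((g, onehot))
    s = np.maximum(skip.W1 @ g + skip.b1, 0.0)
    p = _softmax(skip.W2 @ s + skip.b2)
    return float(p[0])


def gru_cell(x_t: float, h_prev: np.ndarray, gru: GRUParams) -> np.ndarray:
    """One GRU step on a scalar input."""
    h_prev = np.asarray(h_prev, dtype=float)
    c = np.concatenate((h_prev, [float(x_t)]))
    r = _sigmoid(gru.W_r @ c + gru.b_r)
    z = _sigmoid(gru.W_z @ c + gru.b_z)
    cand = np.tanh(gru.W @ np.concatenate((r * h_prev, [float(x_t)])) + gru.b)
    return (1.0 - z) * h_prev + z * cand


# --------------------------------------------------------------------------
# batched forward / backward
# --------------------------------------------------------------------------
def forward_batch(
    model: SkipGRUModel,
    X: np.ndarray,
    mode: str = "hard",
    dropout_masks: np.ndarray | None = None,
    record: bool = False,
):
    """Run the sequence forward for a batch of rows.

    ``X``: (B, T) normalized feature rows; ``dropout_masks``: optional
    (T, B, H) inverted-dropout multipliers applied to h_t after each
    timestep (training only). Returns (class probabilities (B, C),
    cache-or-None). ``record`` keeps intermediates for backprop and traces.
    """
    if mode not in ("hard", "soft"):
        raise ValueError("mode must be 'hard' or 'soft'")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.feature_order):
        raise ValueError("rows must be (B, T) matching the model feature order")
    if not np.isfinite(X).all():
        raise ValueError("non-finite input")
    B, T = X.shape
    H = model.hidden_size
    sp, gp, hp = model.skip, model.gru, model.head
    tau = model.config.skip_threshold
    h = np.zeros((B, H))
    n_pos = sp.W1.shape[1] - 1 - H
    steps = []
    for t in range(T):
        x = X[:, t]
        h_prev = h
        # jump gate: [x_t; h_prev; onehot(t)]
        g = np.concatenate((x[:, None], h_prev), axis=1)
        if n_pos > 0:
            onehot = np.zeros((B, n_pos))
            onehot[:, t % n_pos] = 1.0
            g = np.concatenate((g, onehot), axis=1)
        u = g @ sp.W1.T + sp.b1
        s = np.maximum(u, 0.0)
        logits = s @ sp.W2.T + sp.b2
        p2 = _softmax(logits)
        pi = p2[:, 0]
        # GRU cell
        c = np.concatenate((h_prev, x[:, None]), axis=1)
        r = _sigmoid(c @ gp.W_r.T + gp.b_r)
        z = _sigmoid(c @ gp.W_z.T + gp.b_z)
        cand_in = np.concatenate((r * h_prev, x[:, None]), axis=1)
        hc = np.tanh(cand_in @ gp.W.T + gp.b)
        h_gru = (1.0 - z) * h_prev + z * hc
        if mode == "soft":
            h_new = pi[:, None] * h_gru + (1.0 - pi[:, None]) * h_prev
        else:
            keep = pi >= tau
            h_new = np.where(keep[:, None], h_gru, h_prev)
        mask_t = None
        if dropout_masks is not None:
            mask_t = dropout_masks[t]
            h_new = h_new * mask_t
        if record:
            steps.append(dict(x=x, h_prev=h_prev, g=g, u=u, s=s, p2=p2, pi=pi,
                              c=c, r=r, z=z, cand_in=cand_in, hc=hc,
                              h_gru=h_gru, drop=mask_t))
        h = h_new
    out = h @ hp.W.T + hp.b
    probs = _softmax(out)
    cache = dict(steps=steps, h_final=h, probs=probs) if record else None
    return probs, cache


def loss_and_grads(
    model: SkipGRUModel,
    X: np.ndarray,
    y: np.ndarray,
    dropout_masks: np.ndarray | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Training loss of the soft-gate forward and its analytic gradients
    w.r.t. every parameter (backpropagation through time).

    The loss is mean cross-entropy plus a small *gate usage cost*
    ``gate_cost * mean(pi_t)``: without a budget pressure on the keep
    probability the gate is unidentified (the GRU can suppress irrelevant
    inputs by itself), so keeping a feature must cost a little and pay for
    itself through the likelihood.
    """
    y = np.asarray(y, dtype=int)
    probs, cache = forward_batch(model, X, mode="soft",
                                 dropout_masks=dropout_masks, record=True)
    B, T = X.shape
    eps = 1e-12
    gc = model.config.gate_cost
    loss = float(-np.mean(np.log(probs[np.arange(B), y] + eps)))
    if gc > 0.0:
        loss += gc * float(np.mean([s["pi"].mean() for s in cache["steps"]]))
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite training loss")

    sp, gp, hp = model.skip, model.gru, model.head
    grads = {k: np.zeros_like(v) for k, v in model.params().items()}

    # head
    dout = probs.copy()
    dout[np.arange(B), y] -= 1.0
    dout /= B
    grads["head.W"] += dout.T @ cache["h_final"]
    grads["head.b"] += dout.sum(axis=0)
    dh = dout @ hp.W  # (B, H)

    H = model.hidden_size
    for step in reversed(cache["steps"]):
        if step["drop"] is not None:
            dh = dh * step["drop"]
        pi = step["pi"][:, None]
        h_prev, h_gru = step["h_prev"], step["h_gru"]
        # h_new = pi * h_gru + (1 - pi) * h_prev
        dpi = np.sum(dh * (h_gru - h_prev), axis=1)  # (B,)
        if gc > 0.0:
            dpi = dpi + gc / (B * T)
        dh_gru = dh * pi
        dh_prev = dh * (1.0 - pi)
        # gate backprop: pi = softmax(logits)[:, 0]
        p2 = step["p2"]
        dlogits = np.empty_like(p2)
        dlogits[:, 0] = dpi * p2[:, 0] * (1.0 - p2[:, 0])
        dlogits[:, 1] = -dpi * p2[:, 0] * p2[:, 1]
        grads["skip.W2"] += dlogits.T @ step["s"]
        grads["skip.b2"] += dlogits.sum(axis=0)
        ds = dlogits @ sp.W2
        du = ds * (step["u"] > 0)
        grads["skip.W1"] += du.T @ step["g"]
        grads["skip.b1"] += du.sum(axis=0)
        dg = du @ sp.W1
        dh_prev += dg[:, 1:1 + H]  # positional one-hot block carries no gradient
        # GRU backprop: h_gru = (1 - z) h_prev + z hc
        z, r, hc = step["z"], step["r"], step["hc"]
        dz = dh_gru * (hc - h_prev)
        dhc = dh_gru * z
        dh_prev += dh_gru * (1.0 - z)
        dac = dhc * (1.0 - hc * hc)
        grads["gru.W"] += dac.T @ step["cand_in"]
        grads["gru.b"] += dac.sum(axis=0)
        dcand_in = dac @ gp.W
        drh = dcand_in[:, :H]
        dr = drh * h_prev
        dh_prev += drh * r
        daz = dz * z * (1.0 - z)
        grads["gru.W_z"] += daz.T @ step["c"]
        grads["gru.b_z"] += daz.sum(axis=0)
        dar = dr * r * (1.0 - r)
        grads["gru.W_r"] += dar.T @ step["c"]
        grads["gru.b_r"] += dar.sum(axis=0)
        dc = daz @ gp.W_z + dar @ gp.W_r
        dh_prev += dc[:, :H]
        dh = dh_prev
    return loss, grads


# --------------------------------------------------------------------------
# gradient clipping and optimization
# --------------------------------------------------------------------------
def global_norm(grads: dict[str, np.ndarray]) -> float:
    return float(np.sqrt(sum(float(np.sum(g * g)) for g in grads.values())))


def clip_gradients(
    grads: dict[str, np.ndarray], eta_c: float
) -> tuple[dict[str, np.ndarray], float]:
    """Clip by global norm: scale all gradients by min(eta_c / ||g||, 1).

    Returns (clipped gradients, scale applied). Direction is preserved;
    the post-clip norm never exceeds eta_c.
    """
    if eta_c <= 0:
        raise ValueError("clip threshold must be > 0")
    for name, g in grads.items():
        if not np.isfinite(g).all():
            raise FloatingPointError(f"non-finite gradient in {name}")
    norm = global_norm(grads)
    scale = min(eta_c / norm, 1.0) if norm > 0 else 1.0
    if scale < 1.0:
        grads = {k: g * scale for k, g in grads.items()}
    return grads, scale


class _Adam:
    """Adam with decoupled weight decay (AdamW-style)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            mhat = self.m[k] / b1c
            vhat = self.v[k] / b2c
            p -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p)


def train(
    dataset: TabularDataset,
    mask: FeatureMask | None = None,
    config: SkipGRUConfig | None = None,
    seed: int = 0,
) -> tuple[SkipGRUModel, TrainingHistory]:
    """Train a Skip-GRU on (normalized, imputed) data.

    The mask restricts the model to the selected features in dataset
    column order; ``None`` uses all features. Mini-batch Adam with
    decoupled weight decay, soft-gate forward, inverted dropout on the
    hidden state (training only) and clip-by-norm every step.
    Reproducible from the seed in single-threaded execution.
    """
    config = config or SkipGRUConfig()
    config.validate()
    if mask is None:
        sel = np.arange(dataset.n_features)
    else:
        sel = mask.indices()
    X = dataset.features[:, sel]
    y = dataset.labels
    order = tuple(dataset.feature_names[j] for j in sel)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least two classes")
    model = init_model(len(sel), dataset.n_classes, config, seed=seed, feature_order=order)
    rng = np.random.default_rng(seed + 1)
    opt = _Adam(model.params(), config.learning_rate, config.weight_decay)
    history = TrainingHistory(seed=seed)
    n = X.shape[0]
    H, T = config.hidden_size, len(sel)
    keep_p = 1.0 - config.dropout
    for _epoch in range(config.epochs):
        perm = rng.permutation(n)
        losses, pre_norms, post_norms = [], [], []
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb, yb = X[idx], y[idx]
            if config.dropout > 0.0:
                masks = (rng.random((T, len(idx), H)) < keep_p) / keep_p
            else:
                masks = None
            loss, grads = loss_and_grads(model, xb, yb, dropout_masks=masks)
            pre = global_norm(grads)
            grads, scale = clip_gradients(grads, config.clip_threshold)
            opt.step(grads)
            losses.append(loss)
            pre_norms.append(pre)
            post_norms.append(pre * scale)
        history.loss.append(float(np.mean(losses)))
        history.pre_clip_norm.append(float(np.mean(pre_norms)))
        history.post_clip_norm.append(float(np.mean(post_norms)))
    return model, history


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------
def forward(row: np.ndarray, model: SkipGRUModel, mode: str = "hard") -> ForwardTrace:
    """Full per-timestep trace for one row (no dropout)."""
    row = np.asarray(row, dtype=float)
    if row.shape != (len(model.feature_order),):
        raise ValueError("row length must match the model feature order")
    probs, cache = forward_batch(model, row[None, :], mode=mode, record=True)
    steps = cache["steps"]
    pi = np.array([s["pi"][0] for s in steps])
    tau = model.config.skip_threshold
    hidden = []
    h = np.zeros(model.hidden_size)
    for s in steps:
        if mode == "hard" and s["pi"][0] < tau:
            h = s["h_prev"][0]
        elif mode == "hard":
            h = s["h_gru"][0]
        else:
            h = s["pi"][0] * s["h_gru"][0] + (1 - s["pi"][0]) * s["h_prev"][0]
        hidden.append(h)
    return ForwardTrace(
        keep_probability=pi,
        skipped=pi < tau,
        hidden=np.asarray(hidden),
        class_probabilities=probs[0],
    )


def predict(
    rows: np.ndarray, model: SkipGRUModel, with_traces: bool = False
) -> tuple[np.ndarray, np.ndarray, list[ForwardTrace] | None]:
    """Hard-mode prediction; argmax with lowest-index tie-break."""
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[1] != len(model.feature_order):
        raise ValueError("rows must be (n, T) matching the model feature order")
    probs, _ = forward_batch(model, rows, mode="hard")
    indices = np.argmax(probs, axis=1)
    traces = [forward(r, model, mode="hard") for r in rows] if with_traces else None
    return indices, probs, traces


def gate_importance(model: SkipGRUModel, rows: np.ndarray) -> dict[str, float]:
    """Mean keep probability per feature position across rows.

    The gate's learned keep probabilities are the model's built-in
    transparency mechanism: features the gate consistently keeps are the
    ones driving predictions.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] < 1:
        raise ValueError("need at least one row")
    if rows.shape[1] != len(model.feature_order):
        raise ValueError("rows must match the model feature order")
    total = np.zeros(rows.shape[1])
    # batched hard forward records pi per step
    _, cache = forward_batch(model, rows, mode="hard", record=True)
    for t, step in enumerate(cache["steps"]):
        total[t] = step["pi"].mean()
    return {name: float(total[t]) for t, name in enumerate(model.feature_order)}
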