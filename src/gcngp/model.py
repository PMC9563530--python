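"""Semi-supervised graph-convolutional classifier for gene prioritization.

The model combines two information channels:

* **Graph channel.**  The binary GO feature matrix X is propagated over
  the self-loop-augmented PPI adjacency Ã with the boolean OR operator
  (see :mod:`gcngp.ppi`): after one round, a gene's vector is the OR of
  its closed neighbourhood's vectors; ``or_propagation_depth`` rounds
  reach the depth-k neighbourhood while the matrix stays strictly 0/1.

* **Feed-forward channel.**  On top of the propagated binary features a
  stack of l = l1 + l2 ReLU layers is applied per gene,
  h^k(x) = ReLU(W^k h^{k-1}(x) + b^k) with h^0(x) = x.  The embedding
  e = h^{l1}(x) feeds an unsupervised context loss; class probabilities
  are a softmax over w_y applied to the concatenation [e, h^l(x)].

Training minimizes L_s + λ·L_u by alternating plain-SGD steps: one step
on the supervised cross-entropy L_s over a batch of N1 labeled genes,
then one step on λ·L_u over N2 context triples (i, c, γ), where
L_u = −E log σ(γ · w_c^T e_i).  Context triples come from random-walk
co-occurrence on the PPI graph and from shared labels; γ = −1 triples
are uniform negatives.  Early stopping monitors a held-out labeled
validation split.

Everything is NumPy float64 with hand-derived gradients; gradient
correctness against central finite differences is part of the test
suite.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .go_features import FeatureMatrix
from .ppi import PPINetwork, add_self_loops, or_propagate

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    ``layer_sizes`` are the hidden widths of layers 1..l; the embedding
    is taken after layer ``l1`` and ``l2 = l - l1`` layers follow it.
    Defaults: a four-layer network of width 16, learning rate 0.01,
    at most 200 epochs with early stopping at patience 10.
    """

    layer_sizes: tuple[int, ...] = (16, 16, 16, 16)
    l1: int = 2
    lambda_weight: float = 1.0
    learning_rate: float = 0.01
    max_epochs: int = 200
    patience: int = 10
    batch_labeled: int = 64   # N1
    batch_context: int = 64   # N2
    walk_length: int = 10     # q
    window: int = 3           # d
    negative_ratio: float = 0.5
    label_context_ratio: float = 0.5
    or_propagation_depth: int = 1
    normalize_adjacency: bool = False
    val_fraction: float = 0.2
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.layer_sizes or any(w <= 0 for w in self.layer_sizes):
            raise ValueError("layer_sizes must be positive widths")
        if not (1 <= self.l1 <= len(self.layer_sizes)):
            raise ValueError("l1 must satisfy 1 <= l1 <= total depth")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience < 1 or self.max_epochs < 1:
            raise ValueError("patience and max_epochs must be >= 1")
        if self.lambda_weight < 0:
            raise ValueError("lambda_weight must be >= 0")
        if min(self.batch_labeled, self.batch_context) < 1:
            raise ValueError("batch sizes must be >= 1")
        if self.or_propagation_depth < 0:
            raise ValueError("or_propagation_depth must be >= 0")

    @property
    def l(self) -> int:
        return len(self.layer_sizes)

    @property
    def l2(self) -> int:
        return self.l - self.l1


@dataclass
class ModelParams:
    """All trainable arrays.

    ``weights[k]`` has shape (fan_in, fan_out) so activations are row
    vectors; ``context_weights`` holds one w_c per context unit (= per
    graph node); ``class_weights`` maps [e, h^l] to class logits.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    context_weights: np.ndarray
    class_weights: np.ndarray

    def copy(self) -> "ModelParams":
        return ModelParams(
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.context_weights.copy(),
            self.class_weights.copy(),
        )

    def zeros_like(self) -> "ModelParams":
        return ModelParams(
            [np.zeros_like(w) for w in self.weights],
            [np.zeros_like(b) for b in self.biases],
            np.zeros_like(self.context_weights),
            np.zeros_like(self.class_weights),
        )

    def flat_arrays(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases, self.context_weights, self.class_weights]


@dataclass
class ContextTriple:
    i: int
    c: int
    gamma: int

    def __post_init__(self) -> None:
        if self.gamma not in (+1, -1):
            raise ValueError("gamma must be +1 or -1")


@dataclass
class LossReport:
    epoch: int
    supervised: float
    unsupervised: float
    total: float
    validation: float


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


def init_params(
    config: ModelConfig,
    input_width: int,
    n_classes: int,
    rng_seed: int,
    n_contexts: int = 0,
) -> ModelParams:
    """Glorot-uniform weights (±sqrt(6/(fan_in+fan_out))), zero biases."""
    if input_width <= 0 or n_classes <= 0:
        raise ValueError("input_width and n_classes must be positive")
    rng = np.random.default_rng(rng_seed)
    widths = [input_width, *config.layer_sizes]
    weights = [_glorot(rng, widths[k], widths[k + 1]) for k in range(config.l)]
    biases = [np.zeros(widths[k + 1]) for k in range(config.l)]
    head_in = config.layer_sizes[config.l1 - 1] + config.layer_sizes[-1]
    class_w = _glorot(rng, head_in, n_classes)
    emb = config.layer_sizes[config.l1 - 1]
    ctx_w = _glorot(rng, max(n_contexts, 1), emb)
    return ModelParams(weights, biases, ctx_w, class_w)


# ---------------------------------------------------------------------------
# forward / backward


def _forward(X: np.ndarray, params: ModelParams, n_layers: int | None = None):
    """Feed-forward pass; returns (activations, pre-activations).

    ``activations[k]`` = h^k for k = 0..n_layers (h^0 = input rows).
    """
    if n_layers is None:
        n_layers = len(params.weights)
    acts = [np.atleast_2d(np.asarray(X, dtype=float))]
    pres = []
    for k in range(n_layers):
        z = acts[-1] @ params.weights[k] + params.biases[k]
        pres.append(z)
        acts.append(np.maximum(z, 0.0))
    return acts, pres


def hidden_forward(x: np.ndarray, params: ModelParams, depth: int) -> np.ndarray:
    """h^depth(x): ``depth`` ReLU layers applied to one feature vector."""
    if not 0 <= depth <= len(params.weights):
        raise ValueError(f"depth must be in 0..{len(params.weights)}")
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be a vector")
    if depth > 0 and x.shape[0] != params.weights[0].shape[0]:
        raise ValueError("x width does not match the input layer")
    acts, _ = _forward(x[None, :], params, n_layers=depth)
    return acts[-1][0]


def gcn_layer(
    A_tilde, H, W: np.ndarray, binary_mode: bool = True, bias: np.ndarray | None = None
) -> np.ndarray:
    """One graph-convolution layer: ReLU((Ã ⊛ H) W + b).

    With ``binary_mode`` the propagation ⊛ is the boolean OR product
    (defined only for 0/1 H); otherwise the ordinary matrix product.
    """
    if binary_mode:
        P = or_propagate(A_tilde, H)
        P = np.asarray(P.todense()) if sp.issparse(P) else P
    else:
        P = A_tilde @ H
        P = np.asarray(P.todense()) if sp.issparse(P) else np.asarray(P)
    out = P.astype(float) @ W
    if bias is not None:
        out = out + bias
    return np.maximum(out, 0.0)


def _logits(acts: list[np.ndarray], params: ModelParams, l1: int) -> tuple:
    E = acts[l1]
    top = acts[-1]
    concat = np.concatenate([E, top], axis=1)
    return concat @ params.class_weights, concat


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict_proba(
    x: np.ndarray, params: ModelParams, config: ModelConfig
) -> np.ndarray:
    """Class distribution softmax([h^{l1}(x), h^l(x)] w_y); rows sum to 1."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    acts, _ = _forward(X, params)
    logits, _ = _logits(acts, params, config.l1)
    probs = _softmax(logits)
    return probs[0] if np.asarray(x).ndim == 1 else probs


def supervised_loss(
    labeled: Sequence[tuple[np.ndarray, int]], params: ModelParams, config: ModelConfig
) -> float:
    """L_s: mean negative log-probability of the true labels."""
    if not labeled:
        raise ValueError("labeled set is empty")
    X = np.vstack([np.asarray(x, dtype=float) for x, _ in labeled])
    y = np.array([int(yy) for _, yy in labeled])
    loss, _ = _supervised_loss_grads(X, y, params, config, want_grads=False)
    return loss


def context_loss(
    triples: Sequence[ContextTriple], embeddings: np.ndarray, params: ModelParams
) -> float:
    """L_u: mean over triples of −log σ(γ · w_c^T e_i)."""
    if not len(triples):
        raise ValueError("no context triples")
    dots = np.array(
        [t.gamma * params.context_weights[t.c] @ embeddings[t.i] for t in triples]
    )
    # -log sigmoid(d) = log(1 + exp(-d)), computed stably
    return float(np.mean(np.logaddexp(0.0, -dots)))


def _supervised_loss_grads(
    X: np.ndarray,
    y: np.ndarray,
    params: ModelParams,
    config: ModelConfig,
    want_grads: bool = True,
):
    n = X.shape[0]
    acts, pres = _forward(X, params)
    logits, concat = _logits(acts, params, config.l1)
    probs = _softmax(logits)
    eps_rows = probs[np.arange(n), y]
    loss = float(-np.mean(np.log(np.clip(eps_rows, 1e-300, None))))
    if not want_grads:
        return loss, None
    grads = params.zeros_like()
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n
    grads.class_weights[:] = concat.T @ dlogits
    dconcat = dlogits @ params.class_weights.T
    emb_w = config.layer_sizes[config.l1 - 1]
    dE_head, dtop = dconcat[:, :emb_w], dconcat[:, emb_w:]
    _backprop_layers(acts, pres, params, grads, dtop, config.l1, dE_head, config.l)
    return loss, grads


def _backprop_layers(acts, pres, params, grads, d_out, l1, dE_head, n_layers):
    """Backward through the feed-forward stack, injecting the head's
    gradient on the embedding at layer l1."""
    g = d_out
    if dE_head is not None and l1 == n_layers:
        g = g + dE_head
    for k in range(n_layers - 1, -1, -1):
        dz = g * (pres[k] > 0)
        grads.weights[k] += acts[k].T @ dz
        grads.biases[k] += dz.sum(axis=0)
        g = dz @ params.weights[k].T
        if dE_head is not None and k == l1:
            g = g + dE_head


def _context_loss_grads(
    X: np.ndarray,
    c_idx: np.ndarray,
    gamma: np.ndarray,
    params: ModelParams,
    config: ModelConfig,
    scale: float = 1.0,
):
    """loss and grads of ``scale * L_u`` for triples whose sample rows are X."""
    n = X.shape[0]
    acts, pres = _forward(X, params, n_layers=config.l1)
    E = acts[-1]
    wc = params.context_weights[c_idx]
    dots = gamma * np.einsum("ij,ij->i", wc, E)
    loss = float(np.mean(np.logaddexp(0.0, -dots)))
    grads = params.zeros_like()
    # d/d(dot) of -log sigmoid(dot) = -(1 - sigmoid(dot)) = -sigmoid(-dot)
    dd = -_sigmoid(-dots) * gamma * (scale / n)
    np.add.at(grads.context_weights, c_idx, dd[:, None] * E)
    dE = dd[:, None] * wc
    _backprop_layers(acts, pres, params, grads, dE, config.l1, None, config.l1)
    return loss, grads


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# context sampling


def sample_context(
    network: PPINetwork,
    labels: Mapping[int, int],
    config: ModelConfig,
    rng: np.random.Generator,
) -> Iterator[ContextTriple]:
    """Endless stream of (i, c, γ) context triples.

    Positives are label-based (i, c share a class) with probability
    ``label_context_ratio``, else graph-based (c co-occurs with i within
    window d on a length-q random walk).  A ``negative_ratio`` fraction
    of draws are γ = −1 pairs: a uniform non-i node (graph) or a node of
    a different class (label).  Walks stop early at dead ends.
    """
    n = network.n
    by_class: dict[int, list[int]] = {}
    for i, y in labels.items():
        by_class.setdefault(int(y), []).append(int(i))
    for v in by_class.values():
        v.sort()
    classes = sorted(by_class)
    pos_classes = [c for c in classes if len(by_class[c]) >= 2]
    label_pos_ok = bool(pos_classes)
    label_neg_ok = len(classes) >= 2
    warned = False

    def walk(start: int) -> list[int]:
        path = [start]
        cur = start
        for _ in range(config.walk_length - 1):
            nbrs = network.neighbors(cur)
            if nbrs.size == 0:
                break
            cur = int(nbrs[rng.integers(nbrs.size)])
            path.append(cur)
        return path

    while True:
        negative = rng.random() < config.negative_ratio
        use_label = rng.random() < config.label_context_ratio
        if use_label and not (label_neg_ok if negative else label_pos_ok):
            if not warned:
                logger.info("label context unavailable; falling back to graph context")
                warned = True
            use_label = False
        if use_label:
            if negative:
                ca, cb = rng.choice(len(classes), size=2, replace=False)
                i = by_class[classes[ca]][rng.integers(len(by_class[classes[ca]]))]
                c = by_class[classes[cb]][rng.integers(len(by_class[classes[cb]]))]
                yield ContextTriple(i, c, -1)
            else:
                cls = pos_classes[rng.integers(len(pos_classes))]
                members = by_class[cls]
                a, b = rng.choice(len(members), size=2, replace=False)
                yield ContextTriple(members[a], members[b], +1)
        else:
            i = int(rng.integers(n))
            if negative:
                c = int(rng.integers(n - 1))
                if c >= i:
                    c += 1
                yield ContextTriple(i, c, -1)
            else:
                path = walk(i)
                if len(path) < 2:
                    continue  # isolated start; resample
                a = int(rng.integers(len(path)))
                lo = max(0, a - config.window)
                hi = min(len(path) - 1, a + config.window)
                choices = [p for p in range(lo, hi + 1) if p != a]
                b = choices[rng.integers(len(choices))]
                if path[a] == path[b]:
                    continue  # walk revisited the node; resample
                yield ContextTriple(path[a], path[b], +1)


def _take(stream: Iterator[ContextTriple], n: int) -> list[ContextTriple]:
    return [next(stream) for _ in range(n)]


# ---------------------------------------------------------------------------
# training


def propagate_features(
    features: FeatureMatrix, network: PPINetwork, config: ModelConfig
) -> np.ndarray:
    """OR-propagate the binary features ``or_propagation_depth`` times
    over Ã and return a dense float array (N × m)."""
    A_tilde = add_self_loops(network)
    if config.normalize_adjacency:
        deg = np.asarray(A_tilde.sum(axis=1)).ravel().astype(float)
        dinv = sp.diags(1.0 / np.sqrt(deg))
        A_norm = dinv @ A_tilde @ dinv
        M = features.values.astype(float)
        for _ in range(config.or_propagation_depth):
            M = A_norm @ M
        return np.asarray(M.todense() if sp.issparse(M) else M, dtype=float)
    M = features.values
    for _ in range(config.or_propagation_depth):
        M = or_propagate(A_tilde, M)
    return np.asarray(M.todense(), dtype=float)


def _clip(grads: ModelParams, max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(g**2)) for g in grads.flat_arrays()))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads.flat_arrays():
            g *= scale
        logger.debug("gradient clipped: norm %.3f -> %.3f", total, max_norm)


def _sgd_step(params: ModelParams, grads: ModelParams, lr: float) -> None:
    for p, g in zip(params.flat_arrays(), grads.flat_arrays()):
        p -= lr * g


def _split_validation(
    labels: dict[int, int], frac: float, rng: np.random.Generator
) -> tuple[dict[int, int], dict[int, int]]:
    """Stratified train/validation split of the labeled nodes."""
    train: dict[int, int] = {}
    val: dict[int, int] = {}
    by_class: dict[int, list[int]] = {}
    for i in sorted(labels):
        by_class.setdefault(labels[i], []).append(i)
    for cls in sorted(by_class):
        members = np.array(by_class[cls])
        n_val = int(np.floor(len(members) * frac))
        if len(members) - n_val < 1:
            n_val = max(len(members) - 1, 0)
        perm = rng.permutation(len(members))
        for j, idx in enumerate(perm):
            (val if j < n_val else train)[int(members[idx])] = cls
    return train, val


def train(
    features: FeatureMatrix,
    network: PPINetwork,
    labels: Mapping[str, int] | Mapping[int, int],
    config: ModelConfig,
) -> tuple[ModelParams, list[LossReport]]:
    """Alternating-SGD training of the semi-supervised classifier.

    Per epoch: one gradient step on L_s over ``batch_labeled`` labeled
    genes, then one on λ·L_u over ``batch_context`` context triples.
    Early stopping returns the parameters of the best-validation epoch.
    Deterministic given ``config.seed``.
    """
    if not labels:
        raise ValueError("empty label set")
    idx = network.index()
    lab: dict[int, int] = {}
    for k, v in labels.items():
        lab[idx[k] if isinstance(k, str) else int(k)] = int(v)
    n_classes = max(lab.values()) + 1
    if len(set(lab.values())) < n_classes:
        raise ValueError("labels must cover every class 0..n_classes-1")

    rng = np.random.default_rng(config.seed)
    Xp = propagate_features(features, network, config)
    params = init_params(
        config, Xp.shape[1], n_classes,
        rng_seed=int(rng.integers(2**31)), n_contexts=network.n,
    )
    train_lab, val_lab = _split_validation(lab, config.val_fraction, rng)
    if not val_lab:
        val_lab = dict(train_lab)
    tr_idx = np.array(sorted(train_lab))
    tr_y = np.array([train_lab[i] for i in tr_idx])
    va_idx = np.array(sorted(val_lab))
    va_y = np.array([val_lab[i] for i in va_idx])

    use_context = config.lambda_weight > 0
    ctx_stream = (
        sample_context(network, train_lab, config, rng) if use_context else None
    )
    reports: list[LossReport] = []
    best = params.copy()
    best_val = np.inf
    stale = 0
    for epoch in range(1, config.max_epochs + 1):
        pick = rng.integers(len(tr_idx), size=config.batch_labeled)
        ls, grads = _supervised_loss_grads(
            Xp[tr_idx[pick]], tr_y[pick], params, config
        )
        _clip(grads, config.grad_clip)
        _sgd_step(params, grads, config.learning_rate)

        if use_context:
            triples = _take(ctx_stream, config.batch_context)
            ci = np.array([t.i for t in triples])
            cc = np.array([t.c for t in triples])
            cg = np.array([t.gamma for t in triples], dtype=float)
            lu, grads = _context_loss_grads(
                Xp[ci], cc, cg, params, config, scale=config.lambda_weight
            )
            _clip(grads, config.grad_clip)
            _sgd_step(params, grads, config.learning_rate)
        else:
            lu = 0.0

        val, _ = _supervised_loss_grads(Xp[va_idx], va_y, params, config, want_grads=False)
        total = ls + config.lambda_weight * lu
        if not np.isfinite(total) or not np.isfinite(val):
            raise RuntimeError(
                f"training diverged at epoch {epoch}: "
                f"L_s={ls:.4g} L_u={lu:.4g} val={val:.4g}"
            )
        reports.append(LossReport(epoch, ls, lu, total, val))
        logger.debug("epoch %d: L_s=%.4f L_u=%.4f total=%.4f val=%.4f",
                     epoch, ls, lu, total, val)
        if val < best_val - 1e-12:
            best_val = val
            best = params.copy()
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    return best, reports


# ---------------------------------------------------------------------------
# checkpoint I/O (versioned JSON archive: plain text, small models)

_CHECKPOINT_VERSION = 1


def save_checkpoint(
    path: str | Path, params: ModelParams, config: ModelConfig
) -> None:
    payload = {
        "version": _CHECKPOINT_VERSION,
        "config": asdict(config),
        "weights": [w.tolist() for w in params.weights],
        "biases": [b.tolist() for b in params.biases],
        "context_weights": params.context_weights.tolist(),
        "class_weights": params.class_weights.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> tuple[ModelParams, ModelConfig]:
    payload = json.loads(Path(path).read_text())
    if payload.get("version") != _CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version: {payload.get('version')}")
    cfg_d = payload["config"]
    cfg_d["layer_sizes"] = tuple(cfg_d["layer_sizes"])
    config = ModelConfig(**cfg_d)
    params = ModelParams(
        [np.array(w, dtype=float) for w in payload["weights"]],
        [np.array(b, dtype=float) for b in payload["biases"]],
        np.array(payload["context_weights"], dtype=float),
        np.array(payload["class_weights"], dtype=float),
    )
    return params, config
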