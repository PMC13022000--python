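"""Contrastive pocket projection trained by KL similarity distillation.

The network maps a mean-pooled pocket embedding (1280-d by default) into a
256-d latent space through two layers, each affine → batch normalization →
dropout (rate 0.1) → GELU, with an intermediate width of 512.  Training
aligns the distribution of latent pocket cosine similarities P(i) within a
batch to the distribution of ligand fingerprint similarities Q(i) by
minimizing KL(P‖Q), so that pockets binding chemically similar ligands end
up close in the latent space.

Both distributions are formed per anchor: the anchor's similarity row over
the other batch members is divided by a temperature, passed through a
softmax, floored at a small epsilon and renormalized.  The loss is the mean
over anchors of Σ_j P_ij log(P_ij / Q_ij).

The network, its gradients and the Adam training loop are implemented
directly on numpy arrays; the analytic gradients are validated against
finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import erf

from .chem import similarity_matrix

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)
_BN_EPS = 1e-5


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact GELU: x Φ(x) with the Gaussian CDF Φ."""
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    cdf = 0.5 * (1.0 + erf(x / _SQRT2))
    pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
    return cdf + x * pdf


@dataclass
class TrainingConfig:
    """Hyperparameters of the contrastive training loop.

    Defaults are the reference recipe: Adam at learning rate 0.001,
    early-stopping patience 100, at most 2000 epochs, 4096 training batches
    and 256 fixed validation batches of 128 samples per epoch.
    """

    learning_rate: float = 0.001
    patience: int = 100
    max_epochs: int = 2000
    train_batches_per_epoch: int = 4096
    val_batches_per_epoch: int = 256
    batch_size: int = 128
    temperature: float = 1.0
    epsilon: float = 1e-8
    seed: int = 0
    val_fraction: float = 0.1
    similarity_metric: str = "cosine"  # ligand similarity for Q
    input_dim: int = 1280
    hidden_dim: int = 512
    output_dim: int = 256
    dropout_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not (0 < self.patience < self.max_epochs):
            raise ValueError("need 0 < patience < max_epochs")
        for name in ("train_batches_per_epoch", "val_batches_per_epoch", "batch_size",
                     "input_dim", "hidden_dim", "output_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class _Layer:
    """Affine → batch normalization → dropout → GELU."""

    def __init__(self, d_in: int, d_out: int, dropout_rate: float, rng: np.random.Generator):
        # He-style fan-in scaling
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.gamma = np.ones(d_out)
        self.beta = np.zeros(d_out)
        self.running_mean = np.zeros(d_out)
        self.running_var = np.ones(d_out)
        self.momentum = 0.1
        self.dropout_rate = dropout_rate

    # parameter access for the optimizer -------------------------------
    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b, "gamma": self.gamma, "beta": self.beta}

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None,
                update_stats: bool, cache: dict | None = None) -> np.ndarray:
        z = x @ self.W + self.b
        if train:
            mu = z.mean(axis=0)
            var = z.var(axis=0)  # population variance over the batch
            if update_stats:
                self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
                self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (z - mu) * inv_std
        y = self.gamma * xhat + self.beta
        if train and self.dropout_rate > 0 and rng is not None:
            keep = 1.0 - self.dropout_rate
            mask = (rng.random(y.shape) < keep) / keep
        else:
            mask = None
        d = y * mask if mask is not None else y
        out = gelu(d)
        if cache is not None:
            cache.update(x=x, z=z, mu=mu, inv_std=inv_std, xhat=xhat,
                         mask=mask, d=d, train=train)
        return out

    def backward(self, dout: np.ndarray, cache: dict) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        dd = dout * gelu_grad(cache["d"])
        dy = dd * cache["mask"] if cache["mask"] is not None else dd
        xhat, inv_std = cache["xhat"], cache["inv_std"]
        dgamma = np.sum(dy * xhat, axis=0)
        dbeta = np.sum(dy, axis=0)
        dxhat = dy * self.gamma
        if cache["train"]:
            B = dy.shape[0]
            # standard batchnorm backward through batch mean and variance
            dz = (inv_std / B) * (
                B * dxhat - np.sum(dxhat, axis=0) - xhat * np.sum(dxhat * xhat, axis=0)
            )
        else:
            dz = dxhat * inv_std
        dW = cache["x"].T @ dz
        db = np.sum(dz, axis=0)
        dx = dz @ self.W.T
        return dx, {"W": dW, "b": db, "gamma": dgamma, "beta": dbeta}


class ProjectionModel:
    """Two-layer projection network (input → hidden → latent)."""

    SCHEMA_VERSION = 1

    def __init__(self, input_dim: int = 1280, hidden_dim: int = 512,
                 output_dim: int = 256, dropout_rate: float = 0.1,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.input_dim = input_dim
        self.output_dim = output_dim
        self.layers = [
            _Layer(input_dim, hidden_dim, dropout_rate, rng),
            _Layer(hidden_dim, output_dim, dropout_rate, rng),
        ]
        self.provider_tag = ""

    # ------------------------------------------------------------------
    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None,
                update_stats: bool = False,
                caches: list | None = None) -> np.ndarray:
        h = X
        for layer in self.layers:
            cache = {} if caches is not None else None
            h = layer.forward(h, train=train, rng=rng, update_stats=update_stats, cache=cache)
            if caches is not None:
                caches.append(cache)
        return h

    def backward(self, dout: np.ndarray, caches: list) -> list[dict[str, np.ndarray]]:
        grads: list[dict[str, np.ndarray]] = [None] * len(self.layers)  # type: ignore
        dh = dout
        for i in reversed(range(len(self.layers))):
            dh, g = self.layers[i].backward(dh, caches[i])
            grads[i] = g
        return grads

    def parameters(self) -> list[dict[str, np.ndarray]]:
        return [layer.params() for layer in self.layers]

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params().items():
                out[f"layer{i}.{name}"] = arr.copy()
            out[f"layer{i}.running_mean"] = layer.running_mean.copy()
            out[f"layer{i}.running_var"] = layer.running_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            layer.W = np.array(state[f"layer{i}.W"])
            layer.b = np.array(state[f"layer{i}.b"])
            layer.gamma = np.array(state[f"layer{i}.gamma"])
            layer.beta = np.array(state[f"layer{i}.beta"])
            layer.running_mean = np.array(state[f"layer{i}.running_mean"])
            layer.running_var = np.array(state[f"layer{i}.running_var"])

    # persistence ------------------------------------------------------
    def save(self, path, config: TrainingConfig | None = None) -> None:
        meta = {
            "schema_version": self.SCHEMA_VERSION,
            "input_dim": self.input_dim,
            "hidden_dim": self.layers[0].W.shape[1],
            "output_dim": self.output_dim,
            "dropout_rate": self.layers[0].dropout_rate,
            "provider_tag": self.provider_tag,
            "config": asdict(config) if config is not None else None,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.state_dict())

    @classmethod
    def load(cls, path) -> "ProjectionModel":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = cls(input_dim=meta["input_dim"], hidden_dim=meta["hidden_dim"],
                    output_dim=meta["output_dim"], dropout_rate=meta["dropout_rate"])
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        model.provider_tag = meta.get("provider_tag", "")
        return model


# ---------------------------------------------------------------------------
# similarity distributions and the KL loss


@dataclass(frozen=True)
class SimilarityDistribution:
    """Per-anchor probability distribution over the other batch members."""

    anchor_index: int
    probs: np.ndarray
    temperature: float = 1.0
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=np.float64)
        if probs.size == 0:
            raise ValueError("empty distribution")
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError("probabilities must be non-negative and sum to 1")
        object.__setattr__(self, "probs", probs)


def to_distribution(sim_row: np.ndarray, temperature: float = 1.0,
                    epsilon: float = 1e-8, anchor_index: int = 0) -> SimilarityDistribution:
    """Turn an anchor's similarity row (self excluded) into a distribution.

    softmax(sim / temperature), floored at ``epsilon`` and renormalized.
    """
    sim_row = np.asarray(sim_row, dtype=np.float64)
    if sim_row.size == 0:
        raise ValueError("empty similarity row")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    logits = sim_row / temperature
    logits = logits - logits.max()
    p = np.exp(logits)
    p /= p.sum()
    p = np.maximum(p, epsilon)
    p /= p.sum()
    return SimilarityDistribution(anchor_index=anchor_index, probs=p,
                                  temperature=temperature, epsilon=epsilon)


def _as_prob_matrix(dists) -> np.ndarray:
    if isinstance(dists, np.ndarray):
        return dists
    rows = [d.probs for d in dists]
    sizes = {r.size for r in rows}
    if len(sizes) != 1:
        raise ValueError("distributions have mismatched index sets")
    return np.stack(rows)


def kl_loss(P, Q) -> float:
    """Mean over anchors of Σ_j P_ij log(P_ij / Q_ij).

    ``P`` and ``Q`` are matching sets of :class:`SimilarityDistribution`
    (or probability matrices with one anchor per row).  Zero iff P = Q;
    non-negative up to epsilon-floor effects.
    """
    Pm, Qm = _as_prob_matrix(P), _as_prob_matrix(Q)
    if Pm.shape != Qm.shape:
        raise ValueError(f"mismatched index sets: {Pm.shape} vs {Qm.shape}")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(Pm > 0, Pm * (np.log(Pm) - np.log(Qm)), 0.0)
    return float(terms.sum(axis=1).mean())


def batch_distributions(sim: np.ndarray, temperature: float, epsilon: float) -> np.ndarray:
    """Per-anchor distributions for a full B×B similarity matrix.

    Returns a B×B matrix whose row i holds the anchor-i distribution over
    j ≠ i, with a zero diagonal.
    """
    B = sim.shape[0]
    logits = sim / temperature
    np.fill_diagonal(logits, -np.inf)
    logits = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    off = ~np.eye(B, dtype=bool)
    p[off] = np.maximum(p[off], epsilon)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _latent_distribution_grad(T: np.ndarray, Q: np.ndarray, temperature: float,
                              epsilon: float) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss and its gradient w.r.t. the latent matrix T (B×d).

    Q is the B×B ligand distribution matrix (zero diagonal).  Returns
    (loss, dL/dT, P).  The epsilon floor is treated as inactive for the
    gradient (its effect is O(epsilon)).
    """
    B = T.shape[0]
    norms = np.linalg.norm(T, axis=1, keepdims=True)
    norms = np.maximum(norms, 1e-30)
    U = T / norms
    C = U @ U.T
    P = batch_distributions(C, temperature, epsilon)

    off = ~np.eye(B, dtype=bool)
    logratio = np.zeros_like(P)
    logratio[off] = np.log(P[off]) - np.log(Q[off])
    loss = float((P * logratio).sum(axis=1).mean())

    # d loss / d logits, logits = C / temperature (per-anchor softmax rows)
    row_dot = (P * logratio).sum(axis=1, keepdims=True)
    dS = P * (logratio - row_dot) / B  # mean over anchors
    np.fill_diagonal(dS, 0.0)
    dC = dS / temperature
    dU = (dC + dC.T) @ U
    # back through row normalization
    dT = (dU - U * np.sum(dU * U, axis=1, keepdims=True)) / norms
    return loss, dT, P


def batch_loss_and_grad(model: ProjectionModel, X: np.ndarray, Q: np.ndarray,
                        temperature: float, epsilon: float,
                        rng: np.random.Generator | None = None,
                        train: bool = True, update_stats: bool = False):
    """Forward + backward pass for one batch.

    Returns ``(loss, grads)`` where grads matches ``model.parameters()``.
    With ``rng=None`` dropout is disabled, making the pass deterministic
    (used by the finite-difference gradient check).
    """
    caches: list = []
    T = model.forward(X, train=train, rng=rng, update_stats=update_stats, caches=caches)
    loss, dT, _ = _latent_distribution_grad(T, Q, temperature, epsilon)
    grads = model.backward(dT, caches)
    return loss, grads


def batch_loss(model: ProjectionModel, X: np.ndarray, Q: np.ndarray,
               temperature: float, epsilon: float,
               rng: np.random.Generator | None = None, train: bool = True) -> float:
    T = model.forward(X, train=train, rng=rng, update_stats=False)
    loss, _, _ = _latent_distribution_grad(T, Q, temperature, epsilon)
    return loss


# ---------------------------------------------------------------------------
# inference


def project(model: ProjectionModel, pocket_vector: np.ndarray, mode: str = "eval") -> np.ndarray:
    """Project one pooled pocket embedding into the latent space."""
    v = np.asarray(pocket_vector, dtype=np.float64)
    if v.ndim == 1:
        v = v[None, :]
    if v.shape[1] != model.input_dim:
        raise ValueError(f"expected input dimension {model.input_dim}, got {v.shape[1]}")
    if mode not in ("eval", "train"):
        raise ValueError("mode must be 'eval' or 'train'")
    out = model.forward(v, train=(mode == "train"))
    return out[0]


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two latent vectors."""
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine undefined for a zero-norm vector")
    return float(np.dot(u, v) / (nu * nv))


def encode(model: ProjectionModel, X: np.ndarray) -> np.ndarray:
    """Encode pooled pocket embeddings into latent vectors (eval mode)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.input_dim:
        raise ValueError(f"expected input dimension {model.input_dim}, got {X.shape[1]}")
    return model.forward(X, train=False)


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params: list[dict[str, np.ndarray]], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [{k: np.zeros_like(v) for k, v in layer.items()} for layer in params]
        self.v = [{k: np.zeros_like(v) for k, v in layer.items()} for layer in params]
        self.t = 0

    def step(self, params: list[dict[str, np.ndarray]], grads: list[dict[str, np.ndarray]]):
        self.t += 1
        b1c = 1 - self.beta1 ** self.t
        b2c = 1 - self.beta2 ** self.t
        for layer, glayer, m, v in zip(params, grads, self.m, self.v):
            for k in layer:
                g = glayer[k]
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                layer[k] -= self.lr * (m[k] / b1c) / (np.sqrt(v[k] / b2c) + self.eps)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


def _ligand_similarity(fingerprints, metric: str) -> np.ndarray:
    if isinstance(fingerprints, np.ndarray) and fingerprints.ndim == 2 \
            and fingerprints.shape[0] == fingerprints.shape[1] \
            and np.allclose(fingerprints, fingerprints.T):
        return fingerprints  # pre-computed similarity matrix
    return similarity_matrix(list(fingerprints), metric=metric)


def train(pocket_embeddings, fingerprints, cfg: TrainingConfig) -> tuple[ProjectionModel, TrainingHistory]:
    """Train the projection by KL similarity distillation.

    Parameters
    ----------
    pocket_embeddings
        n × input_dim array (or sequence of :class:`PocketEmbedding`).
    fingerprints
        n matching :class:`LigandFingerprint` objects (or an n × 2048 bit
        matrix, or a precomputed n × n similarity matrix).
    cfg
        Training hyperparameters; all randomness derives from ``cfg.seed``.

    Returns the model checkpoint with the lowest validation loss and the
    per-epoch loss history.  Training stops after ``cfg.patience`` epochs
    without validation improvement or at ``cfg.max_epochs``.
    """
    X = _stack_embeddings(pocket_embeddings)
    n = X.shape[0]
    sim = _ligand_similarity(fingerprints, cfg.similarity_metric)
    if sim.shape != (n, n):
        raise ValueError("need one fingerprint per pocket")
    if n < 2 * cfg.batch_size:
        raise ValueError(f"need at least {2 * cfg.batch_size} samples, got {n}")

    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    n_val = max(cfg.batch_size, int(round(cfg.val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) < cfg.batch_size:
        raise ValueError("training pool smaller than one batch")

    # fixed validation batches, drawn once at startup
    val_batches = [rng.choice(val_idx, size=cfg.batch_size, replace=False)
                   for _ in range(cfg.val_batches_per_epoch)]

    model = ProjectionModel(input_dim=X.shape[1], hidden_dim=cfg.hidden_dim,
                            output_dim=cfg.output_dim, dropout_rate=cfg.dropout_rate,
                            seed=int(rng.integers(2**31)))
    optimizer = _Adam(model.parameters(), lr=cfg.learning_rate)
    history = TrainingHistory()

    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = -1
    epochs_since_improvement = 0

    for epoch in range(cfg.max_epochs):
        epoch_train = 0.0
        for _ in range(cfg.train_batches_per_epoch):
            batch = rng.choice(train_idx, size=cfg.batch_size, replace=False)
            Q = batch_distributions(sim[np.ix_(batch, batch)], cfg.temperature, cfg.epsilon)
            loss, grads = batch_loss_and_grad(
                model, X[batch], Q, cfg.temperature, cfg.epsilon,
                rng=rng, train=True, update_stats=True,
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "non-finite training loss; consider lowering the learning "
                    "rate or raising epsilon"
                )
            optimizer.step(model.parameters(), grads)
            epoch_train += loss
        epoch_train /= cfg.train_batches_per_epoch

        epoch_val = 0.0
        for batch in val_batches:
            Q = batch_distributions(sim[np.ix_(batch, batch)], cfg.temperature, cfg.epsilon)
            T = model.forward(X[batch], train=False)
            loss, _, _ = _latent_distribution_grad(T, Q, cfg.temperature, cfg.epsilon)
            epoch_val += loss
        epoch_val /= len(val_batches)

        history.train_loss.append(epoch_train)
        history.val_loss.append(epoch_val)

        if epoch_val < best_val:
            best_val = epoch_val
            best_state = model.state_dict()
            best_epoch = epoch
            epochs_since_improvement = 0
        else:
            epochs_since_improvement += 1
        if epochs_since_improvement >= cfg.patience:
            break

    history.best_epoch = best_epoch
    history.stopped_epoch = len(history.train_loss) - 1
    model.load_state_dict(best_state)
    return model, history


def _stack_embeddings(pocket_embeddings) -> np.ndarray:
    if isinstance(pocket_embeddings, np.ndarray):
        return np.asarray(pocket_embeddings, dtype=np.float64)
    return np.stack([
        p.vector if hasattr(p, "vector") else np.asarray(p, dtype=np.float64)
        for p in pocket_embeddings
    ])
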