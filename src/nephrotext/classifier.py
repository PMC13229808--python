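"""Downstream classification head and end-to-end trainable fusion classifier.

The head is a small MLP (affine -> ReLU -> dropout(0.5) -> affine) trained
with AdamW (decoupled weight decay 1e-2), a cosine-annealed learning rate
over 300 epochs, Gaussian-noise data augmentation, inverse-frequency class
weights normalized to unit mean, and label smoothing (alpha = 0.1).  The
loss is the weighted, label-smoothed cross-entropy

    L = -(1/N) sum_i w_{y_i} sum_k y^LS_{i,k} log softmax(z_i)_k .

Two scikit-learn-style estimators are provided:

* :class:`MLPHeadClassifier` trains the MLP head alone on precomputed
  feature vectors.
* :class:`FusionMLPClassifier` trains the full downstream stack end to end:
  the 10 per-layer linear projections, the scaled-sigmoid gamma of the
  co-occurrence head, and the MLP, with gradients backpropagated through
  the Gram matrix.  Its input rows are the raw concatenation of the 10
  layer vectors followed by the mean-pooled primary embedding (11*D
  columns).

Everything is plain NumPy with hand-written backpropagation; determinism is
guaranteed by threading a single seeded Generator through initialization,
shuffling, augmentation and dropout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, log_softmax, softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import ConfigError, ShapeError, TrainingError
from .fusion import N_FUSION_VECTORS, fused_dim

__all__ = [
    "TrainConfig",
    "class_weights",
    "smooth_labels",
    "weighted_smoothed_ce",
    "augment",
    "build_mlp",
    "count_parameters",
    "MLPHeadClassifier",
    "FusionMLPClassifier",
    "train",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults are the reference protocol)."""

    learning_rate: float = 1e-4
    weight_decay: float = 1e-2
    epochs: int = 300
    batch_size: int = 32
    dropout: float = 0.5
    smoothing_alpha: float = 0.1
    hidden_dim: int = 1024
    augment_copies: int = 20
    noise_scale: float = 0.1
    epsilon: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if not (self.learning_rate > 0 and self.weight_decay >= 0 and self.epochs > 0
                and self.batch_size > 0 and self.hidden_dim > 0):
            raise ConfigError("learning_rate/weight_decay/epochs/batch_size/hidden_dim invalid")
        if not 0 <= self.smoothing_alpha < 1:
            raise ConfigError("smoothing_alpha must lie in [0, 1)")
        if not 0 <= self.dropout < 1:
            raise ConfigError("dropout must lie in [0, 1)")
        if self.augment_copies < 0 or self.noise_scale < 0:
            raise ConfigError("augmentation parameters must be nonnegative")


# ---------------------------------------------------------------------------
# Loss components
# ---------------------------------------------------------------------------

def class_weights(counts: Sequence[int], epsilon: float = 1e-8) -> np.ndarray:
    """Inverse-frequency weights w_c = 1/(N_c + eps), normalized to unit mean."""
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0 or np.any(counts < 1):
        raise ConfigError(f"every class must have >= 1 training sample, got counts {counts}")
    w = 1.0 / (counts + epsilon)
    return w / w.mean()


def smooth_labels(y: np.ndarray, alpha: float, n_classes: int | None = None) -> np.ndarray:
    """Label smoothing: y_k^LS = (1 - alpha) y_k + alpha / C for one-hot y."""
    y = np.asarray(y, dtype=float)
    if not 0 <= alpha < 1:
        raise ConfigError("alpha must lie in [0, 1)")
    single = y.ndim == 1
    Y = y[None, :] if single else y
    C = Y.shape[1]
    if n_classes is not None and n_classes != C:
        raise ShapeError(f"one-hot width {C} != declared class count {n_classes}")
    if not (np.all(np.isin(Y, (0.0, 1.0))) and np.all(Y.sum(axis=1) == 1.0)):
        raise ShapeError("labels must be one-hot rows")
    out = (1.0 - alpha) * Y + alpha / C
    return out[0] if single else out


def weighted_smoothed_ce(
    logits: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray | None = None,
    alpha: float = 0.0,
) -> float:
    """Weighted label-smoothed cross-entropy averaged over the batch.

    ``labels`` are integer class indices; ``weights`` are per-class (unit-mean
    by convention, but any positive vector is accepted).
    """
    logits = np.asarray(logits, dtype=float)
    if logits.ndim != 2:
        raise ShapeError(f"logits must be (N, C), got shape {logits.shape}")
    if not np.all(np.isfinite(logits)):
        raise TrainingError("non-finite logits passed to the loss")
    labels = np.asarray(labels, dtype=int)
    n, C = logits.shape
    if labels.shape != (n,) or labels.min() < 0 or labels.max() >= C:
        raise ShapeError("labels must be integer class indices aligned with logits")
    w = np.ones(C) if weights is None else np.asarray(weights, dtype=float)
    onehot = np.eye(C)[labels]
    y_ls = smooth_labels(onehot, alpha)
    logp = log_softmax(logits, axis=1)
    per_sample = -(y_ls * logp).sum(axis=1)
    return float(np.mean(w[labels] * per_sample))


def augment(
    features: np.ndarray,
    labels: np.ndarray,
    copies: int,
    noise_scale: float,
    seed: int | np.random.Generator = 0,
    feature_sd: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Append ``copies`` noisy replicas of the batch (labels carried over).

    Noise is zero-mean Gaussian with per-feature sd = noise_scale * sd of the
    feature over the (training) batch, or over ``feature_sd`` when the
    statistics were fitted elsewhere (e.g. on the training fold only).
    The original batch is always preserved as the first block.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if copies < 0:
        raise ConfigError("copies must be >= 0")
    if copies == 0:
        return X.copy(), y.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = np.asarray(feature_sd, dtype=float) if feature_sd is not None else X.std(axis=0)
    blocks_X = [X]
    blocks_y = [y]
    for _ in range(copies):
        noise = rng.standard_normal(X.shape) * (noise_scale * sd)
        blocks_X.append(X + noise)
        blocks_y.append(y)
    return np.concatenate(blocks_X), np.concatenate(blocks_y)


# ---------------------------------------------------------------------------
# MLP head + AdamW
# ---------------------------------------------------------------------------

@dataclass
class MLP:
    """affine(input -> hidden) -> ReLU -> dropout -> affine(hidden -> C)."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    @property
    def n_parameters(self) -> int:
        return self.W1.size + self.b1.size + self.W2.size + self.b2.size

    def params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, X: np.ndarray, dropout: float = 0.0,
                rng: np.random.Generator | None = None):
        """Return (logits, cache); dropout applied only when rng is given."""
        h_pre = X @ self.W1 + self.b1
        h = np.maximum(h_pre, 0.0)
        if dropout > 0.0 and rng is not None:
            mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
            h_drop = h * mask
        else:
            mask = None
            h_drop = h
        z = h_drop @ self.W2 + self.b2
        return z, (X, h_pre, mask, h_drop)


def build_mlp(input_dim: int, hidden_dim: int, n_classes: int, seed: int = 0) -> MLP:
    """He-initialized MLP head; ``.n_parameters`` reports the parameter count."""
    if min(input_dim, hidden_dim, n_classes) < 1:
        raise ConfigError("all MLP dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    return MLP(
        W1=rng.standard_normal((input_dim, hidden_dim)) * np.sqrt(2.0 / input_dim),
        b1=np.zeros(hidden_dim),
        W2=rng.standard_normal((hidden_dim, n_classes)) * np.sqrt(2.0 / hidden_dim),
        b2=np.zeros(n_classes),
    )


def count_parameters(d_model: int = 4096, proj_dim: int = 1024,
                     hidden_dim: int = 1024, n_classes: int = 2) -> int:
    """Trainable parameters of the full downstream stack (projections + gamma + MLP)."""
    proj = N_FUSION_VECTORS * (proj_dim * d_model + proj_dim)
    f = fused_dim(d_model)
    mlp = (f * hidden_dim + hidden_dim) + (hidden_dim * n_classes + n_classes)
    return proj + 1 + mlp


class _AdamW:
    """AdamW with decoupled weight decay (per-step learning rate supplied)."""

    def __init__(self, params: list[np.ndarray], weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 decay_mask: list[bool] | None = None):
        self.params = params
        self.wd = weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        # biases and gamma are conventionally exempt from weight decay
        self.decay_mask = decay_mask if decay_mask is not None else [p.ndim > 1 for p in params]

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, (p, g) in enumerate(zip(self.params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            update = (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
            if self.decay_mask[i]:
                update = update + self.wd * p
            p -= lr * update


def _cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    return 0.5 * base_lr * (1.0 + np.cos(np.pi * epoch / max(total_epochs, 1)))


def _check_finite_loss(loss: float, epoch: int) -> None:
    if not np.isfinite(loss):
        raise TrainingError(f"training diverged (non-finite loss) at epoch {epoch}")


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class MLPHeadClassifier(ClassifierMixin, BaseEstimator):
    """MLP head trained on fixed feature vectors (scikit-learn interface).

    Parameters mirror :class:`TrainConfig`; fitted attributes carry a
    trailing underscore (``classes_``, ``mlp_``, ``loss_history_``).
    """

    def __init__(self, hidden_dim=1024, learning_rate=1e-4, weight_decay=1e-2,
                 epochs=300, batch_size=32, dropout=0.5, smoothing_alpha=0.1,
                 augment_copies=20, noise_scale=0.1, class_weighting=True,
                 epsilon=1e-8, random_state=0):
        self.hidden_dim = hidden_dim
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.dropout = dropout
        self.smoothing_alpha = smoothing_alpha
        self.augment_copies = augment_copies
        self.noise_scale = noise_scale
        self.class_weighting = class_weighting
        self.epsilon = epsilon
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ConfigError("training requires at least 2 classes")
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        counts = np.bincount(y_idx, minlength=len(self.classes_))
        self.class_weights_ = (class_weights(counts, self.epsilon)
                               if self.class_weighting else np.ones(len(self.classes_)))
        self.feature_sd_ = X.std(axis=0)
        self.mlp_ = build_mlp(X.shape[1], self.hidden_dim, len(self.classes_),
                              seed=int(rng.integers(2**31)))
        opt = _AdamW(self.mlp_.params(), self.weight_decay)
        self.loss_history_ = _train_loop(
            forward_backward=lambda Xb, yb, drop_rng: _mlp_step(
                self.mlp_, Xb, yb, self.class_weights_, self.smoothing_alpha,
                self.dropout, drop_rng),
            opt=opt, X=X, y=y_idx, rng=rng,
            epochs=self.epochs, batch_size=self.batch_size,
            base_lr=self.learning_rate, copies=self.augment_copies,
            noise_scale=self.noise_scale, feature_sd=self.feature_sd_,
        )
        return self

    def decision_function(self, X):
        check_is_fitted(self, "mlp_")
        X = check_array(X)
        z, _ = self.mlp_.forward(X)
        return z

    def predict_proba(self, X):
        return softmax(self.decision_function(X), axis=1)

    def predict(self, X):
        # argmax breaks ties toward the lower class index
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _mlp_step(mlp: MLP, Xb, yb, w, alpha, dropout, rng):
    """One forward/backward pass of the head; returns (loss, grads)."""
    n, C = Xb.shape[0], mlp.b2.shape[0]
    z, (Xc, h_pre, mask, h_drop) = mlp.forward(Xb, dropout=dropout, rng=rng)
    y_ls = smooth_labels(np.eye(C)[yb], alpha)
    logp = log_softmax(z, axis=1)
    loss = float(np.mean(w[yb] * -(y_ls * logp).sum(axis=1)))
    dz = (w[yb][:, None] * (np.exp(logp) - y_ls)) / n
    gW2 = h_drop.T @ dz
    gb2 = dz.sum(axis=0)
    dh = dz @ mlp.W2.T
    if mask is not None:
        dh = dh * mask
    dh_pre = dh * (h_pre > 0)
    gW1 = Xc.T @ dh_pre
    gb1 = dh_pre.sum(axis=0)
    return loss, [gW1, gb1, gW2, gb2], None


class FusionMLPClassifier(ClassifierMixin, BaseEstimator):
    """End-to-end trainable fusion stack on raw dual-backend embeddings.

    Each input row is ``concat(v_1, ..., v_10, vQ)`` with v_j the last-token
    layer vectors (primary backend's 5 layers, then the secondary's) and vQ
    the mean-pooled primary embedding, i.e. 11*D columns.  ``fit`` learns the
    10 projections, gamma, and the MLP head jointly; gradients flow through
    ReLU projections, the Gram matrix, and the scaled sigmoid.
    """

    def __init__(self, proj_dim=1024, hidden_dim=1024, learning_rate=1e-4,
                 weight_decay=1e-2, epochs=300, batch_size=32, dropout=0.5,
                 smoothing_alpha=0.1, augment_copies=20, noise_scale=0.1,
                 class_weighting=True, epsilon=1e-8, gamma_init=1.0,
                 random_state=0):
        self.proj_dim = proj_dim
        self.hidden_dim = hidden_dim
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.dropout = dropout
        self.smoothing_alpha = smoothing_alpha
        self.augment_copies = augment_copies
        self.noise_scale = noise_scale
        self.class_weighting = class_weighting
        self.epsilon = epsilon
        self.gamma_init = gamma_init
        self.random_state = random_state

    # -- geometry -----------------------------------------------------------
    def _split(self, X: np.ndarray):
        n, m = X.shape
        if m % (N_FUSION_VECTORS + 1) != 0:
            raise ShapeError(
                f"input width {m} is not a multiple of {N_FUSION_VECTORS + 1} "
                f"(10 layer vectors + vQ)"
            )
        D = m // (N_FUSION_VECTORS + 1)
        V = X[:, : N_FUSION_VECTORS * D].reshape(n, N_FUSION_VECTORS, D)
        vQ = X[:, N_FUSION_VECTORS * D:]
        return V, vQ, D

    def _forward(self, X: np.ndarray, rng: np.random.Generator | None = None):
        V, vQ, _ = self._split(X)
        W, b, gamma = self.W_, self.b_, self.gamma_[0]
        pre = np.einsum("jpd,bjd->bjp", W, V, optimize=True) + b
        U = np.maximum(pre, 0.0)
        C = np.einsum("bjp,bkp->bjk", U, U, optimize=True)
        c_flat = C.reshape(X.shape[0], -1)
        s = expit(gamma * c_flat)
        p = 2.0 * s - 1.0
        f = np.concatenate([p, vQ], axis=1)
        drop = self.dropout if rng is not None else 0.0
        z, mlp_cache = self.mlp_.forward(f, dropout=drop, rng=rng)
        return z, (V, pre, U, c_flat, s, f, mlp_cache)

    def _step(self, Xb, yb, rng):
        n = Xb.shape[0]
        C_classes = len(self.classes_)
        z, (V, pre, U, c_flat, s, f, (fc, h_pre, mask, h_drop)) = self._forward(Xb, rng=rng)
        y_ls = smooth_labels(np.eye(C_classes)[yb], self.smoothing_alpha)
        logp = log_softmax(z, axis=1)
        loss = float(np.mean(self.class_weights_[yb] * -(y_ls * logp).sum(axis=1)))
        dz = (self.class_weights_[yb][:, None] * (np.exp(logp) - y_ls)) / n
        gW2 = h_drop.T @ dz
        gb2 = dz.sum(axis=0)
        dh = dz @ self.mlp_.W2.T
        if mask is not None:
            dh = dh * mask
        dh_pre = dh * (h_pre > 0)
        gW1 = fc.T @ dh_pre
        gb1 = dh_pre.sum(axis=0)
        df = dh_pre @ self.mlp_.W1.T
        dp = df[:, : N_FUSION_VECTORS ** 2]
        # p = 2*sigmoid(gamma*c_flat) - 1
        dsig = dp * 2.0 * s * (1.0 - s)
        ggamma = np.array([float(np.sum(dsig * c_flat))])
        dc_flat = dsig * self.gamma_[0]
        dC = dc_flat.reshape(n, N_FUSION_VECTORS, N_FUSION_VECTORS)
        dU = np.einsum("bjk,bkp->bjp", dC + dC.transpose(0, 2, 1), U, optimize=True)
        dpre = dU * (pre > 0)
        gW = np.einsum("bjp,bjd->jpd", dpre, V, optimize=True)
        gb = dpre.sum(axis=0)
        return loss, [gW, gb, ggamma, gW1, gb1, gW2, gb2], None

    # -- sklearn surface ----------------------------------------------------
    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ConfigError("training requires at least 2 classes")
        self.n_features_in_ = X.shape[1]
        _, _, D = self._split(X)
        self.d_model_ = D
        rng = np.random.default_rng(self.random_state)
        counts = np.bincount(y_idx, minlength=len(self.classes_))
        self.class_weights_ = (class_weights(counts, self.epsilon)
                               if self.class_weighting else np.ones(len(self.classes_)))
        self.feature_sd_ = X.std(axis=0)

        scale = np.sqrt(2.0 / D)
        self.W_ = rng.standard_normal((N_FUSION_VECTORS, self.proj_dim, D)) * scale
        self.b_ = np.zeros((N_FUSION_VECTORS, self.proj_dim))
        self.gamma_ = np.array([float(self.gamma_init)])
        self.mlp_ = build_mlp(fused_dim(D), self.hidden_dim, len(self.classes_),
                              seed=int(rng.integers(2**31)))
        params = [self.W_, self.b_, self.gamma_] + self.mlp_.params()
        decay_mask = [True, False, False, True, False, True, False]
        opt = _AdamW(params, self.weight_decay, decay_mask=decay_mask)
        self.loss_history_ = _train_loop(
            forward_backward=lambda Xb, yb, drop_rng: self._step(Xb, yb, drop_rng),
            opt=opt, X=X, y=y_idx, rng=rng,
            epochs=self.epochs, batch_size=self.batch_size,
            base_lr=self.learning_rate, copies=self.augment_copies,
            noise_scale=self.noise_scale, feature_sd=self.feature_sd_,
        )
        self.n_parameters_ = sum(p.size for p in params)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "mlp_")
        X = check_array(X)
        z, _ = self._forward(X)
        return z

    def predict_proba(self, X):
        return softmax(self.decision_function(X), axis=1)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _train_loop(forward_backward, opt, X, y, rng, epochs, batch_size,
                base_lr, copies, noise_scale, feature_sd) -> list[float]:
    """Shared mini-batch loop: per-epoch augmentation, shuffling, cosine LR."""
    history: list[float] = []
    for epoch in range(epochs):
        # real-time augmentation: fresh noise every epoch
        Xe, ye = augment(X, y, copies, noise_scale, seed=rng, feature_sd=feature_sd)
        order = rng.permutation(len(ye))
        Xe, ye = Xe[order], ye[order]
        lr = _cosine_lr(base_lr, epoch, epochs)
        losses = []
        for start in range(0, len(ye), batch_size):
            Xb = Xe[start:start + batch_size]
            yb = ye[start:start + batch_size]
            loss, grads, _ = forward_backward(Xb, yb, rng)
            _check_finite_loss(loss, epoch)
            opt.step(grads, lr)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def train(features: np.ndarray, labels: np.ndarray,
          config: TrainConfig = TrainConfig()) -> tuple[MLPHeadClassifier, list[float]]:
    """Train the MLP head on fused feature vectors; returns (model, loss history)."""
    clf = MLPHeadClassifier(
        hidden_dim=config.hidden_dim, learning_rate=config.learning_rate,
        weight_decay=config.weight_decay, epochs=config.epochs,
        batch_size=config.batch_size, dropout=config.dropout,
        smoothing_alpha=config.smoothing_alpha, augment_copies=config.augment_copies,
        noise_scale=config.noise_scale, epsilon=config.epsilon,
        random_state=config.seed,
    )
    clf.fit(features, labels)
    return clf, clf.loss_history_
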