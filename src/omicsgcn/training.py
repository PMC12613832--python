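"""Loss functions, optimizer and the two training strategies.

Weighted message passing (WMP) trains everything end-to-end on the
classification loss, with the per-layer fusion weight k balancing
intra- and inter-omics information.  Dual alignment (DA) first pretrains
the graph-convolution weights without labels on

    alpha * L_align + (1 - alpha) * L_recon,

where the alignment term pulls each block's intra- and inter-omics
representations together and the reconstruction term keeps the
intra-omics representation close to the input, then fine-tunes
end-to-end on the classification loss.  Training is full batch (cohorts
are hundreds of samples); early stopping monitors validation loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graphs import ContractError
from .model import (
    GraphSet,
    HiddenState,
    ModelParams,
    Prediction,
    backward,
    forward,
)

logger = logging.getLogger("omicsgcn")

EPS_CLIP = 1e-7


@dataclass
class TrainConfig:
    """Hyperparameters of one training run."""

    strategy: str = "wmp"  # "wmp" | "da"
    alpha: float = 0.5
    max_epochs: int = 500
    patience: int = 20
    pretrain_epochs: int = 100
    learning_rate: float = 1e-3
    min_improvement: float = 1e-6
    align_layers: str = "final"  # "final" | "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("wmp", "da"):
            raise ValueError("strategy must be 'wmp' or 'da'")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.patience < 1 or self.max_epochs < 1:
            raise ValueError("patience and max_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.align_layers not in ("final", "all"):
            raise ValueError("align_layers must be 'final' or 'all'")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    pretrain_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


# ---------------------------------------------------------------------------
# Losses


def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS_CLIP, 1.0 - EPS_CLIP)


def classification_loss(y: np.ndarray, pred: Prediction, task: str) -> float:
    """Mean binary / categorical cross-entropy over samples."""
    y = np.asarray(y)
    p = _clip(pred.scores)
    if task == "binary":
        if not np.isin(y, (0, 1)).all():
            raise ValueError("binary labels must be 0/1")
        p1 = p[:, 0]
        return float(-np.mean(y * np.log(p1) + (1 - y) * np.log(1 - p1)))
    nc = p.shape[1]
    if y.min() < 0 or y.max() >= nc:
        raise ValueError(f"multiclass labels must lie in 0..{nc - 1}")
    return float(-np.mean(np.log(p[np.arange(len(y)), y])))


def _classification_dlogits(y: np.ndarray, pred: Prediction, task: str) -> np.ndarray:
    n = len(y)
    if task == "binary":
        return (pred.scores - np.asarray(y, dtype=float)[:, None]) / n
    onehot = np.zeros_like(pred.scores)
    onehot[np.arange(n), np.asarray(y)] = 1.0
    return (pred.scores - onehot) / n


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    if a.shape != b.shape:
        raise ContractError("MSE arguments must share a shape")
    return float(np.mean((a - b) ** 2))


def alignment_loss(state: HiddenState, layer: int = -1) -> float:
    """Discrepancy between intra- and inter-omics views of each block.

    Sum over blocks of the mean MSE between the intra-omics
    representation and each inter-omics representation of the same block
    (with two omics this is MSE(Z_u, Z_{v->u}) + MSE(Z_v, Z_{u->v})).
    """
    st = state.layers[layer]
    total = 0.0
    for m in state.omics_names:
        terms = [
            _mse(st.z_intra[m], st.z_inter[(m, src)])
            for src in state.omics_names
            if src != m and (m, src) in st.z_inter
        ]
        if terms:
            total += sum(terms) / len(terms)
    return total


def reconstruction_loss(
    state: HiddenState, X: dict[str, np.ndarray], layer: int = -1
) -> float:
    """Sum over blocks of MSE between Z_intra and the transposed input."""
    st = state.layers[layer]
    return sum(
        _mse(st.z_intra[m], np.asarray(X[m], dtype=float).T)
        for m in state.omics_names
    )


def _pretrain_loss_and_seeds(
    params: ModelParams,
    state: HiddenState,
    X: dict[str, np.ndarray],
    alpha: float,
    align_layers: str,
) -> tuple[float, list[dict]]:
    """Total pretraining loss and per-layer gradient seeds for backward."""
    layer_indices = (
        [params.L - 1] if align_layers == "final" else list(range(params.L))
    )
    names = params.omics_names
    n_inter = max(len(names) - 1, 1)
    total = 0.0
    seeds: list[dict] = [{} for _ in range(params.L)]
    for l in layer_indices:
        st = state.layers[l]
        d_intra: dict[str, np.ndarray] = {}
        d_inter: dict[tuple[str, str], np.ndarray] = {}
        for m in names:
            z = st.z_intra[m]
            acc = np.zeros_like(z)
            for src in names:
                if src == m or (m, src) not in st.z_inter:
                    continue
                zi = st.z_inter[(m, src)]
                diff = z - zi
                total += alpha * float(np.mean(diff**2)) / n_inter
                g = alpha * 2.0 * diff / (diff.size * n_inter)
                acc += g
                d_inter[(m, src)] = -g
            xt = np.asarray(X[m], dtype=float).T
            diff_r = z - xt
            total += (1.0 - alpha) * float(np.mean(diff_r**2))
            acc += (1.0 - alpha) * 2.0 * diff_r / diff_r.size
            d_intra[m] = acc
        seeds[l] = {"intra": d_intra, "inter": d_inter}
    return total, seeds


# ---------------------------------------------------------------------------
# Optimizer


class Adam:
    """Adaptive-moment gradient descent over a list of parameter arrays."""

    def __init__(self, arrays: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.arrays = arrays
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for a, g, m, v in zip(self.arrays, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            a -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# Training strategies


def pretrain_dual(
    params: ModelParams,
    graphs: GraphSet,
    X: dict[str, np.ndarray],
    config: TrainConfig,
) -> TrainHistory:
    """Unsupervised pretraining of the graph-convolution weights.

    Minimizes alpha * alignment + (1 - alpha) * reconstruction by Adam
    for ``pretrain_epochs`` epochs; no labels and no head update.
    Updates ``params`` in place and returns the loss trace.
    """
    history = TrainHistory()
    arrays = params.trainable_arrays(include_head=False)
    opt = Adam(arrays, lr=config.learning_rate)
    for epoch in range(config.pretrain_epochs):
        _, state = forward(params, graphs, X)
        loss, seeds = _pretrain_loss_and_seeds(
            params, state, X, config.alpha, config.align_layers
        )
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"pretraining diverged at epoch {epoch} (loss={loss}); "
                "reduce the learning rate"
            )
        history.pretrain_loss.append(loss)
        grads = backward(params, graphs, state, d_logits=None, z_seeds=seeds)
        opt.step(grads.arrays(include_head=False))
    return history


def train(
    params: ModelParams,
    graphs: GraphSet,
    X_train: dict[str, np.ndarray],
    y_train: np.ndarray,
    X_val: dict[str, np.ndarray],
    y_val: np.ndarray,
    config: TrainConfig,
) -> tuple[ModelParams, TrainHistory]:
    """Supervised training with early stopping on validation loss.

    For the DA strategy, :func:`pretrain_dual` runs first, then the
    whole model (including the head) is fine-tuned end-to-end.  Stops
    when validation loss has not improved by ``min_improvement`` for
    ``patience`` consecutive epochs; the returned parameters are the
    snapshot from the best validation epoch.
    """
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class; cannot train")
    if config.strategy == "da":
        history = pretrain_dual(params, graphs, X_train, config)
    else:
        history = TrainHistory()

    arrays = params.trainable_arrays(include_head=True)
    opt = Adam(arrays, lr=config.learning_rate)
    best_loss = np.inf
    best_params = params.copy()
    best_epoch = 0
    bad_epochs = 0
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        pred, state = forward(params, graphs, X_train)
        loss = classification_loss(y_train, pred, params.task)
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        d_logits = _classification_dlogits(y_train, pred, params.task)
        grads = backward(params, graphs, state, d_logits=d_logits)
        opt.step(grads.arrays(include_head=True))

        pred_val, _ = forward(params, graphs, X_val)
        val_loss = classification_loss(y_val, pred_val, params.task)
        history.train_loss.append(loss)
        history.val_loss.append(val_loss)
        if val_loss < best_loss - config.min_improvement:
            best_loss = val_loss
            best_epoch = epoch
            best_params = params.copy()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    history.stopped_epoch = epoch
    history.best_epoch = best_epoch
    logger.debug(
        "training stopped at epoch %d (best %d, val loss %.5f)",
        epoch, best_epoch, best_loss,
    )
    return best_params, history


def total_wmp_loss(
    params: ModelParams,
    graphs: GraphSet,
    X: dict[str, np.ndarray],
    y: np.ndarray,
) -> float:
    """Classification loss of a fresh forward pass (finite-difference target)."""
    pred, _ = forward(params, graphs, X)
    return classification_loss(np.asarray(y), pred, params.task)
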