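"""Feature-space graph-convolutional model with cross-omics message passing.

Each layer runs, in parallel for every omics block m:

* an intra-omics graph convolution  Z_m = act(W_m @ A_hat_m @ H_m), and
* one bipartite convolution per other block o,
  Z_{o->m} = act(W_{o->m} @ B_hat_{m,o} @ H_o),

where H_m (features x samples) is the previous layer's representation
(H^0 = X^T), A_hat the symmetrically normalized intra-omics adjacency
and B_hat_{m,o} the normalized incidence block aggregating o's features
into m's.  The branches are fused per layer as

    H_m' = k * Z_m + (1 - k) * mean_o Z_{o->m},

with k in [0, 1] trading intra- against inter-omics information (the
ablation modes use only one branch).  The final-layer blocks are
concatenated and fed to a single fully connected head with sigmoid
(binary) or softmax (multiclass) output.  Weight matrices are square, so
the feature-space dimension is preserved through every layer and each
output coordinate remains identified with an input feature.

Everything is dense numpy; gradients are computed analytically in
:func:`backward` (verified against finite differences in the test
suite).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .graphs import ContractError, NormalizedBipartite, NormalizedGraph

MODES = ("both", "intra_only", "inter_only")
TASKS = ("binary", "multiclass")


@dataclass
class GraphSet:
    """Normalized graphs keyed by omics name / (destination, source) pair."""

    intra: dict[str, np.ndarray]
    inter: dict[tuple[str, str], np.ndarray]
    feature_ids: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_normalized(
        cls,
        intra: dict[str, NormalizedGraph],
        bipartite: dict[tuple[str, str], NormalizedBipartite],
    ) -> "GraphSet":
        """Assemble from per-omics graphs and per-pair bipartite blocks.

        A bipartite entry keyed ``(u, v)`` contributes ``hat_bu`` as the
        v->u aggregation block and ``hat_bv`` as the u->v block.
        """
        inter: dict[tuple[str, str], np.ndarray] = {}
        for (u, v), nb in bipartite.items():
            inter[(u, v)] = nb.hat_bu
            inter[(v, u)] = nb.hat_bv
        return cls(
            intra={m: g.values for m, g in intra.items()},
            inter=inter,
            feature_ids={m: list(g.feature_ids) for m, g in intra.items()},
        )


@dataclass
class ModelParams:
    """All trainable weights plus the architecture hyperparameters."""

    omics_names: list[str]
    dims: dict[str, int]
    L: int
    k: float
    leaky_slope: float
    task: str
    nc: int
    mode: str
    intra_weights: list[dict[str, np.ndarray]]
    inter_weights: list[dict[tuple[str, str], np.ndarray]]
    head_weight: np.ndarray

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("layer count L must be >= 1")
        if not 0.0 <= self.k <= 1.0:
            raise ValueError("fusion weight k must lie in [0, 1]")
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be positive")
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.nc < 1 or (self.task == "multiclass" and self.nc < 2):
            raise ValueError("invalid class count")
        for layer in self.intra_weights:
            for m, w in layer.items():
                if w.shape != (self.dims[m], self.dims[m]):
                    raise ValueError(f"intra weight for {m!r} must be square {self.dims[m]}")
        for layer in self.inter_weights:
            for (dst, _src), w in layer.items():
                if w.shape != (self.dims[dst], self.dims[dst]):
                    raise ValueError(f"inter weight into {dst!r} must be square {self.dims[dst]}")

    @property
    def n_out(self) -> int:
        """Head output columns: 1 sigmoid unit for binary, nc for multiclass."""
        return 1 if self.task == "binary" else self.nc

    @property
    def total_dim(self) -> int:
        return sum(self.dims[m] for m in self.omics_names)

    def trainable_arrays(self, include_head: bool = True) -> list[np.ndarray]:
        arrays: list[np.ndarray] = []
        for layer in self.intra_weights:
            arrays.extend(layer.values())
        for layer in self.inter_weights:
            arrays.extend(layer.values())
        if include_head:
            arrays.append(self.head_weight)
        return arrays

    def copy(self) -> "ModelParams":
        return copy.deepcopy(self)


def init_params(
    dims: dict[str, int],
    L: int = 2,
    k: float = 0.5,
    leaky_slope: float = 0.01,
    task: str = "binary",
    nc: int = 2,
    mode: str = "both",
    seed: int | np.random.Generator = 0,
) -> ModelParams:
    """Scaled-uniform (Glorot-style) initialization of all weights."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = list(dims)

    def uniform(fan_in: int, fan_out: int, shape):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape)

    intra, inter = [], []
    for _ in range(L):
        intra.append({m: uniform(d, d, (d, d)) for m, d in ((m, dims[m]) for m in names)})
        inter.append(
            {
                (dst, src): uniform(dims[dst], dims[dst], (dims[dst], dims[dst]))
                for dst in names
                for src in names
                if dst != src
            }
        )
    total = sum(dims.values())
    n_out = 1 if task == "binary" else nc
    head = uniform(total, n_out, (total, n_out))
    return ModelParams(
        omics_names=names,
        dims=dict(dims),
        L=L,
        k=k,
        leaky_slope=leaky_slope,
        task=task,
        nc=nc,
        mode=mode,
        intra_weights=intra,
        inter_weights=inter,
        head_weight=head,
    )


# ---------------------------------------------------------------------------
# Elementary layer operations


def leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def _leaky_grad(pre: np.ndarray, slope: float) -> np.ndarray:
    return np.where(pre >= 0, 1.0, slope)


def intra_layer(H: np.ndarray, A_hat, W: np.ndarray, slope: float = 0.01) -> np.ndarray:
    """One intra-omics convolution: LeakyReLU(W @ A_hat @ H)."""
    A = A_hat.values if isinstance(A_hat, NormalizedGraph) else np.asarray(A_hat)
    H = np.asarray(H, dtype=float)
    if A.shape[0] != A.shape[1] or A.shape[1] != H.shape[0] or W.shape != A.shape:
        raise ContractError("intra_layer shape mismatch")
    return leaky_relu(W @ (A @ H), slope)


def inter_layer(H_other: np.ndarray, B_hat: np.ndarray, W: np.ndarray, slope: float = 0.01) -> np.ndarray:
    """One bipartite convolution: LeakyReLU(W @ B_hat @ H_other)."""
    B = np.asarray(B_hat, dtype=float)
    H_other = np.asarray(H_other, dtype=float)
    if B.shape[1] != H_other.shape[0] or W.shape != (B.shape[0], B.shape[0]):
        raise ContractError("inter_layer shape mismatch")
    return leaky_relu(W @ (B @ H_other), slope)


def fuse_weighted(Z_intra: np.ndarray, Z_inter: np.ndarray, k: float) -> np.ndarray:
    """k * Z_intra + (1 - k) * Z_inter, exact at the endpoints."""
    if not 0.0 <= k <= 1.0:
        raise ValueError("k must lie in [0, 1]")
    if Z_intra.shape != Z_inter.shape:
        raise ContractError("fuse_weighted shape mismatch")
    if k == 1.0:
        return Z_intra.copy()
    if k == 0.0:
        return Z_inter.copy()
    return k * Z_intra + (1.0 - k) * Z_inter


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class Prediction:
    logits: np.ndarray  # n x n_out
    scores: np.ndarray  # n x n_out probabilities


def predict_head(H_blocks: list[np.ndarray], W: np.ndarray, task: str) -> Prediction:
    """Concatenate final representations and apply the linear head.

    Blocks are stacked feature-wise to (sum d) x n, transposed to sample
    rows and multiplied by W; sigmoid for binary, softmax rows for
    multiclass.
    """
    H_cat = np.vstack(H_blocks)
    logits = H_cat.T @ W
    if task == "binary":
        scores = 1.0 / (1.0 + np.exp(-logits))
    else:
        scores = _softmax(logits)
    return Prediction(logits=logits, scores=scores)


# ---------------------------------------------------------------------------
# Full forward pass


@dataclass
class LayerState:
    """Intermediate quantities of one layer (kept for losses/backprop)."""

    h_in: dict[str, np.ndarray]
    ah_intra: dict[str, np.ndarray]          # A_hat @ H, pre-weight
    pre_intra: dict[str, np.ndarray]
    z_intra: dict[str, np.ndarray]
    bh_inter: dict[tuple[str, str], np.ndarray]   # B_hat @ H_src
    pre_inter: dict[tuple[str, str], np.ndarray]
    z_inter: dict[tuple[str, str], np.ndarray]
    h_out: dict[str, np.ndarray]


@dataclass
class HiddenState:
    """Per-layer representations; ``layers[-1].h_out`` feeds the head."""

    omics_names: list[str]
    layers: list[LayerState]

    def final_blocks(self) -> list[np.ndarray]:
        return [self.layers[-1].h_out[m] for m in self.omics_names]


def _check_graphs(params: ModelParams, graphs: GraphSet) -> None:
    names = params.omics_names
    for m in names:
        if params.mode != "inter_only" and m not in graphs.intra:
            raise ContractError(f"missing intra-omics graph for {m!r}")
    if params.mode != "intra_only":
        missing = [
            (dst, src)
            for dst in names
            for src in names
            if dst != src and (dst, src) not in graphs.inter
        ]
        if missing:
            raise ContractError(f"missing bipartite graph block(s) for pair(s): {missing}")


def forward(
    params: ModelParams, graphs: GraphSet, X: dict[str, np.ndarray]
) -> tuple[Prediction, HiddenState]:
    """Run L layers and the prediction head on sample-major inputs.

    ``X[m]`` is n x d_m; internally H^0_m = X_m^T.  Works for any number
    of omics blocks >= 1 intra-only, >= 2 otherwise.
    """
    _check_graphs(params, graphs)
    names = params.omics_names
    n = next(iter(X.values())).shape[0]
    H = {}
    for m in names:
        Xm = np.asarray(X[m], dtype=float)
        if Xm.shape != (n, params.dims[m]):
            raise ContractError(f"input block {m!r} must be n x {params.dims[m]}")
        H[m] = Xm.T
    slope = params.leaky_slope
    need_intra = params.mode != "inter_only"
    need_inter = params.mode != "intra_only" and len(names) > 1
    layers: list[LayerState] = []
    for l in range(params.L):
        st = LayerState({m: H[m] for m in names}, {}, {}, {}, {}, {}, {}, {})
        for m in names:
            if need_intra:
                ah = graphs.intra[m] @ H[m]
                pre = params.intra_weights[l][m] @ ah
                st.ah_intra[m] = ah
                st.pre_intra[m] = pre
                st.z_intra[m] = leaky_relu(pre, slope)
            if need_inter:
                for src in names:
                    if src == m:
                        continue
                    bh = graphs.inter[(m, src)] @ H[src]
                    pre = params.inter_weights[l][(m, src)] @ bh
                    st.bh_inter[(m, src)] = bh
                    st.pre_inter[(m, src)] = pre
                    st.z_inter[(m, src)] = leaky_relu(pre, slope)
        for m in names:
            if params.mode == "intra_only" or not need_inter:
                st.h_out[m] = st.z_intra[m]
            else:
                inters = [st.z_inter[(m, src)] for src in names if src != m]
                z_inter = inters[0] if len(inters) == 1 else sum(inters) / len(inters)
                if params.mode == "inter_only":
                    st.h_out[m] = z_inter
                else:
                    st.h_out[m] = fuse_weighted(st.z_intra[m], z_inter, params.k)
        H = st.h_out
        layers.append(st)
    state = HiddenState(list(names), layers)
    pred = predict_head(state.final_blocks(), params.head_weight, params.task)
    return pred, state


# The M-omics generalization and the two-omics path are the same code;
# the alias keeps the two entry points explicit at call sites.
forward_multiomics = forward


def extract_embeddings(
    state: HiddenState,
    feature_ids: dict[str, list[str]] | None = None,
    sample_ids: list[str] | None = None,
):
    """Sample-major matrix of the final-layer representations.

    Returns the transpose of the feature-wise concatenation that feeds
    the prediction head (omics blocks in model order), as a pandas
    DataFrame when identifiers are available.
    """
    import pandas as pd

    emb = np.vstack(state.final_blocks()).T
    cols: list[str] | None = None
    if feature_ids is not None:
        cols = [f for m in state.omics_names for f in feature_ids[m]]
    return pd.DataFrame(emb, index=sample_ids, columns=cols)


# ---------------------------------------------------------------------------
# Analytic gradients


@dataclass
class Gradients:
    intra: list[dict[str, np.ndarray]]
    inter: list[dict[tuple[str, str], np.ndarray]]
    head: np.ndarray

    def arrays(self, include_head: bool = True) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.intra:
            out.extend(layer.values())
        for layer in self.inter:
            out.extend(layer.values())
        if include_head:
            out.append(self.head)
        return out


def backward(
    params: ModelParams,
    graphs: GraphSet,
    state: HiddenState,
    d_logits: np.ndarray | None = None,
    z_seeds: list[dict] | None = None,
) -> Gradients:
    """Backpropagate loss gradients through head and all layers.

    ``d_logits`` (n x n_out) seeds the classification path;
    ``z_seeds[l]``, when given, holds extra gradient contributions
    ``{"intra": {m: dZ}, "inter": {(m, src): dZ}}`` attached directly to
    layer ``l``'s pre-fusion representations (used by the alignment /
    reconstruction objectives).
    """
    names = params.omics_names
    slope = params.leaky_slope
    need_intra = params.mode != "inter_only"
    need_inter = params.mode != "intra_only" and len(names) > 1
    grads = Gradients(
        intra=[
            {m: np.zeros_like(w) for m, w in layer.items()}
            for layer in params.intra_weights
        ],
        inter=[
            {key: np.zeros_like(w) for key, w in layer.items()}
            for layer in params.inter_weights
        ],
        head=np.zeros_like(params.head_weight),
    )
    d_h: dict[str, np.ndarray] = {
        m: np.zeros_like(state.layers[-1].h_out[m]) for m in names
    }
    if d_logits is not None:
        H_cat = np.vstack(state.final_blocks())
        grads.head = H_cat @ d_logits
        d_cat = params.head_weight @ d_logits.T
        offset = 0
        for m in names:
            d = params.dims[m]
            d_h[m] = d_h[m] + d_cat[offset : offset + d]
            offset += d

    n_inter = len(names) - 1
    for l in range(params.L - 1, -1, -1):
        st = state.layers[l]
        seeds = z_seeds[l] if z_seeds is not None and z_seeds[l] else {}
        d_h_in = {m: np.zeros_like(st.h_in[m]) for m in names}
        for m in names:
            if need_intra:
                if params.mode == "intra_only" or not need_inter:
                    coef = 1.0
                elif params.mode == "inter_only":
                    coef = 0.0
                else:
                    coef = params.k
                d_z = coef * d_h[m]
                if "intra" in seeds and m in seeds["intra"]:
                    d_z = d_z + seeds["intra"][m]
                if np.any(d_z):
                    d_pre = d_z * _leaky_grad(st.pre_intra[m], slope)
                    grads.intra[l][m] += d_pre @ st.ah_intra[m].T
                    d_h_in[m] += graphs.intra[m].T @ (
                        params.intra_weights[l][m].T @ d_pre
                    )
            if need_inter:
                if params.mode == "intra_only":
                    coef = 0.0
                elif params.mode == "inter_only":
                    coef = 1.0 / n_inter
                else:
                    coef = (1.0 - params.k) / n_inter
                for src in names:
                    if src == m:
                        continue
                    d_z = coef * d_h[m]
                    if "inter" in seeds and (m, src) in seeds["inter"]:
                        d_z = d_z + seeds["inter"][(m, src)]
                    if np.any(d_z):
                        d_pre = d_z * _leaky_grad(st.pre_inter[(m, src)], slope)
                        grads.inter[l][(m, src)] += d_pre @ st.bh_inter[(m, src)].T
                        d_h_in[src] += graphs.inter[(m, src)].T @ (
                            params.inter_weights[l][(m, src)].T @ d_pre
                        )
        d_h = d_h_in
    return grads
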