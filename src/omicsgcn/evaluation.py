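"""Metrics (AUROC, Youden threshold, MCC) and experiment runners.

The protocol mirrors repeated-holdout evaluation of high-dimensional
cohorts: per repeat, a stratified 80/20 test split and an 80/20
validation sub-split, graphs rebuilt from the training portion, the
model trained with early stopping, and test AUROC / MCC collected.
Binary MCC uses the Youden-index threshold (maximizing sensitivity +
specificity) applied to the predicted probabilities; multiclass uses
macro one-vs-rest AUROC and argmax labels.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from . import preprocess
from .graphs import (
    BipartiteGraph,
    assemble_and_normalize_bipartite,
    auto_threshold,
    build_data_driven_bipartite,
    compute_affinity,
    hybrid_bipartite,
    median_distance_sigma,
    normalize_sym,
    threshold_graph,
    _pairwise_affinity,
)
from .model import GraphSet, ModelParams, forward, init_params
from .preprocess import Split, make_split
from .training import TrainConfig, TrainHistory, train

logger = logging.getLogger("omicsgcn")


# ---------------------------------------------------------------------------
# Metrics


def auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Probability that a random positive outranks a random negative
    (ties count one half)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC is undefined for single-class labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def youden_threshold(labels: np.ndarray, scores: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the distinct observed scores; a sample is predicted
    positive when its score is >= the threshold; among equally optimal
    thresholds the smallest is returned.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("Youden threshold is undefined for single-class labels")
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    best_t, best_j = np.inf, -np.inf
    for t in np.unique(scores):
        pred = scores >= t
        sens = (pred & pos).sum() / n_pos
        spec = (~pred & ~pos).sum() / n_neg
        j = sens + spec
        if j > best_j or (j == best_j and t < best_t):
            best_j, best_t = j, t
    return float(best_t)


def mcc(labels: np.ndarray, predicted_labels: np.ndarray) -> float:
    """Matthews correlation coefficient (binary or multiclass);
    0 by convention when a confusion-matrix marginal is zero."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(matthews_corrcoef(np.asarray(labels), np.asarray(predicted_labels)))


def evaluate_split(
    params: ModelParams,
    graphs: GraphSet,
    X_test: dict[str, np.ndarray],
    y_test: np.ndarray,
) -> dict:
    """Held-out metrics of a trained model on one split."""
    pred, _ = forward(params, graphs, X_test)
    y = np.asarray(y_test)
    if params.task == "binary":
        scores = pred.scores[:, 0]
        auc = auroc(y, scores)
        t = youden_threshold(y, scores)
        labels_hat = (scores >= t).astype(int)
        return {"auroc": auc, "mcc": mcc(y, labels_hat), "threshold": float(t)}
    auc = float(
        roc_auc_score(y, pred.scores, multi_class="ovr", average="macro")
    )
    labels_hat = pred.scores.argmax(axis=1)
    return {"auroc": auc, "mcc": mcc(y, labels_hat), "threshold": float("nan")}


# ---------------------------------------------------------------------------
# Dataset and experiment configuration


@dataclass
class MultiOmicsDataset:
    """Sample-aligned omics blocks, labels and optional prior networks."""

    X: dict[str, pd.DataFrame]
    y: pd.Series
    prior_bipartite: dict[tuple[str, str], BipartiteGraph] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mat in self.X.items():
            if not (mat.index == self.y.index).all():
                raise ValueError(f"omics block {name!r} is not sample-aligned with y")


def from_synthetic(synth) -> MultiOmicsDataset:
    """View a generated cohort as a runnable dataset (true bipartite as prior)."""
    return MultiOmicsDataset(
        X={"u": synth.X_u, "v": synth.X_v},
        y=synth.y,
        prior_bipartite={("u", "v"): synth.bipartite},
    )


@dataclass
class ExperimentConfig:
    """Everything one repeated-split experiment needs.

    Training defaults (full-batch Adam at 1e-3, patience 20, epoch
    ceiling 400) are sized for standardized cohorts of a few hundred
    samples.
    """

    # graph construction (per repeat, from training data only)
    affinity_method: str = "cosine"
    intra_eps: dict | None = None          # per-omics eps; None -> auto
    intra_target_degree: int = 10
    bipartite_source: str = "prior"        # "prior" | "data" | "hybrid"
    bipartite_eps: float = 0.5
    hybrid_lam: float = 0.5
    sigma: float | None = None
    # model
    L: int = 2
    k: float = 0.5
    leaky_slope: float = 0.01
    mode: str = "both"
    task: str = "binary"
    # training
    strategy: str = "wmp"
    alpha: float = 0.5
    learning_rate: float = 1e-3
    max_epochs: int = 400
    patience: int = 20
    pretrain_epochs: int = 50
    # protocol
    n_repeats: int = 20
    seed: int = 0

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            strategy=self.strategy,
            alpha=self.alpha,
            max_epochs=self.max_epochs,
            patience=self.patience,
            pretrain_epochs=self.pretrain_epochs,
            learning_rate=self.learning_rate,
            seed=self.seed,
        )


@dataclass
class EvalReport:
    """Per-repeat metrics plus aggregate summary."""

    auroc: list[float] = field(default_factory=list)
    mcc: list[float] = field(default_factory=list)
    threshold: list[float] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def n_repeats(self) -> int:
        return len(self.auroc)

    @property
    def partial(self) -> bool:
        return bool(self.errors)

    def aggregate(self) -> dict:
        out = {}
        for name in ("auroc", "mcc", "threshold"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if vals.size:
                out[f"{name}_mean"] = float(np.mean(vals))
                out[f"{name}_sd"] = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out["n_repeats"] = self.n_repeats
        return out

    def to_json(self) -> str:
        payload = {
            "per_repeat": {
                "auroc": self.auroc,
                "mcc": self.mcc,
                "threshold": self.threshold,
            },
            "aggregate": self.aggregate(),
            "errors": self.errors,
            "partial": self.partial,
            "config": self.config,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        payload = json.loads(text)
        return cls(
            auroc=payload["per_repeat"]["auroc"],
            mcc=payload["per_repeat"]["mcc"],
            threshold=payload["per_repeat"]["threshold"],
            errors=payload.get("errors", []),
            config=payload.get("config", {}),
        )


# ---------------------------------------------------------------------------
# Per-repeat pipeline


def _build_graphs(
    data: MultiOmicsDataset,
    X_train: dict[str, pd.DataFrame],
    config: ExperimentConfig,
) -> GraphSet:
    """Training-data intra graphs + prior / data-driven bipartite blocks."""
    intra = {}
    for name, mat in X_train.items():
        fv = mat.to_numpy(dtype=float).T  # features x samples
        sigma = config.sigma
        if config.affinity_method == "rbf" and sigma is None:
            sigma = median_distance_sigma(fv)
        aff = compute_affinity(
            fv, config.affinity_method, sigma, feature_ids=list(mat.columns)
        )
        eps = None if config.intra_eps is None else config.intra_eps.get(name)
        if eps is None:
            eps = auto_threshold(aff, config.intra_target_degree)
        intra[name] = normalize_sym(threshold_graph(aff, eps, omics_id=name))

    names = list(X_train)
    bipartite = {}
    for i, u in enumerate(names):
        for v in names[i + 1 :]:
            prior = data.prior_bipartite.get((u, v))
            if prior is not None:
                # align the prior's feature order with the matrices
                bip = _reindex_bipartite(prior, list(X_train[u].columns), list(X_train[v].columns))
            if config.bipartite_source == "prior" and prior is not None:
                pass
            elif config.bipartite_source == "hybrid" and prior is not None:
                aff_uv = _pairwise_affinity(
                    X_train[u].to_numpy(dtype=float).T,
                    X_train[v].to_numpy(dtype=float).T,
                    config.affinity_method,
                    config.sigma,
                )
                bip = hybrid_bipartite(bip, aff_uv, config.hybrid_lam, config.bipartite_eps)
            else:
                bip = build_data_driven_bipartite(
                    X_train[u].to_numpy(dtype=float).T,
                    X_train[v].to_numpy(dtype=float).T,
                    method=config.affinity_method,
                    eps=config.bipartite_eps,
                    sigma=config.sigma,
                    u_ids=list(X_train[u].columns),
                    v_ids=list(X_train[v].columns),
                )
            bipartite[(u, v)] = assemble_and_normalize_bipartite(bip)
    return GraphSet.from_normalized(intra, bipartite)


def _reindex_bipartite(
    bip: BipartiteGraph, row_ids: list[str], col_ids: list[str]
) -> BipartiteGraph:
    if bip.row_feature_ids == row_ids and bip.col_feature_ids == col_ids:
        return bip
    inc = pd.DataFrame(
        bip.incidence, index=bip.row_feature_ids, columns=bip.col_feature_ids
    )
    inc = inc.reindex(index=row_ids, columns=col_ids, fill_value=0)
    return BipartiteGraph(row_ids, col_ids, inc.to_numpy(dtype=np.int8))


def _n_classes(y: pd.Series) -> int:
    return int(len(np.unique(y.to_numpy())))


def run_repeat(
    data: MultiOmicsDataset, config: ExperimentConfig, repeat: int
) -> tuple[dict, ModelParams, GraphSet, Split, TrainHistory]:
    """One split -> graphs -> training -> held-out metrics."""
    split = make_split(data.X, data.y, config.seed + repeat)
    graphs = _build_graphs(data, split.X_train, config)
    nc = _n_classes(data.y)
    init_rng = np.random.default_rng([config.seed, repeat])
    params = init_params(
        dims={m: split.X_train[m].shape[1] for m in data.X},
        L=config.L,
        k=config.k,
        leaky_slope=config.leaky_slope,
        task=config.task,
        nc=nc,
        mode=config.mode,
        seed=init_rng,
    )
    to_arrays = lambda d: {m: v.to_numpy(dtype=float) for m, v in d.items()}
    params, history = train(
        params,
        graphs,
        to_arrays(split.X_train),
        split.y_train.to_numpy(),
        to_arrays(split.X_val),
        split.y_val.to_numpy(),
        config.train_config(),
    )
    metrics = evaluate_split(params, graphs, to_arrays(split.X_test), split.y_test.to_numpy())
    return metrics, params, graphs, split, history


def repeated_eval(
    data: MultiOmicsDataset, config: ExperimentConfig, n_repeats: int | None = None
) -> EvalReport:
    """Aggregate test metrics over repeated stratified splits."""
    n_repeats = config.n_repeats if n_repeats is None else n_repeats
    report = EvalReport(config={**_config_echo(config), "n_repeats": n_repeats})
    for r in range(n_repeats):
        try:
            metrics, *_ = run_repeat(data, config, r)
        except Exception as exc:  # noqa: BLE001 - repeat failures are recorded
            logger.warning("repeat %d failed: %s", r, exc)
            report.errors.append(f"repeat {r}: {exc}")
            continue
        report.auroc.append(metrics["auroc"])
        report.mcc.append(metrics["mcc"])
        report.threshold.append(metrics["threshold"])
    return report


def _config_echo(config: ExperimentConfig) -> dict:
    echo = asdict(config)
    return {k: v for k, v in echo.items() if not isinstance(v, np.ndarray)}


# ---------------------------------------------------------------------------
# Experiment runners


def run_ablation(
    data: MultiOmicsDataset, config: ExperimentConfig
) -> dict[str, EvalReport]:
    """Same splits and seeds under both / intra_only / inter_only modes."""
    from dataclasses import replace

    return {
        mode: repeated_eval(data, replace(config, mode=mode))
        for mode in ("both", "intra_only", "inter_only")
    }


def run_k_sweep(
    data: MultiOmicsDataset,
    config: ExperimentConfig,
    k_values: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
) -> pd.DataFrame:
    """Mean AUROC / MCC per fusion weight k over shared splits."""
    from dataclasses import replace

    rows = []
    for k in k_values:
        if not 0.0 <= k <= 1.0:
            raise ValueError("k values must lie in [0, 1]")
        report = repeated_eval(data, replace(config, k=float(k)))
        agg = report.aggregate()
        rows.append(
            {
                "k": float(k),
                "auroc_mean": agg.get("auroc_mean", float("nan")),
                "mcc_mean": agg.get("mcc_mean", float("nan")),
            }
        )
    return pd.DataFrame(rows)


def rewire_bipartite(
    bip: BipartiteGraph, fraction: float, seed: int = 0
) -> BipartiteGraph:
    """Randomly rewire a fraction of the cross-omics edges.

    Removes ``ceil(fraction * |E|)`` uniformly chosen edges and adds the
    same number of uniformly chosen absent pairs, preserving the edge
    count.  Dense graphs where too few absent pairs remain are rewired
    best-effort with a warning.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    inc = bip.incidence.copy()
    rng = np.random.default_rng(seed)
    edges = np.flatnonzero(inc)
    n_move = int(np.ceil(fraction * edges.size))
    if n_move == 0:
        return BipartiteGraph(list(bip.row_feature_ids), list(bip.col_feature_ids), inc)
    remove = rng.choice(edges, size=n_move, replace=False)
    flat = inc.reshape(-1)
    flat[remove] = 0
    absent = np.flatnonzero(flat == 0)
    if absent.size < n_move:
        warnings.warn("graph too dense to rewire fully; best effort", stacklevel=2)
        n_move = absent.size
    add = rng.choice(absent, size=n_move, replace=False)
    flat[add] = 1
    return BipartiteGraph(
        list(bip.row_feature_ids), list(bip.col_feature_ids), flat.reshape(inc.shape)
    )
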