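"""Construction and normalization of feature-level graphs.

Intra-omics graphs connect molecular features of a single omics type
(e.g. gene--gene co-expression); inter-omics bipartite graphs connect
features of two omics types (e.g. miRNA--target-mRNA).  Graphs are built
either from data affinities (cosine, Pearson, Gaussian RBF) thresholded
at ``eps``, or from prior edge lists such as TargetScan-style
regulator/target tables, or from a blend of the two.

All matrices here are feature-major: a "feature vector" is the row of
values of one feature across samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("omicsgcn")

AFFINITY_METHODS = ("cosine", "pearson", "rbf")


class ContractError(ValueError):
    """An input violates a structural precondition (shape, symmetry...)."""


@dataclass
class AffinityMatrix:
    """Dense pairwise affinity between features of one block.

    ``values[i, j]`` is cosine similarity, Pearson correlation or a
    Gaussian kernel between feature i and feature j.  Degenerate pairs
    (zero-norm vector under cosine, zero-variance under Pearson) are
    assigned affinity 0 so constant features never gain edges.
    """

    feature_ids: list[str]
    values: np.ndarray
    method: str
    sigma: float | None = None


@dataclass
class FeatureGraph:
    """Binary intra-omics adjacency with zero diagonal."""

    omics_id: str
    feature_ids: list[str]
    adjacency: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ContractError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ContractError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ContractError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ContractError("adjacency must be binary")


@dataclass
class NormalizedGraph:
    """Symmetrically normalized adjacency D^{-1/2} (A + I) D^{-1/2}."""

    feature_ids: list[str]
    values: np.ndarray


@dataclass
class BipartiteGraph:
    """Binary incidence between two feature sets (rows -> omics1)."""

    row_feature_ids: list[str]
    col_feature_ids: list[str]
    incidence: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.incidence)
        if b.shape != (len(self.row_feature_ids), len(self.col_feature_ids)):
            raise ContractError("incidence shape does not match id lists")
        if not np.isin(b, (0, 1)).all():
            raise ContractError("incidence must be binary")

    @property
    def n_edges(self) -> int:
        return int(self.incidence.sum())


@dataclass
class NormalizedBipartite:
    """Normalized off-diagonal blocks of the joint bipartite adjacency.

    ``hat_bu`` (p x q) aggregates omics2 signals into omics1 features;
    ``hat_bv`` (q x p) is its transpose.
    """

    row_feature_ids: list[str]
    col_feature_ids: list[str]
    hat_bu: np.ndarray
    hat_bv: np.ndarray


# ---------------------------------------------------------------------------
# Affinities


def _pairwise_affinity(
    X: np.ndarray,
    Y: np.ndarray,
    method: str,
    sigma: float | None,
) -> np.ndarray:
    """Affinity between rows of X (d1 x n) and rows of Y (d2 x n)."""
    if method not in AFFINITY_METHODS:
        raise ValueError(f"unknown affinity method {method!r}")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ContractError("feature matrices must share the sample axis")
    if method == "rbf":
        if sigma is None or sigma <= 0:
            raise ValueError("rbf affinity requires sigma > 0")
        sq = (
            (X**2).sum(axis=1)[:, None]
            + (Y**2).sum(axis=1)[None, :]
            - 2.0 * X @ Y.T
        )
        np.maximum(sq, 0.0, out=sq)
        return np.exp(-sq / (2.0 * sigma**2))
    if method == "pearson":
        X = X - X.mean(axis=1, keepdims=True)
        Y = Y - Y.mean(axis=1, keepdims=True)
    nx = np.linalg.norm(X, axis=1)
    ny = np.linalg.norm(Y, axis=1)
    bad_x, bad_y = nx == 0, ny == 0
    if bad_x.any() or bad_y.any():
        n_bad = int(bad_x.sum() + bad_y.sum())
        warnings.warn(
            f"{n_bad} degenerate feature vector(s) for {method} affinity; "
            "their affinities are set to 0",
            stacklevel=2,
        )
    out = X @ Y.T / np.outer(np.where(bad_x, 1.0, nx), np.where(bad_y, 1.0, ny))
    out[bad_x, :] = 0.0
    out[:, bad_y] = 0.0
    return np.clip(out, -1.0, 1.0)


def compute_affinity(
    feature_vectors: np.ndarray,
    method: str = "cosine",
    sigma: float | None = None,
    feature_ids: list[str] | None = None,
) -> AffinityMatrix:
    """Full pairwise affinity among rows of ``feature_vectors`` (d x n)."""
    X = np.asarray(feature_vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 2:
        raise ContractError("need a d x n matrix with d >= 1 and n >= 2")
    if np.isnan(X).any():
        raise ContractError("affinity input must not contain missing values")
    vals = _pairwise_affinity(X, X, method, sigma)
    vals = (vals + vals.T) / 2.0  # enforce exact symmetry
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(X.shape[0])]
    return AffinityMatrix(list(feature_ids), vals, method, sigma)


def median_distance_sigma(feature_vectors: np.ndarray) -> float:
    """Median pairwise Euclidean distance heuristic for the RBF width."""
    X = np.asarray(feature_vectors, dtype=float)
    sq = (
        (X**2).sum(axis=1)[:, None]
        + (X**2).sum(axis=1)[None, :]
        - 2.0 * X @ X.T
    )
    np.maximum(sq, 0.0, out=sq)
    d = np.sqrt(sq[np.triu_indices_from(sq, k=1)])
    med = float(np.median(d)) if d.size else 1.0
    return med if med > 0 else 1.0


def auto_threshold(affinity: AffinityMatrix, target_degree: int = 10) -> float:
    """Pick ``eps`` so the expected node degree is ~``target_degree``.

    Uses the matching upper quantile of the off-diagonal affinities,
    which lands the median degree in a single-digit-to-tens range for
    any non-pathological affinity distribution.
    """
    d = affinity.values.shape[0]
    if d < 2:
        return 1.0
    off = affinity.values[np.triu_indices(d, k=1)]
    frac = min(target_degree / (d - 1), 1.0)
    return float(np.quantile(off, 1.0 - frac))


# ---------------------------------------------------------------------------
# Thresholding and normalization


def threshold_graph(
    affinity: AffinityMatrix, eps: float, omics_id: str = "omics"
) -> FeatureGraph:
    """Binary adjacency: edge iff affinity >= eps; diagonal forced to 0."""
    vals = affinity.values
    if not np.allclose(vals, vals.T):
        raise ContractError("affinity must be symmetric")
    adj = (vals >= eps).astype(np.int8)
    np.fill_diagonal(adj, 0)
    adj = np.maximum(adj, adj.T)  # guard tiny asymmetries after casting
    return FeatureGraph(omics_id, list(affinity.feature_ids), adj, float(eps))


def _sym_normalize(a_tilde: np.ndarray) -> np.ndarray:
    deg = a_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    return a_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]


def normalize_sym(graph: FeatureGraph) -> NormalizedGraph:
    """D^{-1/2} (A + I) D^{-1/2} with D the degree matrix of A + I.

    Adding the identity before computing degrees keeps every degree >= 1,
    so isolated features are well defined (they become pure self-loops).
    """
    a = np.asarray(graph.adjacency, dtype=float)
    if not np.array_equal(a, a.T):
        raise ContractError("adjacency must be symmetric")
    a_tilde = a + np.eye(a.shape[0])
    return NormalizedGraph(list(graph.feature_ids), _sym_normalize(a_tilde))


def assemble_and_normalize_bipartite(bip: BipartiteGraph) -> NormalizedBipartite:
    """Normalize the joint bipartite adjacency and extract its blocks.

    The (p+q) x (p+q) joint matrix has zero diagonal blocks and the
    incidence / its transpose off-diagonal; it gets self-loops and the
    same symmetric normalization as intra-omics graphs, then the
    off-diagonal blocks are read back out.
    """
    b = np.asarray(bip.incidence, dtype=float)
    p, q = b.shape
    joint = np.zeros((p + q, p + q))
    joint[:p, p:] = b
    joint[p:, :p] = b.T
    hat = _sym_normalize(joint + np.eye(p + q))
    return NormalizedBipartite(
        list(bip.row_feature_ids),
        list(bip.col_feature_ids),
        hat[:p, p:].copy(),
        hat[p:, :p].copy(),
    )


# ---------------------------------------------------------------------------
# Bipartite builders


def build_bipartite_from_prior(
    edges: list[tuple],
    u_ids: list[str],
    v_ids: list[str],
    score_cutoff: float | None = None,
    score_mode: str = "le",
) -> BipartiteGraph:
    """Binary incidence from a prior edge list.

    ``edges`` holds ``(u_id, v_id)`` or ``(u_id, v_id, score)`` records.
    Records naming unknown features are skipped (count logged).  With a
    ``score_cutoff``, ``score_mode='le'`` keeps edges whose score is <=
    the cutoff (TargetScan context++ convention: more negative = stronger
    repression) and ``'ge'`` keeps score >= cutoff (generic weights).
    Duplicate records collapse to a single edge.
    """
    if score_mode not in ("le", "ge"):
        raise ValueError("score_mode must be 'le' or 'ge'")
    u_index = {f: i for i, f in enumerate(u_ids)}
    v_index = {f: i for i, f in enumerate(v_ids)}
    inc = np.zeros((len(u_ids), len(v_ids)), dtype=np.int8)
    skipped = 0
    for rec in edges:
        u, v = rec[0], rec[1]
        if u not in u_index or v not in v_index:
            skipped += 1
            continue
        if score_cutoff is not None and len(rec) > 2 and rec[2] is not None:
            score = float(rec[2])
            keep = score <= score_cutoff if score_mode == "le" else score >= score_cutoff
            if not keep:
                continue
        inc[u_index[u], v_index[v]] = 1
    if skipped:
        logger.info("build_bipartite_from_prior: skipped %d edge(s) with unknown features", skipped)
    if inc.sum() == 0:
        warnings.warn(
            "prior bipartite graph is empty; the model will rely on intra-omics signal only",
            stacklevel=2,
        )
    return BipartiteGraph(list(u_ids), list(v_ids), inc)


def build_data_driven_bipartite(
    Xu_features: np.ndarray,
    Xv_features: np.ndarray,
    method: str = "cosine",
    eps: float = 0.5,
    sigma: float | None = None,
    u_ids: list[str] | None = None,
    v_ids: list[str] | None = None,
) -> BipartiteGraph:
    """Cross-omics incidence from thresholded feature affinities.

    ``Xu_features`` (p x n) and ``Xv_features`` (q x n) must share the
    sample axis; incidence_ij = 1 iff affinity(u_i, v_j) >= eps.
    """
    Xu = np.asarray(Xu_features, dtype=float)
    Xv = np.asarray(Xv_features, dtype=float)
    aff = _pairwise_affinity(Xu, Xv, method, sigma)
    inc = (aff >= eps).astype(np.int8)
    if u_ids is None:
        u_ids = [f"u{i}" for i in range(Xu.shape[0])]
    if v_ids is None:
        v_ids = [f"v{i}" for i in range(Xv.shape[0])]
    return BipartiteGraph(list(u_ids), list(v_ids), inc)


def hybrid_bipartite(
    prior: BipartiteGraph,
    data_affinity: np.ndarray,
    lam: float,
    eps: float,
) -> BipartiteGraph:
    """Blend prior edges with data affinities.

    Keeps edge (i, j) iff ``lam * prior_ij + (1 - lam) * a_ij >= eps``;
    lam=1 reduces to the thresholded prior, lam=0 to the pure
    data-driven graph.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    a = np.asarray(data_affinity, dtype=float)
    if a.shape != prior.incidence.shape:
        raise ContractError("data affinity shape must match the prior incidence")
    blend = lam * prior.incidence + (1.0 - lam) * a
    return BipartiteGraph(
        list(prior.row_feature_ids),
        list(prior.col_feature_ids),
        (blend >= eps).astype(np.int8),
    )


# ---------------------------------------------------------------------------
# Edge-list views


def graph_to_edge_list(graph: FeatureGraph) -> list[tuple[str, str]]:
    ids = graph.feature_ids
    i, j = np.nonzero(np.triu(graph.adjacency, k=1))
    return [(ids[a], ids[b]) for a, b in zip(i, j)]


def bipartite_to_edge_list(bip: BipartiteGraph) -> list[tuple[str, str]]:
    i, j = np.nonzero(bip.incidence)
    return [(bip.row_feature_ids[a], bip.col_feature_ids[b]) for a, b in zip(i, j)]
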