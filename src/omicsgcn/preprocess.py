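"""Cohort preparation: imputation, feature selection, repeated splits.

The protocol is: KNN-impute missing values (K=5), keep the top-variance
features per omics (1000 mRNA / 200 miRNA / 1000 methylation by
convention), drop features absent from the interaction networks, then
repeatedly split 80/20 into train/test and the training portion 80/20
into train/validation, z-scoring each subset with its *own* statistics.
Per-subset standardization (rather than reusing training statistics) is
deliberate: every subset is scaled from its own Z-scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer
from sklearn.model_selection import train_test_split

DEFAULT_TOP_FEATURES = {"mrna": 1000, "mirna": 200, "methylation": 1000}


def knn_impute(X: pd.DataFrame, K: int = 5) -> pd.DataFrame:
    """Replace each missing entry by the mean of that feature over the
    K nearest samples (Euclidean distance on mutually observed features).

    Features missing in every sample cannot be imputed and are dropped
    with a warning.  A complete matrix is returned unchanged.
    """
    if not X.isna().any().any():
        return X.copy()
    all_missing = X.columns[X.isna().all(axis=0)]
    if len(all_missing):
        warnings.warn(
            f"dropping {len(all_missing)} feature(s) missing in all samples",
            stacklevel=2,
        )
        X = X.drop(columns=all_missing)
    imputer = KNNImputer(n_neighbors=K)
    vals = imputer.fit_transform(X.to_numpy(dtype=float))
    return pd.DataFrame(vals, index=X.index, columns=X.columns)


def top_variance_select(X: pd.DataFrame, n_keep: int) -> pd.DataFrame:
    """Keep the ``n_keep`` features with largest sample variance (ddof=1).

    Order is by descending variance; ties keep the original column
    order.  Asking for more features than exist keeps all, with a
    warning.
    """
    if n_keep >= X.shape[1]:
        if n_keep > X.shape[1]:
            warnings.warn(
                f"n_keep={n_keep} exceeds feature count {X.shape[1]}; keeping all",
                stacklevel=2,
            )
        return X.copy()
    var = X.var(axis=0, ddof=1).to_numpy()
    order = np.argsort(-var, kind="stable")[:n_keep]
    return X.iloc[:, order]


def restrict_to_network(X: pd.DataFrame, node_ids) -> pd.DataFrame:
    """Keep only features that appear in the given graph node set(s).

    ``node_ids`` is an iterable (or iterable of iterables) of feature
    identifiers with at least one edge; survivors keep their input
    column order.
    """
    universe: set[str] = set()
    for item in node_ids:
        if isinstance(item, str):
            universe.add(item)
        else:
            universe.update(item)
    keep = [c for c in X.columns if c in universe]
    if not keep:
        raise ValueError(
            "no feature of the matrix appears in the network node set; "
            f"matrix has {X.shape[1]} features, network {len(universe)} nodes"
        )
    dropped = X.shape[1] - len(keep)
    if dropped:
        warnings.warn(f"dropped {dropped} feature(s) without network edges", stacklevel=2)
    return X[keep]


def zscore(X: pd.DataFrame) -> pd.DataFrame:
    """Per-feature z-score using this matrix's own mean/sd (ddof=1).

    Constant features are centred and left at zero rather than divided
    by a zero standard deviation.
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = sd.where(sd > 0, 1.0)
    return (X - mu) / sd


@dataclass
class Split:
    """One repeat: index sets plus per-subset standardized matrices."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    X_train: dict[str, pd.DataFrame]
    X_val: dict[str, pd.DataFrame]
    X_test: dict[str, pd.DataFrame]
    y_train: pd.Series
    y_val: pd.Series
    y_test: pd.Series
    seed: int


def _stratified_split(idx: np.ndarray, y: np.ndarray, test_size: float, seed: int):
    _, counts = np.unique(y, return_counts=True)
    stratify = y
    if counts.min() < 5:
        warnings.warn(
            "a class has fewer than 5 samples; stratification is best-effort",
            stacklevel=3,
        )
    if counts.min() < 2:
        stratify = None
    return train_test_split(
        idx, test_size=test_size, stratify=stratify, random_state=seed
    )


def make_split(X: dict[str, pd.DataFrame], y: pd.Series, seed: int) -> Split:
    """One stratified 80/20 test split + 80/20 validation sub-split.

    Each of the three subsets is z-scored per feature from its own
    statistics only, so no information flows between subsets.
    """
    n = len(y)
    for name, mat in X.items():
        if len(mat) != n or not (mat.index == y.index).all():
            raise ValueError(f"omics block {name!r} does not share the sample axis with y")
    idx = np.arange(n)
    y_arr = y.to_numpy()
    train_full, test_idx = _stratified_split(idx, y_arr, 0.2, seed)
    train_idx, val_idx = _stratified_split(train_full, y_arr[train_full], 0.2, seed)

    def take(rows: np.ndarray):
        return (
            {name: zscore(mat.iloc[rows]) for name, mat in X.items()},
            y.iloc[rows],
        )

    X_train, y_train = take(train_idx)
    X_val, y_val = take(val_idx)
    X_test, y_test = take(test_idx)
    return Split(
        train_idx=np.sort(train_idx),
        val_idx=np.sort(val_idx),
        test_idx=np.sort(test_idx),
        X_train=X_train,
        X_val=X_val,
        X_test=X_test,
        y_train=y_train,
        y_val=y_val,
        y_test=y_test,
        seed=seed,
    )


def make_splits(
    X: dict[str, pd.DataFrame], y: pd.Series, n_repeats: int = 100, seed: int = 0
) -> list[Split]:
    """Repeat ``make_split`` with seeds ``seed + r`` for r in 0..n_repeats-1."""
    return [make_split(X, y, seed + r) for r in range(n_repeats)]
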