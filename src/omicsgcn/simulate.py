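"""Synthetic multi-omics cohorts with planted cross-omics structure.

The generator emulates the statistical regime of paired tumour omics
profiles: far more features than samples, a small "regulator" block
(miRNA-like, q features) carrying class-dependent signal on a few driver
features, and a large "target" block (mRNA-like, p features) that
receives that signal *only* through a known sparse bipartite graph —
so cross-omics message passing is required to read the class signal out
of the target block.  Intra-omics correlation modules and optional
uniform missingness complete the picture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphs import BipartiteGraph


@dataclass
class SyntheticSpec:
    """Generator settings.

    effect
        Mean shift per class code on the driver features of omics2.
    coupling
        Scale of the propagated signal: each connected omics1 feature is
        ``coupling *`` the mean of its linked omics2 features plus noise.
    bipartite_density
        Bernoulli edge probability of the regulator->target incidence.
    intra_module_count
        Number of correlated feature modules planted per omics block.
    """

    n: int = 300
    p: int = 200
    q: int = 50
    nc: int = 2
    effect: float = 2.0
    coupling: float = 1.0
    noise_sd: float = 1.0
    n_drivers: int = 10
    bipartite_density: float = 0.05
    intra_module_count: int = 5
    module_strength: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n < 4 or self.p < 1 or self.q < 1:
            raise ValueError("need n >= 4 and at least one feature per omics")
        if self.nc < 2:
            raise ValueError("nc must be >= 2")
        if not 0 <= self.n_drivers <= self.q:
            raise ValueError("n_drivers must lie in [0, q]")
        if not 0.0 < self.bipartite_density < 1.0:
            raise ValueError("bipartite_density must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class SyntheticDataset:
    """Generated cohort plus all planted ground truth."""

    X_u: pd.DataFrame
    X_v: pd.DataFrame
    y: pd.Series
    bipartite: BipartiteGraph
    modules_u: list[list[str]]
    modules_v: list[list[str]]
    driver_ids: list[str]
    spec: SyntheticSpec


def _make_modules(ids: list[str], count: int) -> list[list[str]]:
    if count <= 0:
        return []
    chunks = np.array_split(np.arange(len(ids)), count)
    return [[ids[i] for i in c] for c in chunks if len(c) > 1]


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one cohort under ``spec`` (bit-reproducible from its seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p, q = spec.n, spec.p, spec.q

    sample_ids = [f"S{i:04d}" for i in range(n)]
    u_ids = [f"gene_{i:04d}" for i in range(p)]
    v_ids = [f"mir_{i:03d}" for i in range(q)]

    # balanced class labels, shuffled
    y = np.repeat(np.arange(spec.nc), int(np.ceil(n / spec.nc)))[:n]
    rng.shuffle(y)

    # omics2: drivers carry the class shift, the rest is noise
    Xv = rng.normal(0.0, spec.noise_sd, size=(n, q))
    drivers = rng.choice(q, size=spec.n_drivers, replace=False)
    class_code = y.astype(float)
    Xv[:, drivers] += spec.effect * class_code[:, None]

    # sparse regulator -> target incidence (rows: omics1 targets)
    inc = (rng.random((p, q)) < spec.bipartite_density).astype(np.int8)

    # omics1: class signal arrives only through the bipartite edges
    Xu = rng.normal(0.0, spec.noise_sd, size=(n, p))
    deg = inc.sum(axis=1)
    linked = deg > 0
    if linked.any():
        means = Xv @ inc[linked].T / deg[linked]
        Xu[:, linked] += spec.coupling * means

    # correlated intra-omics modules: shared latent factor per module
    modules_u = _make_modules(u_ids, spec.intra_module_count)
    modules_v = _make_modules(v_ids, spec.intra_module_count)
    for mats, ids_all, modules in ((Xu, u_ids, modules_u), (Xv, v_ids, modules_v)):
        index = {f: i for i, f in enumerate(ids_all)}
        for module in modules:
            g = rng.normal(0.0, 1.0, size=n)
            cols = [index[f] for f in module]
            mats[:, cols] += spec.module_strength * g[:, None]

    X_u = pd.DataFrame(Xu, index=sample_ids, columns=u_ids)
    X_v = pd.DataFrame(Xv, index=sample_ids, columns=v_ids)
    if spec.missing_rate > 0:
        X_u = pd.DataFrame(
            inject_missing(X_u.to_numpy(), spec.missing_rate, spec.seed + 1)[0],
            index=sample_ids,
            columns=u_ids,
        )
        X_v = pd.DataFrame(
            inject_missing(X_v.to_numpy(), spec.missing_rate, spec.seed + 2)[0],
            index=sample_ids,
            columns=v_ids,
        )

    return SyntheticDataset(
        X_u=X_u,
        X_v=X_v,
        y=pd.Series(y, index=sample_ids, name="label"),
        bipartite=BipartiteGraph(u_ids, v_ids, inc),
        modules_u=modules_u,
        modules_v=modules_v,
        driver_ids=[v_ids[i] for i in sorted(drivers)],
        spec=spec,
    )


def inject_missing(
    X: np.ndarray, rate: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Set exactly ``ceil(rate * cells)`` uniformly chosen entries to NaN.

    Returns the masked copy and the boolean missingness mask.
    """
    if not 0.0 <= rate <= 0.5:
        raise ValueError("rate must lie in [0, 0.5]")
    X = np.asarray(X, dtype=float)
    out = X.copy()
    mask = np.zeros(X.size, dtype=bool)
    n_missing = int(np.ceil(rate * X.size))
    if n_missing:
        rng = np.random.default_rng(seed)
        idx = rng.choice(X.size, size=n_missing, replace=False)
        mask[idx] = True
    mask = mask.reshape(X.shape)
    out[mask] = np.nan
    return out, mask
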