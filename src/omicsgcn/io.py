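"""Readers and writers for the pipeline's external formats.

Matrices travel as delimited text, samples x features, first column the
sample identifier and the header row the feature identifiers.  Networks
travel as two/three-column edge lists (regulator, target, optional
score).  Metrics are JSON with sorted keys and no timestamps, so a run
repeated with the same seed writes byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .graphs import BipartiteGraph
from .model import GraphSet, ModelParams


def _sniff_delimiter(path: Path, override: str | None = None) -> str:
    if override:
        return override
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_matrix(path, delimiter: str | None = None) -> pd.DataFrame:
    """Samples x features matrix with sample IDs in the first column."""
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"could not parse matrix {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path, delimiter: str = "\t") -> None:
    df.to_csv(path, sep=delimiter, index_label="sample_id")


def read_labels(path, delimiter: str | None = None) -> pd.Series:
    """TSV of [sample_id, label] -> integer-coded label series."""
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    s = df.iloc[:, 0]
    s.index = s.index.astype(str)
    return s.astype(int).rename("label")


def write_labels(y: pd.Series, path, delimiter: str = "\t") -> None:
    y.rename("label").to_csv(path, sep=delimiter, index_label="sample_id")


def read_edge_list(path, delimiter: str | None = None, header: bool = False) -> list[tuple]:
    """Edge records (source, target[, score]) from a delimited file."""
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, header=0 if header else None, dtype=str)
    records = []
    for row in df.itertuples(index=False):
        vals = list(row)
        if len(vals) >= 3 and vals[2] is not None and str(vals[2]) != "nan":
            records.append((str(vals[0]), str(vals[1]), float(vals[2])))
        else:
            records.append((str(vals[0]), str(vals[1])))
    return records


def write_edge_list(edges: list[tuple], path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for rec in edges:
            fh.write(delimiter.join(str(x) for x in rec) + "\n")


def write_bipartite(bip: BipartiteGraph, path) -> None:
    i, j = np.nonzero(bip.incidence)
    write_edge_list(
        [(bip.row_feature_ids[a], bip.col_feature_ids[b]) for a, b in zip(i, j)], path
    )


def read_bipartite(path, u_ids: list[str], v_ids: list[str]) -> BipartiteGraph:
    from .graphs import build_bipartite_from_prior

    return build_bipartite_from_prior(read_edge_list(path), u_ids, v_ids)


def write_metrics_json(payload: dict, path) -> None:
    """Deterministic JSON: sorted keys, full float repr, trailing newline."""
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config_yaml(config, path) -> None:
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Model archive: weights + graphs + config echo in one .npz


def save_model(path, params: ModelParams, graphs: GraphSet | None = None) -> None:
    arrays: dict[str, np.ndarray] = {}
    for l, layer in enumerate(params.intra_weights):
        for m, w in layer.items():
            arrays[f"intra/{l}/{m}"] = w
    for l, layer in enumerate(params.inter_weights):
        for (dst, src), w in layer.items():
            arrays[f"inter/{l}/{dst}/{src}"] = w
    arrays["head"] = params.head_weight
    if graphs is not None:
        for m, a in graphs.intra.items():
            arrays[f"graph_intra/{m}"] = a
        for (dst, src), b in graphs.inter.items():
            arrays[f"graph_inter/{dst}/{src}"] = b
    meta = {
        "omics_names": params.omics_names,
        "dims": params.dims,
        "L": params.L,
        "k": params.k,
        "leaky_slope": params.leaky_slope,
        "task": params.task,
        "nc": params.nc,
        "mode": params.mode,
        "feature_ids": graphs.feature_ids if graphs is not None else {},
    }
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path) -> tuple[ModelParams, GraphSet | None]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"].tobytes()).decode())
        L = meta["L"]
        intra = [
            {m: data[f"intra/{l}/{m}"] for m in meta["omics_names"]} for l in range(L)
        ]
        inter = [
            {
                (dst, src): data[f"inter/{l}/{dst}/{src}"]
                for dst in meta["omics_names"]
                for src in meta["omics_names"]
                if dst != src and f"inter/{l}/{dst}/{src}" in data
            }
            for l in range(L)
        ]
        params = ModelParams(
            omics_names=meta["omics_names"],
            dims=meta["dims"],
            L=L,
            k=meta["k"],
            leaky_slope=meta["leaky_slope"],
            task=meta["task"],
            nc=meta["nc"],
            mode=meta["mode"],
            intra_weights=intra,
            inter_weights=inter,
            head_weight=data["head"],
        )
        graphs = None
        g_intra = {
            m: data[f"graph_intra/{m}"]
            for m in meta["omics_names"]
            if f"graph_intra/{m}" in data
        }
        if g_intra:
            g_inter = {
                (dst, src): data[f"graph_inter/{dst}/{src}"]
                for dst in meta["omics_names"]
                for src in meta["omics_names"]
                if dst != src and f"graph_inter/{dst}/{src}" in data
            }
            graphs = GraphSet(
                intra=g_intra, inter=g_inter, feature_ids=meta.get("feature_ids", {})
            )
    return params, graphs
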