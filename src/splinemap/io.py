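"""Readers and writers for the plain-text interchange formats.

All artifacts are deterministic given the run seed: CSVs carry a comment
header line embedding the config hash and seed so any output directory is
reconstructible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import FlowMatrix, Geography
from .simulate import OFFSET_SCALE, SimulatedDataset

__all__ = [
    "config_hash",
    "read_data_csv",
    "read_centroids_csv",
    "read_flow_csv",
    "read_edgelist_csv",
    "read_geojson",
    "geography_from_centroids",
    "write_dataset_csv",
    "read_dataset_csv",
    "write_matrix_csv",
    "write_posterior_csv",
    "write_json",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_comment(meta: dict | None) -> str:
    if not meta:
        return ""
    parts = " ".join(f"{k}={v}" for k, v in sorted(meta.items()))
    return f"# {parts}\n"


def read_data_csv(path) -> pd.DataFrame:
    """Area-level data table with columns area_id, count, population[, trials]."""
    df = pd.read_csv(path, comment="#")
    required = {"area_id", "count", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"data table missing columns: {sorted(missing)}")
    if (df["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    if (df["population"] <= 0).any():
        raise ValueError("populations must be positive")
    return df


def read_centroids_csv(path) -> pd.DataFrame:
    """Centroid table with columns area_id, x, y."""
    df = pd.read_csv(path, comment="#")
    missing = {"area_id", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"centroid table missing columns: {sorted(missing)}")
    return df


def read_flow_csv(path, area_ids=None) -> FlowMatrix:
    """Dense flow matrix CSV with a header row and an index column of area ids."""
    df = pd.read_csv(path, index_col=0, comment="#")
    if df.shape[0] != df.shape[1]:
        raise ValueError("flow matrix must be square")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError("flow matrix row and column ids differ")
    if area_ids is not None:
        want = [str(a) for a in area_ids]
        have = [str(a) for a in df.index]
        if have != want:
            if sorted(have) != sorted(want):
                raise ValueError("flow matrix ids do not match the geography")
            df = df.loc[area_ids, [str(a) for a in area_ids]]
    return FlowMatrix(df.to_numpy(dtype=float))


def read_edgelist_csv(path, n: int) -> np.ndarray:
    """Adjacency from an edge-list CSV with header ``i,j``.

    Indices are 0-based positions in the sorted area_id order.
    """
    df = pd.read_csv(path, comment="#")
    if list(df.columns[:2]) != ["i", "j"]:
        raise ValueError("edge list must have columns 'i,j'")
    W = np.zeros((n, n), dtype=int)
    for i, j in df[["i", "j"]].to_numpy(dtype=int):
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"edge ({i}, {j}) out of range for n = {n}")
        if i != j:
            W[i, j] = W[j, i] = 1
    return W


def read_geojson(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def geography_from_centroids(data: pd.DataFrame, centroids: pd.DataFrame, adjacency=None) -> Geography:
    """Assemble a Geography from data + centroid tables (sorted by area_id)."""
    data = data.sort_values("area_id").reset_index(drop=True)
    centroids = centroids.sort_values("area_id").reset_index(drop=True)
    if list(data["area_id"]) != list(centroids["area_id"]):
        raise ValueError("area ids in data and centroid tables differ")
    n = len(data)
    if adjacency is None:
        adjacency = np.zeros((n, n), dtype=int)
    return Geography(
        tuple(data["area_id"]),
        centroids[["x", "y"]].to_numpy(dtype=float),
        data["population"].to_numpy(dtype=float),
        adjacency,
    )


def write_dataset_csv(path, dataset: SimulatedDataset, area_ids, meta: dict | None = None):
    """Write a simulated dataset: area_id, count, population, true_S, true_smooth_k."""
    cols = {
        "area_id": list(area_ids),
        "count": dataset.counts,
        "population": dataset.offsets * OFFSET_SCALE,
        "true_S": dataset.true_field,
    }
    for k, (label, vals) in enumerate(dataset.true_smooths.items(), start=1):
        cols[f"true_smooth_{k}"] = vals
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(_header_comment(meta))
        df.to_csv(fh, index=False)


def read_dataset_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_matrix_csv(path, M: np.ndarray, ids, meta: dict | None = None):
    df = pd.DataFrame(np.asarray(M), index=list(ids), columns=list(ids))
    with open(path, "w") as fh:
        fh.write(_header_comment(meta))
        df.to_csv(fh)


def write_posterior_csv(path, samples, meta: dict | None = None, scalars_only: bool = True):
    """Tidy posterior draws: columns (draw, chain, parameter, value)."""
    chains = samples.meta["chains"]
    rows = []
    for name, arr in samples.draws.items():
        arr = np.asarray(arr)
        if arr.ndim != 1:
            if scalars_only:
                continue
            arr = arr.reshape(arr.shape[0], -1)
        per = arr.shape[0] // chains
        for s in range(arr.shape[0]):
            val = arr[s]
            if np.ndim(val) == 0:
                rows.append((s % per, s // per, name, float(val)))
            else:
                rows.extend((s % per, s // per, f"{name}[{k}]", float(v)) for k, v in enumerate(val))
    df = pd.DataFrame(rows, columns=["draw", "chain", "parameter", "value"])
    with open(path, "w") as fh:
        fh.write(_header_comment(meta))
        df.to_csv(fh, index=False)


def write_json(path, payload: dict, meta: dict | None = None):
    out = dict(payload)
    if meta:
        out["_meta"] = meta
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True, default=float) + "\n")
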