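"""Plain-text persistence for networks and spike trains.

Networks are saved as a positions CSV (id, x_mm, y_mm, type,
dendrite_radius_mm), an edge-list CSV (pre, post, weight) and a JSON
metadata file; the adjacency can also be exported as MatrixMarket.
Spike trains are two-column CSVs (neuron_id, time_ms) plus JSON metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmwrite

from .dynamics import SpikeTrain
from .growth import StructuralNetwork

__all__ = [
    "save_network",
    "load_network",
    "save_spikes",
    "load_spikes",
    "export_adjacency_mtx",
]


def save_network(net: StructuralNetwork, prefix,
                 dendrite_radii: np.ndarray | None = None) -> dict:
    """Write ``<prefix>_positions.csv``, ``<prefix>_edges.csv`` and JSON meta."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = net.n_neurons
    pos_df = pd.DataFrame({
        "id": np.arange(n),
        "x_mm": net.positions[:, 0],
        "y_mm": net.positions[:, 1],
        "type": np.where(net.types == 1, "inhibitory", "excitatory"),
        "dendrite_radius_mm": (dendrite_radii if dendrite_radii is not None
                               else np.full(n, np.nan)),
    })
    coo = net.W.tocoo()
    edge_df = pd.DataFrame({"pre": coo.col, "post": coo.row,
                            "weight": coo.data})
    paths = {
        "positions": prefix.with_name(prefix.name + "_positions.csv"),
        "edges": prefix.with_name(prefix.name + "_edges.csv"),
        "meta": prefix.with_name(prefix.name + "_meta.json"),
    }
    pos_df.to_csv(paths["positions"], index=False)
    edge_df.to_csv(paths["edges"], index=False)
    paths["meta"].write_text(json.dumps(
        {"n_neurons": n, "n_edges": net.n_edges, "meta": _jsonable(net.meta)},
        indent=2))
    return paths


def load_network(prefix) -> StructuralNetwork:
    prefix = Path(prefix)
    pos_df = pd.read_csv(prefix.with_name(prefix.name + "_positions.csv"))
    edge_df = pd.read_csv(prefix.with_name(prefix.name + "_edges.csv"))
    meta = json.loads(
        prefix.with_name(prefix.name + "_meta.json").read_text())
    n = len(pos_df)
    w = sp.csr_matrix(
        (edge_df["weight"], (edge_df["post"], edge_df["pre"])), shape=(n, n))
    s = w.copy()
    s.data = np.ones_like(s.data, dtype=np.int8)
    return StructuralNetwork(
        S=s.astype(np.int8), W=w,
        types=(pos_df["type"] == "inhibitory").to_numpy().astype(np.int8),
        positions=pos_df[["x_mm", "y_mm"]].to_numpy(),
        meta=meta.get("meta", {}),
    )


def export_adjacency_mtx(matrix, path) -> None:
    """Write a (sparse) adjacency or score matrix in MatrixMarket format."""
    m = matrix if sp.issparse(matrix) else sp.csr_matrix(np.asarray(matrix))
    mmwrite(str(path), m)


def save_spikes(spikes: SpikeTrain, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"neuron_id": spikes.ids, "time_ms": spikes.times}).to_csv(
        path, index=False)
    meta = {"duration_ms": spikes.duration, "n_neurons": spikes.n_neurons,
            "meta": _jsonable(spikes.meta)}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_spikes(path) -> SpikeTrain:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return SpikeTrain(
        ids=df["neuron_id"].to_numpy(), times=df["time_ms"].to_numpy(),
        duration=meta["duration_ms"], n_neurons=meta["n_neurons"],
        meta=meta.get("meta", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
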