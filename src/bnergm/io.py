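"""Readers and writers for the standard plain-text formats the pipeline
consumes: edge lists, adjacency CSVs, node-attribute TSVs, correlation
CSVs, GraphML, and FitResult JSON.

Arbitrary node labels are mapped to contiguous 0-based indices; the label
table travels alongside the Network so outputs can be written back with the
original names.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .construct import CorrelationMatrix
from .fit import FitResult
from .network import InvalidInputError, Network, NodeAttributes

__all__ = [
    "read_edgelist",
    "write_edgelist",
    "read_adjacency_csv",
    "read_node_attributes",
    "read_correlation_csv",
    "read_graphml",
    "write_graphml",
    "write_fit_json",
]

PathLike = Union[str, Path]


def read_edgelist(
    path: PathLike, header: bool = False
) -> tuple[Network, tuple]:
    """Whitespace/TSV edge list with two label columns.

    Returns the network and the node label table (index -> label).
    """
    try:
        df = pd.read_csv(path, sep=r"\s+", header=0 if header else None,
                         dtype=str, comment="#")
    except Exception as exc:
        raise InvalidInputError(f"cannot parse edge list {path}: {exc}") from exc
    if df.shape[1] != 2 or df.empty:
        raise InvalidInputError(f"edge list {path} must have exactly two columns")
    labels: dict[str, int] = {}
    edges = []
    for u, v in df.itertuples(index=False):
        if pd.isna(u) or pd.isna(v):
            raise InvalidInputError(f"edge list {path} contains missing labels")
        iu = labels.setdefault(str(u), len(labels))
        iv = labels.setdefault(str(v), len(labels))
        edges.append((iu, iv))
    net = Network(len(labels), edges)
    return net, tuple(labels)


def write_edgelist(net: Network, path: PathLike, labels: Optional[tuple] = None) -> None:
    labels = labels or tuple(str(i) for i in range(net.n_nodes))
    with open(path, "w") as fh:
        for i, j in net.edges:
            fh.write(f"{labels[i]}\t{labels[j]}\n")


def read_adjacency_csv(path: PathLike, header: bool = "infer") -> tuple[Network, tuple]:
    """Square symmetric 0/1 CSV; optional label header row/column.

    The diagonal is ignored.
    """
    try:
        df = pd.read_csv(path, header=None, dtype=str)
    except Exception as exc:
        raise InvalidInputError(f"cannot parse adjacency CSV {path}: {exc}") from exc
    labels = None
    # label headers: first cell not numeric
    def _is_num(x):
        try:
            float(x)
            return True
        except (TypeError, ValueError):
            return False

    if df.shape[0] and not _is_num(df.iloc[0, min(1, df.shape[1] - 1)]):
        labels = tuple(str(x) for x in df.iloc[0, 1:])
        df = df.iloc[1:, 1:]
    try:
        a = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise InvalidInputError(f"adjacency CSV {path} has non-numeric entries") from exc
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InvalidInputError(f"adjacency CSV {path} is not square")
    np.fill_diagonal(a, 0)
    if not np.array_equal(a, a.T):
        raise InvalidInputError(f"adjacency CSV {path} is not symmetric")
    if not np.isin(a, (0.0, 1.0)).all():
        raise InvalidInputError(f"adjacency CSV {path} must be 0/1")
    net = Network.from_adjacency(a.astype(np.uint8))
    return net, labels or tuple(str(i) for i in range(net.n_nodes))


def read_node_attributes(
    path: PathLike, labels: tuple, name: str = "attribute"
) -> NodeAttributes:
    """TSV with columns node_label, attribute_value (no header)."""
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    except Exception as exc:
        raise InvalidInputError(f"cannot parse attribute table {path}: {exc}") from exc
    if df.shape[1] != 2:
        raise InvalidInputError(f"attribute table {path} must have two columns")
    index = {lab: i for i, lab in enumerate(labels)}
    mapping = {}
    for lab, val in df.itertuples(index=False):
        if str(lab) not in index:
            raise InvalidInputError(f"attribute table {path}: unknown node {lab!r}")
        mapping[index[str(lab)]] = str(val)
    return NodeAttributes.from_mapping(name, mapping, len(labels))


def read_correlation_csv(path: PathLike) -> CorrelationMatrix:
    """Square symmetric correlation CSV, with or without label headers."""
    try:
        df = pd.read_csv(path, header=None, dtype=str)
    except Exception as exc:
        raise InvalidInputError(f"cannot parse correlation CSV {path}: {exc}") from exc
    labels = None
    try:
        float(df.iloc[0, min(1, df.shape[1] - 1)])
    except (TypeError, ValueError):
        labels = tuple(str(x) for x in df.iloc[0, 1:])
        df = df.iloc[1:, 1:]
    try:
        m = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise InvalidInputError(f"correlation CSV {path} has non-numeric entries") from exc
    return CorrelationMatrix(m, labels=labels)


def read_graphml(path: PathLike) -> tuple[Network, tuple]:
    import networkx as nx

    try:
        g = nx.read_graphml(path)
    except Exception as exc:
        raise InvalidInputError(f"cannot parse GraphML {path}: {exc}") from exc
    if g.is_directed() or g.is_multigraph():
        raise InvalidInputError(f"GraphML {path} must be a simple undirected graph")
    labels = tuple(str(v) for v in g.nodes())
    index = {lab: i for i, lab in enumerate(labels)}
    edges = [(index[str(u)], index[str(v)]) for u, v in g.edges()]
    return Network(len(labels), edges), labels


def write_graphml(net: Network, path: PathLike, labels: Optional[tuple] = None) -> None:
    import networkx as nx

    labels = labels or tuple(str(i) for i in range(net.n_nodes))
    g = nx.relabel_nodes(net.to_networkx(), dict(enumerate(labels)))
    nx.write_graphml(g, path)


def write_fit_json(fit: FitResult, path: PathLike) -> None:
    Path(path).write_text(fit.to_json())
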