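"""File formats: dense/MatrixMarket adjacency matrices, node metadata
TSV, partition TSV, subject covariate CSV, and input filters.

All ids in files are 1-based; internal indices are 0-based.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import FormatError, NodeMetadata, Partition, WeightedConnectome

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_nodes",
    "write_nodes",
    "read_connectome",
    "read_partition",
    "write_partition",
    "read_subject_table",
    "apply_input_filters",
]


def read_matrix(path) -> np.ndarray:
    """Dense whitespace/CSV or MatrixMarket coordinate matrix."""
    path = Path(path)
    with open(path) as fh:
        head = fh.read(64)
    if head.startswith("%%MatrixMarket"):
        M = scipy.io.mmread(path)
        if scipy.sparse.issparse(M):
            M = M.toarray()
        return np.asarray(M, dtype=float)
    delimiter = "," if ("," in head) else None
    try:
        return np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_matrix(path, W: np.ndarray) -> None:
    """Writer mirrors the dialect implied by the extension
    (``.mtx`` -> MatrixMarket, ``.csv`` -> comma, else whitespace)."""
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(W))
    elif path.suffix == ".csv":
        np.savetxt(path, W, delimiter=",")
    else:
        np.savetxt(path, W)


def read_nodes(path) -> list[NodeMetadata]:
    df = pd.read_csv(path, sep="\t")
    required = {"id", "hemisphere", "x", "y", "z"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: needs columns {sorted(required)}")
    return [
        NodeMetadata(
            int(r.id),
            str(r.hemisphere),
            (float(r.x), float(r.y), float(r.z)),
            str(getattr(r, "name_", getattr(r, "name", ""))),
        )
        for r in df.itertuples(index=False)
    ]


def write_nodes(path, nodes: list[NodeMetadata]) -> None:
    pd.DataFrame(
        {
            "id": [n.node_id for n in nodes],
            "hemisphere": [n.hemisphere for n in nodes],
            "x": [n.xyz[0] for n in nodes],
            "y": [n.xyz[1] for n in nodes],
            "z": [n.xyz[2] for n in nodes],
            "name": [n.name for n in nodes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_connectome(matrix_path, nodes_path=None) -> WeightedConnectome:
    W = read_matrix(matrix_path)
    nodes = read_nodes(nodes_path) if nodes_path else None
    return WeightedConnectome(weights=W, nodes=nodes)


def read_partition(path) -> Partition:
    """Two-column TSV (node_id, block), 1-based, sorted by node id."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (node_id, block)")
    df = df.sort_values(df.columns[0])
    labels = df.iloc[:, 1].to_numpy(dtype=int)
    return Partition.from_labels(labels)


def write_partition(path, partition: Partition) -> None:
    pd.DataFrame(
        {
            "node_id": np.arange(1, partition.n_nodes + 1),
            "block": partition.labels,
        }
    ).to_csv(path, sep="\t", index=False)


def read_subject_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "id" not in df.columns or "age" not in df.columns:
        raise FormatError(f"{path}: subject table needs 'id' and 'age' columns")
    return df


def apply_input_filters(
    A: WeightedConnectome,
    min_weight: float = 0.0,
    density_cutoff: float = 0.0,
) -> tuple[WeightedConnectome, bool]:
    """Zero entries below the weight floor; flag the subject for
    exclusion when the filtered binary density falls below the cutoff.

    Returns (filtered connectome, too_sparse flag).
    """
    W = A.weights.copy()
    W[W < min_weight] = 0.0
    filtered = WeightedConnectome(weights=W, nodes=A.nodes)
    return filtered, filtered.density() < density_cutoff
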