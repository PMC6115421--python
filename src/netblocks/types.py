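"""Core data structures shared by all pipeline stages.

Conventions used throughout the package:

* adjacency matrices are dense ``numpy`` arrays, symmetric, non-negative,
  with a zero diagonal;
* block labels are integers ``1..k`` (files are 1-based; internal node
  indices are 0-based);
* "total strength" of a network is the sum of upper-triangle weights
  (each undirected edge counted once).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConfigError",
    "FormatError",
    "NoMatchingPartition",
    "NodeMetadata",
    "WeightedConnectome",
    "Partition",
    "WSBMParams",
    "AssignmentPrior",
    "WSBMPosterior",
    "BlockMatrix",
    "BlockVector",
    "block_vector_length",
    "triu_pairs",
    "total_strength",
    "check_adjacency",
]


class ConfigError(ValueError):
    """Invalid configuration (bad block counts, empty ranges, ...)."""


class FormatError(ValueError):
    """Malformed input data (asymmetric matrix, negative weights, ...)."""


class NoMatchingPartition(Exception):
    """Typed exclusion signal: no sweep partition with the requested
    community count exists.  Mirrors subject exclusion rather than a crash."""


@dataclass(frozen=True)
class NodeMetadata:
    node_id: int            # 1-based external id
    hemisphere: str         # "L" or "R"
    xyz: tuple[float, float, float]  # mm
    name: str = ""


def check_adjacency(weights: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Validate and return a square symmetric non-negative zero-diagonal
    matrix as float64.  Raises :class:`FormatError` with the offending
    entry on failure."""
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise FormatError(f"adjacency must be square, got shape {W.shape}")
    asym = np.abs(W - W.T)
    if asym.max(initial=0.0) > tol:
        i, j = np.unravel_index(np.argmax(asym), W.shape)
        raise FormatError(
            f"adjacency not symmetric: entry ({i + 1},{j + 1}) "
            f"{W[i, j]!r} != ({j + 1},{i + 1}) {W[j, i]!r}"
        )
    if (W < 0).any():
        i, j = np.unravel_index(int(np.argmin(W)), W.shape)
        raise FormatError(f"negative weight {W[i, j]!r} at ({i + 1},{j + 1})")
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    return W


def total_strength(weights: np.ndarray) -> float:
    """Sum of upper-triangle weights (each undirected edge once)."""
    return float(np.triu(weights, k=1).sum())


@dataclass
class WeightedConnectome:
    """One subject's weighted undirected network plus node metadata."""

    weights: np.ndarray
    nodes: list[NodeMetadata] | None = None

    def __post_init__(self) -> None:
        self.weights = check_adjacency(self.weights)
        if self.nodes is not None and len(self.nodes) != self.n_nodes:
            raise FormatError(
                f"{len(self.nodes)} node records for {self.n_nodes} nodes"
            )

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def coords(self) -> np.ndarray:
        if self.nodes is None:
            raise FormatError("node coordinates unavailable")
        return np.array([n.xyz for n in self.nodes], dtype=float)

    @property
    def hemispheres(self) -> np.ndarray:
        if self.nodes is None:
            raise FormatError("node hemispheres unavailable")
        return np.array([n.hemisphere for n in self.nodes])

    @property
    def binary(self) -> np.ndarray:
        return (self.weights > 0).astype(float)

    def density(self) -> float:
        n = self.n_nodes
        if n < 2:
            return 0.0
        m = int(np.count_nonzero(np.triu(self.weights, k=1)))
        return m / (n * (n - 1) / 2)

    def total_strength(self) -> float:
        return total_strength(self.weights)


@dataclass(frozen=True)
class Partition:
    """Hard node-to-block assignment; labels in ``1..k``."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if self.k < 1:
            raise ConfigError(f"k must be >= 1, got {self.k}")
        if labels.ndim != 1:
            raise ConfigError("labels must be a 1-D vector")
        if labels.size and (labels.min() < 1 or labels.max() > self.k):
            raise ConfigError(
                f"labels must lie in 1..{self.k}, got range "
                f"[{labels.min()}, {labels.max()}]"
            )

    @property
    def n_nodes(self) -> int:
        return self.labels.size

    def sizes(self) -> np.ndarray:
        """Block sizes, length k (empty blocks allowed)."""
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    def n_nonempty(self) -> int:
        return int(np.count_nonzero(self.sizes()))

    def onehot(self) -> np.ndarray:
        Z = np.zeros((self.n_nodes, self.k))
        Z[np.arange(self.n_nodes), self.labels - 1] = 1.0
        return Z

    @staticmethod
    def from_labels(labels: Sequence[int], k: int | None = None) -> "Partition":
        labels = np.asarray(labels, dtype=int)
        if k is None:
            k = int(labels.max()) if labels.size else 1
        return Partition(labels=labels, k=k)


def _check_symmetric_kk(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ConfigError(f"{name} must be square k x k")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ConfigError(f"{name} must be symmetric")
    return 0.5 * (M + M.T)


@dataclass
class WSBMParams:
    """Block-pair parameters: Poisson edge-existence rates and Normal
    weight mean/variance per (block, block) pair."""

    edge_rate: np.ndarray
    weight_mean: np.ndarray
    weight_var: np.ndarray

    def __post_init__(self) -> None:
        self.edge_rate = _check_symmetric_kk(self.edge_rate, "edge_rate")
        self.weight_mean = _check_symmetric_kk(self.weight_mean, "weight_mean")
        self.weight_var = _check_symmetric_kk(self.weight_var, "weight_var")
        if (self.edge_rate < 0).any():
            raise ConfigError("edge_rate entries must be >= 0")
        if (self.weight_var <= 0).any():
            raise ConfigError("weight_var entries must be > 0")
        if not (self.edge_rate.shape == self.weight_mean.shape == self.weight_var.shape):
            raise ConfigError("parameter matrices must share one k")

    @property
    def k(self) -> int:
        return self.edge_rate.shape[0]


@dataclass
class AssignmentPrior:
    """Per-node block prior weights (n x k, non-negative rows with
    positive sums).  Rows are normalized to probabilities on access."""

    concentration: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.concentration, dtype=float)
        if C.ndim != 2:
            raise ConfigError("concentration must be n x k")
        if (C < 0).any():
            raise ConfigError("concentration must be non-negative")
        if (C.sum(axis=1) <= 0).any():
            raise ConfigError("each concentration row needs a positive sum")
        self.concentration = C

    @property
    def n_nodes(self) -> int:
        return self.concentration.shape[0]

    @property
    def k(self) -> int:
        return self.concentration.shape[1]

    def probabilities(self) -> np.ndarray:
        C = self.concentration
        return C / C.sum(axis=1, keepdims=True)

    @staticmethod
    def uniform(n_nodes: int, k: int) -> "AssignmentPrior":
        return AssignmentPrior(np.ones((n_nodes, k)))

    @staticmethod
    def concentrated(partition: Partition, level: float) -> "AssignmentPrior":
        """Each node's given block gets weight ``level`` against 1 for the
        other blocks (``level=1`` reduces to uniform)."""
        if level <= 0:
            raise ConfigError("concentration level must be > 0")
        C = np.ones((partition.n_nodes, partition.k))
        C[np.arange(partition.n_nodes), partition.labels - 1] = level
        return AssignmentPrior(C)


@dataclass
class WSBMPosterior:
    """Converged variational solution.

    ``params`` holds posterior-mean point estimates; ``state`` keeps the
    full variational parameters so the evidence can be recomputed.
    """

    responsibilities: np.ndarray
    params: WSBMParams
    log_evidence: float
    map_partition: Partition
    elbo_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    state: dict | None = None

    def __post_init__(self) -> None:
        R = np.asarray(self.responsibilities, dtype=float)
        if not np.allclose(R.sum(axis=1), 1.0, atol=1e-8):
            raise ConfigError("responsibility rows must sum to 1")
        if not np.isfinite(self.log_evidence):
            raise ConfigError("log_evidence must be finite")
        self.responsibilities = R


@dataclass
class BlockMatrix:
    """k x k community-interaction strength summary."""

    values: np.ndarray
    mode: str  # "total" or "mean"

    def __post_init__(self) -> None:
        self.values = _check_symmetric_kk(self.values, "block matrix")
        if self.mode not in ("total", "mean"):
            raise ConfigError(f"unknown block-matrix mode {self.mode!r}")

    @property
    def k(self) -> int:
        return self.values.shape[0]

    def unroll(self) -> "BlockVector":
        return BlockVector.from_matrix(self.values)


def block_vector_length(k: int) -> int:
    """Number of distinct block interactions: upper triangle plus
    diagonal, ``(k^2 - k) / 2 + k``."""
    if k < 1:
        raise ConfigError("k must be >= 1")
    return (k * k - k) // 2 + k


def triu_pairs(k: int) -> list[tuple[int, int]]:
    """Fixed (i <= j) ordering of block pairs used by every unrolled
    vector: row-major over the upper triangle including the diagonal,
    1-based labels."""
    return [(i, j) for i in range(1, k + 1) for j in range(i, k + 1)]


@dataclass(frozen=True)
class BlockVector:
    """Unrolled upper-triangle-plus-diagonal of a k x k block matrix."""

    entries: np.ndarray
    k: int

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", entries)
        if entries.size != block_vector_length(self.k):
            raise ConfigError(
                f"expected length {block_vector_length(self.k)} at k={self.k}, "
                f"got {entries.size}"
            )

    @staticmethod
    def from_matrix(M: np.ndarray) -> "BlockVector":
        M = _check_symmetric_kk(M, "block matrix")
        k = M.shape[0]
        iu = np.triu_indices(k)
        return BlockVector(entries=M[iu], k=k)

    def to_matrix(self) -> np.ndarray:
        M = np.zeros((self.k, self.k))
        iu = np.triu_indices(self.k)
        M[iu] = self.entries
        return M + np.triu(M, k=1).T
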