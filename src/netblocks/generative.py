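"""Generative model evaluation: synthesize network ensembles from
block-pair parameters and score the mean Kolmogorov-Smirnov statistic
("energy") of four binary node-statistic distributions against an
empirical network, with a permuted-parameter null.

Energy is the MEAN of the four KS components, not the max.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .types import (
    ConfigError,
    Partition,
    WeightedConnectome,
    WSBMParams,
    triu_pairs,
)
from .wsbm import sample_network

__all__ = [
    "EvalResult",
    "ks_statistic",
    "node_statistics",
    "evaluate_model",
    "permuted_model",
    "modular_as_generative",
]


def ks_statistic(x, y) -> float:
    """Maximum absolute difference between the two empirical CDFs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigError("KS statistic needs nonempty samples")
    grid = np.concatenate([x, y])
    grid.sort()
    fx = np.searchsorted(np.sort(x), grid, side="right") / x.size
    fy = np.searchsorted(np.sort(y), grid, side="right") / y.size
    return float(np.abs(fx - fy).max())


def node_statistics(
    A_binary: np.ndarray,
    coords: np.ndarray,
    distance_mode: str = "mean",
) -> dict[str, np.ndarray]:
    """Binary degree, clustering coefficient, unnormalized shortest-path
    betweenness, and node Euclidean distance (mean -- or, with
    ``distance_mode="total"``, total -- distance to connected
    neighbors).  Isolated nodes score 0 on all four."""
    Ab = (np.asarray(A_binary) > 0).astype(float)
    n = Ab.shape[0]
    deg = Ab.sum(axis=1)

    tri = np.einsum("ij,jk,ki->i", Ab, Ab, Ab)
    denom = deg * (deg - 1.0)
    clust = np.where(denom > 0, tri / np.where(denom > 0, denom, 1.0), 0.0)

    G = nx.from_numpy_array(Ab)
    bc = nx.betweenness_centrality(G, normalized=False)
    btw = np.array([bc[i] for i in range(n)])

    D = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    tot = (Ab * D).sum(axis=1)
    if distance_mode == "mean":
        dist = np.where(deg > 0, tot / np.where(deg > 0, deg, 1.0), 0.0)
    elif distance_mode == "total":
        dist = tot
    else:
        raise ConfigError(f"unknown distance_mode {distance_mode!r}")
    return {
        "degree": deg,
        "clustering": clust,
        "betweenness": btw,
        "distance": dist,
    }


@dataclass
class EvalResult:
    ks_degree: np.ndarray
    ks_clustering: np.ndarray
    ks_betweenness: np.ndarray
    ks_distance: np.ndarray
    energy: np.ndarray
    n_replicates: int

    def mean_energy(self) -> float:
        return float(self.energy.mean())


def evaluate_model(
    params: WSBMParams,
    partition: Partition,
    empirical: WeightedConnectome,
    n_replicates: int = 10000,
    seed=None,
    distance_mode: str = "mean",
) -> EvalResult:
    """Per replicate: sample a network, binarize, compute the four node
    statistics, and take the KS of each against the empirical binary
    statistics; energy is the mean of the four."""
    coords = empirical.coords
    emp = node_statistics(empirical.binary, coords, distance_mode)
    rng = np.random.default_rng(seed)
    cols = {k: np.empty(n_replicates) for k in
            ("degree", "clustering", "betweenness", "distance")}
    for rep in range(n_replicates):
        W = sample_network(params, partition, seed=rng)
        syn = node_statistics(W, coords, distance_mode)
        for key in cols:
            cols[key][rep] = ks_statistic(syn[key], emp[key])
    energy = (
        cols["degree"] + cols["clustering"]
        + cols["betweenness"] + cols["distance"]
    ) / 4.0
    return EvalResult(
        ks_degree=cols["degree"],
        ks_clustering=cols["clustering"],
        ks_betweenness=cols["betweenness"],
        ks_distance=cols["distance"],
        energy=energy,
        n_replicates=n_replicates,
    )


def permuted_model(params: WSBMParams, seed=None) -> WSBMParams:
    """One random permutation applied jointly to the
    upper-triangle-plus-diagonal (rate, mean, variance) triplets,
    preserving symmetry and the parameter multiset."""
    rng = np.random.default_rng(seed)
    k = params.k
    pairs = triu_pairs(k)
    perm = rng.permutation(len(pairs))
    out = [np.zeros((k, k)) for _ in range(3)]
    mats = (params.edge_rate, params.weight_mean, params.weight_var)
    for dst, src in enumerate(perm):
        (i, j) = pairs[dst]
        (a, b) = pairs[src]
        for M, O in zip(mats, out):
            O[i - 1, j - 1] = O[j - 1, i - 1] = M[a - 1, b - 1]
    return WSBMParams(*out)


def modular_as_generative(
    A, partition: Partition, var_floor: float | None = None
) -> tuple[WSBMParams, Partition]:
    """Parameter estimation under a fixed partition (no membership
    inference): per block pair, the Poisson rate is the inverse of the
    truncated-presence probability at the observed density,
    ``-log(1 - density)``, and weight mean/variance come from the
    observed nonzero weights.  Deterministic.

    Block pairs with fewer than 2 edges fall back to the global nonzero
    mean and a variance floor (global nonzero variance by default).
    """
    W = A.weights if hasattr(A, "weights") else np.asarray(A, dtype=float)
    lab = partition.labels - 1
    k = partition.k
    iu = np.triu_indices(W.shape[0], k=1)
    w = W[iu]
    r = np.minimum(lab[iu[0]], lab[iu[1]])
    s = np.maximum(lab[iu[0]], lab[iu[1]])
    nz = w[w > 0]
    g_mean = float(nz.mean()) if nz.size else 0.0
    g_var = float(nz.var()) if nz.size > 1 else 1e-6
    if var_floor is None:
        var_floor = max(g_var, 1e-6)

    rate = np.zeros((k, k))
    mean = np.full((k, k), g_mean)
    var = np.full((k, k), var_floor)
    for (bi, bj) in [(i, j) for i in range(k) for j in range(i, k)]:
        sel = (r == bi) & (s == bj)
        n_pairs = int(sel.sum())
        if n_pairs == 0:
            continue
        wsel = w[sel]
        density = float((wsel > 0).mean())
        density = min(density, 1.0 - 1e-12)
        rate[bi, bj] = rate[bj, bi] = -np.log1p(-density)
        present = wsel[wsel > 0]
        if present.size >= 1:
            mean[bi, bj] = mean[bj, bi] = float(present.mean())
        if present.size >= 2:
            v = float(present.var(ddof=1))
            var[bi, bj] = var[bj, bi] = max(v, 1e-12)
    return WSBMParams(edge_rate=rate, weight_mean=mean, weight_var=var), partition
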