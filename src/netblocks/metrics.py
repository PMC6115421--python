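"""Community-conditional node statistics and cross-subject consistency
measures: participation coefficient, within-community z-score, a
node-level decomposition of weighted degree assortativity, hemispheric
laterality KS, high-degree dispersion ICC(3,1), spatial compactness,
and across-subject versatility with permutation inference.
"""

from __future__ import annotations

import numpy as np

from .consensus import align_partitions
from .generative import ks_statistic
from .types import ConfigError, Partition, check_adjacency

__all__ = [
    "participation_coefficient",
    "within_module_z",
    "node_assortativity",
    "community_assortativity",
    "laterality_ks",
    "icc_3_1",
    "top_degree_dispersion_icc",
    "compactness",
    "versatility",
    "versatility_difference_test",
]


def _as_w(A) -> np.ndarray:
    return A.weights if hasattr(A, "weights") else check_adjacency(A)


def participation_coefficient(A, partition: Partition) -> np.ndarray:
    """P_i = 1 - sum_s (w_is / w_i)^2 over communities s, with weighted
    strengths; strength-0 nodes score 0."""
    W = _as_w(A)
    Z = partition.onehot()
    ws = W @ Z                        # n x k strength into each community
    wi = W.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(wi[:, None] > 0, ws / wi[:, None], 0.0)
    P = 1.0 - (frac**2).sum(axis=1)
    return np.where(wi > 0, P, 0.0)


def within_module_z(A, partition: Partition) -> np.ndarray:
    """z_i of within-community strength, standardized within the node's
    own community; singleton communities or zero spread give 0.
    Standard deviation is the population (ddof=0) form."""
    W = _as_w(A)
    lab = partition.labels
    kappa = np.array(
        [W[i, lab == lab[i]].sum() for i in range(W.shape[0])]
    )
    z = np.zeros_like(kappa)
    for c in np.unique(lab):
        members = lab == c
        if members.sum() < 2:
            continue
        mu = kappa[members].mean()
        sd = kappa[members].std()
        if sd > 0:
            z[members] = (kappa[members] - mu) / sd
    return z


def node_assortativity(A, partition: Partition | None = None) -> np.ndarray:
    """Per-node contribution to the global weighted degree-assortativity
    coefficient; contributions sum exactly to the global coefficient.

    With edge-end strength values x, the global coefficient is
    ``r = sum_{i != j} w_ij (x_i - xbar)(x_j - xbar) / (2W sigma^2)``
    (weighted Pearson over ordered edge ends); node i's contribution is
    its ordered-pair share of the numerator."""
    W = _as_w(A)
    x = W.sum(axis=1)  # strengths
    two_w = W.sum()
    if two_w <= 0:
        return np.zeros(W.shape[0])
    xbar = (W @ x).sum() / two_w           # weighted mean over edge ends
    var = (W @ (x**2)).sum() / two_w - xbar**2
    if var <= 0:
        return np.zeros(W.shape[0])
    xc = x - xbar
    contrib = xc * (W @ xc) / (two_w * var)
    return contrib


def community_assortativity(A, partition: Partition) -> np.ndarray:
    """Sum of member node contributions per community (length k)."""
    contrib = node_assortativity(A, partition)
    out = np.zeros(partition.k)
    np.add.at(out, partition.labels - 1, contrib)
    return out


def laterality_ks(values: np.ndarray, hemispheres: np.ndarray) -> float:
    """KS statistic between the left- and right-hemisphere value
    distributions."""
    values = np.asarray(values, dtype=float)
    hemispheres = np.asarray(hemispheres)
    left = values[hemispheres == "L"]
    right = values[hemispheres == "R"]
    return ks_statistic(left, right)


def icc_3_1(M: np.ndarray) -> float:
    """ICC(3,1): two-way mixed, single measures, consistency.
    ``M`` is targets x raters; ICC = (BMS - EMS) / (BMS + (r-1) EMS)."""
    M = np.asarray(M, dtype=float)
    n, r = M.shape
    if n < 2 or r < 2:
        raise ConfigError("ICC needs >= 2 targets and >= 2 raters")
    grand = M.mean()
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    bms = r * ((row_means - grand) ** 2).sum() / (n - 1)
    jms = n * ((col_means - grand) ** 2).sum() / (r - 1)
    sst = ((M - grand) ** 2).sum()
    sse = sst - bms * (n - 1) - jms * (r - 1)
    ems = sse / ((n - 1) * (r - 1))
    denom = bms + (r - 1) * ems
    if denom == 0:
        return 0.0
    return float((bms - ems) / denom)


def _top_counts(
    partition: Partition, degrees: np.ndarray, top_frac: float
) -> np.ndarray:
    """Count of a subject's top-fraction-degree nodes per community.
    The count rounds up; ties at the threshold break by node index."""
    n = degrees.size
    q = int(np.ceil(top_frac * n))
    order = np.lexsort((np.arange(n), -degrees))
    top = order[:q]
    counts = np.zeros(partition.k)
    np.add.at(counts, partition.labels[top] - 1, 1.0)
    return counts


def top_degree_dispersion_icc(
    partitions_by_subject: list[Partition],
    A_by_subject: list,
    top_frac: float = 0.25,
    degree_kind: str = "binary",
    n_boot: int = 500,
    seed=None,
) -> tuple[float, tuple[float, float]]:
    """Consistency, across subjects, of how top-degree nodes disperse
    among (aligned) communities: ICC(3,1) with communities as targets
    and subjects as raters, plus a bootstrap CI over subjects."""
    if degree_kind not in ("binary", "weighted"):
        raise ConfigError(f"unknown degree_kind {degree_kind!r}")
    ref = partitions_by_subject[0]
    aligned = align_partitions(partitions_by_subject, ref)
    cols = []
    for part, A in zip(aligned, A_by_subject):
        W = _as_w(A)
        deg = (W > 0).sum(axis=1) if degree_kind == "binary" else W.sum(axis=1)
        cols.append(_top_counts(part, deg, top_frac))
    M = np.column_stack(cols)  # k x S
    icc = icc_3_1(M)
    rng = np.random.default_rng(seed)
    S = M.shape[1]
    boots = np.array(
        [icc_3_1(M[:, rng.integers(0, S, S)]) for _ in range(n_boot)]
    )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return icc, (float(lo), float(hi))


def compactness(partition: Partition, coords: np.ndarray) -> float:
    """Total within-community Euclidean distance: sum over communities
    of all pairwise member distances (mm)."""
    coords = np.asarray(coords, dtype=float)
    total = 0.0
    for c in np.unique(partition.labels):
        P = coords[partition.labels == c]
        if P.shape[0] < 2:
            continue
        D = np.linalg.norm(P[:, None] - P[None, :], axis=2)
        total += D[np.triu_indices(P.shape[0], k=1)].sum()
    return float(total)


def _align_columns(assignments: np.ndarray, k: int, reference=None) -> np.ndarray:
    cols = [
        Partition(assignments[:, j], k) for j in range(assignments.shape[1])
    ]
    ref = cols[0] if reference is None else reference
    aligned = align_partitions(cols, ref)
    return np.column_stack([p.labels for p in aligned])


def versatility(
    assignments: np.ndarray, reference: Partition | None = None, align: bool = True
) -> np.ndarray:
    """Across-subject versatility: after aligning every subject column to
    a reference (the first column by default), the Shannon entropy (nats)
    of each node's block-frequency vector.  0 iff the node always sits in
    one block; at most ln k."""
    assignments = np.asarray(assignments, dtype=int)
    k = int(assignments.max())
    if align:
        assignments = _align_columns(assignments, k, reference)
    n, S = assignments.shape
    out = np.empty(n)
    for i in range(n):
        counts = np.bincount(assignments[i], minlength=k + 1)[1:]
        p = counts[counts > 0] / S
        out[i] = float(-(p * np.log(p)).sum())
    return out


def versatility_difference_test(
    assignA: np.ndarray,
    assignB: np.ndarray,
    n_perm: int = 10000,
    seed=None,
    alpha: float = 0.05,
    align: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Permutation test of per-node versatility differences between two
    methods' node x subject assignment matrices.

    Per permutation each subject's column pair is randomly swapped
    between the methods; two-sided p-values per node come from the null
    difference distribution, with a Bonferroni mask at ``alpha / n``.

    Returns (difference, p_values, significant_mask).
    """
    A = np.asarray(assignA, dtype=int)
    B = np.asarray(assignB, dtype=int)
    if A.shape != B.shape:
        raise ConfigError("assignment matrices must share a shape")
    k = int(max(A.max(), B.max()))
    if align:
        ref = Partition(A[:, 0], k)
        A = _align_columns(A, k, ref)
        B = _align_columns(B, k, ref)
    n, S = A.shape
    obs = versatility(A, align=False) - versatility(B, align=False)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n)
    for _ in range(n_perm):
        swap = rng.random(S) < 0.5
        PA = np.where(swap[None, :], B, A)
        PB = np.where(swap[None, :], A, B)
        null = versatility(PA, align=False) - versatility(PB, align=False)
        exceed += np.abs(null) >= np.abs(obs)
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    mask = pvals < alpha / n
    return obs, pvals, mask
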