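"""Consensus community detection: partition comparison (VI, NMI),
centroid selection, Hungarian label alignment, staged-prior fitting,
k selection by mean evidence, the frequency-prior consensus loop, and
subject-level seeded fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .types import AssignmentPrior, ConfigError, Partition, WSBMPosterior
from .wsbm import fit_wsbm

__all__ = [
    "ConsensusResult",
    "vi_distance",
    "nmi",
    "contingency",
    "find_centroid",
    "align_partitions",
    "stage1_fit",
    "stage2_refine",
    "DEFAULT_CONCENTRATION_LADDER",
    "select_k",
    "consensus_loop",
    "fit_subject",
]

# extra prior weight per refinement level: the seeded block gets weight
# 1 + c against 1 elsewhere (c = 1 is "100% higher", then the percent
# ladder 150% ... 600%)
DEFAULT_CONCENTRATION_LADDER = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0)


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def contingency(p: Partition, q: Partition) -> np.ndarray:
    """Joint label-count table, shape (p.k, q.k)."""
    if p.n_nodes != q.n_nodes:
        raise ConfigError(
            f"partition length mismatch: {p.n_nodes} vs {q.n_nodes}"
        )
    C = np.zeros((p.k, q.k), dtype=float)
    np.add.at(C, (p.labels - 1, q.labels - 1), 1.0)
    return C


def _entropies(C: np.ndarray) -> tuple[float, float, float]:
    n = C.sum()
    pr, pc = C.sum(axis=1) / n, C.sum(axis=0) / n
    pj = C / n

    def h(x):
        x = x[x > 0]
        return float(-(x * np.log(x)).sum())

    hp, hq = h(pr), h(pc)
    hj = h(pj.ravel())
    mi = hp + hq - hj
    return hp, hq, mi


def vi_distance(p: Partition, q: Partition) -> float:
    """Variation of information, nats: H(p) + H(q) - 2 I(p; q)."""
    hp, hq, mi = _entropies(contingency(p, q))
    return max(hp + hq - 2.0 * mi, 0.0)


def nmi(p: Partition, q: Partition) -> float:
    """Normalized mutual information in [0, 1]; normalization by the
    arithmetic mean of the entropies.  Two deterministic partitions
    (zero entropy each) are identical, hence NMI 1; zero entropy on one
    side only gives 0."""
    hp, hq, mi = _entropies(contingency(p, q))
    denom = 0.5 * (hp + hq)
    if denom <= 0:
        return 1.0 if np.array_equal(p.labels, q.labels) else 0.0
    return float(np.clip(mi / denom, 0.0, 1.0))


def _vi_matrix(partitions: list[Partition]) -> np.ndarray:
    m = len(partitions)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = vi_distance(partitions[i], partitions[j])
    return D


def find_centroid(partitions: list[Partition]) -> int:
    """Index of the partition with minimum VI row sum; ties -> lowest."""
    if not partitions:
        raise ConfigError("empty partition list")
    return int(np.argmin(_vi_matrix(partitions).sum(axis=1)))


def align_partitions(
    partitions: list[Partition], reference: Partition
) -> list[Partition]:
    """Relabel each partition to maximize label overlap with the
    reference (Hungarian algorithm on the negated contingency table).
    Node memberships are unchanged as sets; smaller label sets are
    padded with empty blocks up to a common k."""
    k = max([reference.k] + [p.k for p in partitions])
    ref = Partition(reference.labels, k)
    out = []
    for p in partitions:
        C = contingency(Partition(p.labels, k), ref)
        rows, cols = linear_sum_assignment(-C)
        mapping = np.empty(k, dtype=int)
        mapping[rows] = cols + 1
        out.append(Partition(mapping[p.labels - 1], k))
    return out


def stage1_fit(
    A, k: int, n_trials: int = 250, seed=None, **fit_kwargs
) -> WSBMPosterior:
    """Best (maximum lower-bound) posterior over independent
    uniform-prior trials."""
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    seeds = _seedseq(seed).spawn(n_trials)
    best = None
    for s in seeds:
        post = fit_wsbm(A, k, seed=s, **fit_kwargs)
        if best is None or post.log_evidence > best.log_evidence:
            best = post
    return best


def stage2_refine(
    A,
    k: int,
    seed_partition: Partition,
    ladder=DEFAULT_CONCENTRATION_LADDER,
    n_trials: int = 100,
    seed=None,
    **fit_kwargs,
) -> WSBMPosterior:
    """Refinement with increasingly concentrated priors.

    At each ladder level ``c`` every node's current best block receives
    prior weight ``1 + c`` against 1 for the others; the best posterior
    over ``n_trials`` prior-seeded fits advances to the next level.
    ``c = 0`` is a uniform prior (stage-1 behavior).
    """
    ladder = tuple(ladder)
    if not ladder:
        raise ConfigError("empty concentration ladder")
    ss = _seedseq(seed)
    current = seed_partition
    best = None
    for c, level_seed in zip(ladder, ss.spawn(len(ladder))):
        prior = AssignmentPrior.concentrated(current, 1.0 + c)
        level_best = None
        for s in level_seed.spawn(n_trials):
            post = fit_wsbm(A, k, prior=prior, seed=s, **fit_kwargs)
            if level_best is None or post.log_evidence > level_best.log_evidence:
                level_best = post
        current = level_best.map_partition
        if best is None or level_best.log_evidence > best.log_evidence:
            best = level_best
    return best


def select_k(
    A, k_range=range(6, 12), n_fits: int = 100, seed=None, **fit_kwargs
) -> tuple[int, dict[int, float]]:
    """Mean log-evidence over ``n_fits`` uniform-prior fits at each k;
    returns the maximizing k and the full table for Bayes-factor
    reporting.  Ties -> lowest k."""
    ks = list(k_range)
    if not ks:
        raise ConfigError("empty k range")
    ss = _seedseq(seed)
    table: dict[int, float] = {}
    for k, kseed in zip(ks, ss.spawn(len(ks))):
        evs = [
            fit_wsbm(A, k, seed=s, **fit_kwargs).log_evidence
            for s in kseed.spawn(n_fits)
        ]
        table[k] = float(np.mean(evs))
    best_k = max(table, key=lambda k: (table[k], -k))
    return best_k, table


@dataclass
class ConsensusResult:
    partition: Partition
    frequency_prior: np.ndarray
    n_outer_iterations: int
    converged: bool
    fit_log: list[dict] = field(default_factory=list)


def consensus_loop(
    A,
    k: int,
    n_fits: int = 100,
    max_outer: int = 10,
    seed=None,
    initial_prior: AssignmentPrior | None = None,
    **fit_kwargs,
) -> ConsensusResult:
    """Frequency-prior consensus loop.

    Per outer iteration: ``n_fits`` fits seeded by the current prior ->
    VI centroid -> Hungarian alignment of all fits to the centroid ->
    assignment-frequency matrix -> next prior.  Stops when the consensus
    partition is identical (VI = 0 after alignment) between successive
    iterations, or after ``max_outer`` iterations.
    """
    ss = _seedseq(seed)
    prior = initial_prior
    previous: Partition | None = None
    freq = None
    log: list[dict] = []
    converged = False
    n_outer = 0
    for outer, outer_seed in enumerate(ss.spawn(max_outer)):
        parts = []
        for s in outer_seed.spawn(n_fits):
            post = fit_wsbm(A, k, prior=prior, seed=s, **fit_kwargs)
            parts.append(post.map_partition)
        centroid = parts[find_centroid(parts)]
        aligned = align_partitions(parts, centroid)
        F = np.zeros((centroid.n_nodes, k))
        for p in aligned:
            F[np.arange(p.n_nodes), p.labels - 1] += 1.0
        freq = F / len(aligned)
        n_outer = outer + 1
        if previous is not None:
            vi = vi_distance(centroid, previous)
            log.append(
                {"iteration": n_outer, "vi_to_previous": vi,
                 "nmi_to_previous": nmi(centroid, previous)}
            )
            if vi == 0.0:
                previous = centroid
                converged = True
                break
        else:
            log.append({"iteration": n_outer, "vi_to_previous": np.nan,
                        "nmi_to_previous": np.nan})
        previous = centroid
        prior = AssignmentPrior(np.maximum(freq, 0.0))
    return ConsensusResult(
        partition=previous,
        frequency_prior=freq,
        n_outer_iterations=n_outer,
        converged=converged,
        fit_log=log,
    )


def fit_subject(
    A,
    consensus: Partition,
    concentration: float = 3.0,
    n_fits: int = 5,
    seed=None,
    **fit_kwargs,
) -> Partition:
    """Subject-level fit seeded by the consensus partition: per-node
    prior weight ``concentration`` on the consensus block against 1
    elsewhere; returns the VI centroid of the ``n_fits`` MAP partitions."""
    if n_fits < 1:
        raise ConfigError("n_fits must be >= 1")
    prior = AssignmentPrior.concentrated(consensus, concentration)
    parts = []
    for s in _seedseq(seed).spawn(n_fits):
        post = fit_wsbm(A, consensus.k, prior=prior, seed=s, **fit_kwargs)
        parts.append(post.map_partition)
    return parts[find_centroid(parts)]
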