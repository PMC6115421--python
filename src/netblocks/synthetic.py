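"""Synthetic bilateral connectome cohorts with planted block structure
and age-dependent block-weight trends.

Conventions
-----------
* Nodes ``0..n/2-1`` form the left hemisphere, ``n/2..n-1`` the right;
  node ``i``'s homotopic partner is ``i + n/2`` and shares its block.
* Node coordinates are a jittered grid in mm, mirrored across x = 0
  (left hemisphere x < 0).
* Edge presence is Poisson-with-truncation (count >= 1 means an edge);
  present-edge weights are Normal, clipped at a small positive floor.
* "Linear" age trends are slopes about the mid-point of the age range;
  "quadratic" trends peak at ``peak_age`` with value ``amplitude`` and
  fall off over half the age range; "poisson_curve" trends follow
  ``b1 * age * exp(-b2 * age)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    ConfigError,
    NodeMetadata,
    Partition,
    WeightedConnectome,
    WSBMParams,
    triu_pairs,
)
from .wsbm import WEIGHT_FLOOR

__all__ = [
    "TrendSpec",
    "CohortConfig",
    "SyntheticSubject",
    "make_planted_partition",
    "make_node_metadata",
    "sample_subject",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class TrendSpec:
    """Age modulation of one block pair's mean weight."""

    kind: str = "none"  # none | linear | quadratic | poisson_curve
    slope: float = 0.0          # linear
    peak_age: float = 45.0      # quadratic
    amplitude: float = 0.0      # quadratic
    b1: float = 0.0             # poisson_curve
    b2: float = 0.05            # poisson_curve

    def __call__(self, age: float, age_range: tuple[float, float]) -> float:
        lo, hi = age_range
        if self.kind == "none":
            return 0.0
        if self.kind == "linear":
            return self.slope * (age - 0.5 * (lo + hi))
        if self.kind == "quadratic":
            half = max(0.5 * (hi - lo), 1e-9)
            return self.amplitude * (1.0 - ((age - self.peak_age) / half) ** 2)
        if self.kind == "poisson_curve":
            return self.b1 * age * np.exp(-self.b2 * age)
        raise ConfigError(f"unknown trend kind {self.kind!r}")


@dataclass
class CohortConfig:
    n_subjects: int
    n_nodes: int
    k_planted: int
    age_range: tuple[float, float] = (6.0, 85.0)
    edge_rate_matrix: np.ndarray | None = None
    weight_mean_matrix: np.ndarray | None = None
    weight_sd_matrix: np.ndarray | None = None
    trend_spec: dict[tuple[int, int], TrendSpec] = field(default_factory=dict)
    sex_effect: float = 0.0
    motion_noise_sd: float = 0.1
    rng_seed: int = 0
    block_sizes: np.ndarray | None = None  # full-network sizes, must be even
    weight_floor: float = WEIGHT_FLOOR

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.n_nodes % 2:
            raise ConfigError("n_nodes must be even (half per hemisphere)")
        if self.k_planted > self.n_nodes:
            raise ConfigError("k_planted cannot exceed n_nodes")
        if self.age_range[0] > self.age_range[1]:
            raise ConfigError("age_range must be (min, max)")
        k = self.k_planted
        if self.edge_rate_matrix is None:
            self.edge_rate_matrix = np.full((k, k), 0.2)
            np.fill_diagonal(self.edge_rate_matrix, 0.8)
        if self.weight_mean_matrix is None:
            self.weight_mean_matrix = np.full((k, k), 1.0)
            np.fill_diagonal(self.weight_mean_matrix, 2.5)
        if self.weight_sd_matrix is None:
            self.weight_sd_matrix = np.full((k, k), 0.4)
        self.edge_rate_matrix = np.asarray(self.edge_rate_matrix, dtype=float)
        self.weight_mean_matrix = np.asarray(self.weight_mean_matrix, dtype=float)
        self.weight_sd_matrix = np.asarray(self.weight_sd_matrix, dtype=float)
        for name, M in [
            ("edge_rate_matrix", self.edge_rate_matrix),
            ("weight_mean_matrix", self.weight_mean_matrix),
            ("weight_sd_matrix", self.weight_sd_matrix),
        ]:
            if M.shape != (k, k):
                raise ConfigError(f"{name} must be {k} x {k}")
            if not np.allclose(M, M.T):
                raise ConfigError(f"{name} must be symmetric")
        if (self.weight_sd_matrix <= 0).any():
            raise ConfigError("weight_sd_matrix entries must be > 0")
        if (self.edge_rate_matrix < 0).any():
            raise ConfigError("edge_rate_matrix entries must be >= 0")
        for pair in self.trend_spec:
            i, j = pair
            if not (1 <= i <= j <= k):
                raise ConfigError(f"trend_spec pair {pair} out of range for k={k}")

    def full_trend_spec(self) -> dict[tuple[int, int], TrendSpec]:
        """Trend spec for all (k^2 - k)/2 + k block pairs, "none" filled in."""
        none = TrendSpec()
        return {p: self.trend_spec.get(p, none) for p in triu_pairs(self.k_planted)}

    def params_at(self, age: float, sex: int) -> WSBMParams:
        """Block-pair parameters for one subject."""
        k = self.k_planted
        mean = self.weight_mean_matrix.copy()
        for (i, j), trend in self.full_trend_spec().items():
            delta = trend(age, self.age_range)
            mean[i - 1, j - 1] += delta
            mean[j - 1, i - 1] = mean[i - 1, j - 1]
        mean += self.sex_effect * int(sex)
        return WSBMParams(
            edge_rate=self.edge_rate_matrix,
            weight_mean=mean,
            weight_var=self.weight_sd_matrix**2,
        )


@dataclass
class SyntheticSubject:
    subject_id: int
    connectome: WeightedConnectome
    true_partition: Partition
    age: float
    sex: int
    motion: float

    @property
    def total_strength(self) -> float:
        return self.connectome.total_strength()


def make_planted_partition(
    n_nodes: int,
    k_planted: int,
    bilateral: bool = True,
    block_sizes: np.ndarray | None = None,
) -> Partition:
    """Planted partition with homotopic pairs sharing a block.

    Left-hemisphere labels cycle ``1..k`` and are mirrored onto the right
    hemisphere, so every block is bilateral.  ``block_sizes`` (even,
    summing to ``n_nodes``) overrides the near-equal default.
    """
    if n_nodes % 2:
        raise ConfigError("n_nodes must be even")
    if k_planted > n_nodes:
        raise ConfigError(f"k_planted={k_planted} exceeds n_nodes={n_nodes}")
    if bilateral and k_planted > n_nodes // 2:
        raise ConfigError("bilateral layout needs k_planted <= n_nodes / 2")
    half = n_nodes // 2
    if bilateral:
        if block_sizes is not None:
            sizes = np.asarray(block_sizes, dtype=int)
            if sizes.size != k_planted or sizes.sum() != n_nodes:
                raise ConfigError("block_sizes must have length k and sum to n")
            if (sizes % 2).any() or (sizes < 2).any():
                raise ConfigError("bilateral block_sizes must be even and >= 2")
            left = np.repeat(np.arange(1, k_planted + 1), sizes // 2)
        else:
            left = 1 + np.arange(half) % k_planted
        labels = np.concatenate([left, left])
    else:
        labels = 1 + np.arange(n_nodes) % k_planted
    return Partition(labels=labels, k=k_planted)


def make_node_metadata(n_nodes: int, seed=0, jitter: float = 2.0) -> list[NodeMetadata]:
    """Jittered-grid coordinates, left hemisphere mirrored at x = 0."""
    if n_nodes % 2:
        raise ConfigError("n_nodes must be even")
    rng = np.random.default_rng(seed)
    half = n_nodes // 2
    side = int(np.ceil(np.sqrt(half)))
    ys, zs = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    grid = np.c_[ys.ravel(), zs.ravel()][:half] * 15.0
    base_x = 40.0 + rng.uniform(-jitter, jitter, half)
    jyz = rng.uniform(-jitter, jitter, (half, 2))
    nodes: list[NodeMetadata] = []
    for i in range(half):
        y, z = grid[i] + jyz[i]
        nodes.append(
            NodeMetadata(i + 1, "L", (-base_x[i], y, z), f"L_{i + 1}")
        )
    for i in range(half):
        y, z = grid[i] + jyz[i]
        nodes.append(
            NodeMetadata(half + i + 1, "R", (base_x[i], y, z), f"R_{i + 1}")
        )
    return nodes


def sample_subject(
    config: CohortConfig,
    age: float,
    seed=None,
    sex: int | None = None,
    motion: float | None = None,
    nodes: list[NodeMetadata] | None = None,
    subject_id: int = 0,
) -> SyntheticSubject:
    """Draw one subject's network at the given age."""
    rng = np.random.default_rng(seed)
    if sex is None:
        sex = int(rng.integers(0, 2))
    if motion is None:
        motion = float(abs(rng.normal(0.0, config.motion_noise_sd)))
    partition = make_planted_partition(
        config.n_nodes, config.k_planted, block_sizes=config.block_sizes
    )
    params = config.params_at(age, sex)
    from .wsbm import sample_network

    W = sample_network(
        params, partition, seed=rng, weight_floor=config.weight_floor
    )
    if nodes is None:
        nodes = make_node_metadata(config.n_nodes, seed=config.rng_seed)
    return SyntheticSubject(
        subject_id=subject_id,
        connectome=WeightedConnectome(weights=W, nodes=nodes),
        true_partition=partition,
        age=float(age),
        sex=sex,
        motion=motion,
    )


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """Full cohort: ages uniform over the configured range, one row of
    covariates per subject.  Reproducible given ``config.rng_seed``."""
    rng = np.random.default_rng(config.rng_seed)
    ages = rng.uniform(*config.age_range, size=config.n_subjects)
    nodes = make_node_metadata(config.n_nodes, seed=config.rng_seed)
    seeds = np.random.SeedSequence(config.rng_seed).spawn(config.n_subjects)
    subjects = [
        sample_subject(
            config, age, seed=s, nodes=nodes, subject_id=i + 1
        )
        for i, (age, s) in enumerate(zip(ages, seeds))
    ]
    table = pd.DataFrame(
        {
            "id": [s.subject_id for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "motion": [s.motion for s in subjects],
            "total_strength": [s.total_strength for s in subjects],
        }
    )
    return subjects, table


def write_cohort(subjects, table, outdir) -> None:
    """Write one dense matrix per subject plus nodes.tsv, subjects.csv and
    truth.tsv (all ids 1-based)."""
    from pathlib import Path

    from .io import write_matrix, write_nodes

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        write_matrix(outdir / f"subject_{s.subject_id:04d}.txt", s.connectome.weights)
    write_nodes(outdir / "nodes.tsv", subjects[0].connectome.nodes)
    table.to_csv(outdir / "subjects.csv", index=False)
    truth = subjects[0].true_partition
    pd.DataFrame(
        {"node": np.arange(1, truth.n_nodes + 1), "planted_block": truth.labels}
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
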