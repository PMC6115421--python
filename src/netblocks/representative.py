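"""Group-representative connectome by distance-binned constrained
averaging: match the subject-average edge density while preserving the
distribution of inter-node distances among retained edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ConfigError, FormatError, WeightedConnectome

__all__ = ["build_representative", "RepresentativeProvenance"]


@dataclass
class RepresentativeProvenance:
    bin_edges: np.ndarray
    per_bin_targets: np.ndarray
    per_bin_retained: np.ndarray


def build_representative(
    cohort: list[WeightedConnectome],
    n_bins: int = 10,
) -> tuple[WeightedConnectome, RepresentativeProvenance]:
    """Distance-binned consensus averaging.

    Candidate edges (nonzero in at least one subject) are binned by the
    Euclidean distance between their node centroids into ``n_bins``
    equal-width bins.  Within each bin, edges are ranked by cross-subject
    occurrence frequency (ties: higher mean nonzero weight, then lower
    node-index pair) and retained until the bin holds the rounded
    per-subject average count for that bin.  Retained edges carry the
    mean of their nonzero subject weights.
    """
    if len(cohort) < 2:
        raise ConfigError("need at least 2 subjects")
    if n_bins < 1:
        raise ConfigError("n_bins must be >= 1")
    n = cohort[0].n_nodes
    for c in cohort:
        if c.n_nodes != n:
            raise FormatError("subjects must share one node set")
    if cohort[0].nodes is None:
        raise FormatError("node coordinates required for distance binning")
    coords = cohort[0].coords

    stack = np.stack([c.weights for c in cohort])  # S x n x n
    iu = np.triu_indices(n, k=1)
    w = stack[:, iu[0], iu[1]]                     # S x P
    present = w > 0
    freq = present.sum(axis=0)
    candidate = freq > 0
    with np.errstate(invalid="ignore"):
        mean_w = np.where(candidate, w.sum(axis=0) / np.maximum(freq, 1), 0.0)

    d = np.linalg.norm(coords[iu[0]] - coords[iu[1]], axis=1)
    dc = d[candidate]
    lo, hi = float(dc.min()), float(dc.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    # assign bins over candidate pairs only; right-inclusive last bin
    bin_ix = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)

    keep = np.zeros(iu[0].size, dtype=bool)
    targets = np.zeros(n_bins, dtype=int)
    retained = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        in_bin = candidate & (bin_ix == b)
        # per-subject edge count in this distance bin, averaged; ties-to-even
        per_subject = present[:, bin_ix == b].sum(axis=1)
        target = int(np.round(per_subject.mean()))
        targets[b] = target
        if target <= 0 or not in_bin.any():
            continue
        ids = np.flatnonzero(in_bin)
        order = sorted(
            ids, key=lambda p: (-freq[p], -mean_w[p], iu[0][p], iu[1][p])
        )
        chosen = order[: min(target, len(order))]
        keep[chosen] = True
        retained[b] = len(chosen)

    W = np.zeros((n, n))
    W[iu[0][keep], iu[1][keep]] = mean_w[keep]
    W = W + W.T
    rep = WeightedConnectome(weights=W, nodes=cohort[0].nodes)
    return rep, RepresentativeProvenance(edges, targets, retained)
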