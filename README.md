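# netblocks

Weighted stochastic block modeling, consensus community detection, and
lifespan trend analysis for weighted brain-style networks.

The package implements an end-to-end analysis pipeline for cohorts of
weighted, symmetric, non-negative adjacency matrices:

1. **Synthetic cohorts** (`netblocks.synthetic`) — bilateral networks with
   planted block structure, Poisson edge existence, Normal edge weights,
   and age-modulated block-weight trends (linear, inverted-U quadratic,
   or `b1 * age * exp(-b2 * age)` curves) with sex/motion nuisance
   covariates.
2. **WSBM inference** (`netblocks.wsbm`) — variational Bayes for a
   weighted stochastic block model (truncated-Poisson edge existence,
   Normal edge weights) with conjugate Gamma / Normal-Gamma updates,
   configurable per-node assignment priors, and a monotone evidence
   lower bound.
3. **Representative matrix** (`netblocks.representative`) — distance-binned
   constrained averaging matching subject-average density while
   preserving the edge-length distribution.
4. **Consensus fitting** (`netblocks.consensus`) — multi-trial uniform-prior
   search, a concentration-ladder refinement stage, k selection by mean
   log-evidence (Bayes factors), a VI-centroid / Hungarian-alignment /
   frequency-prior consensus loop, and consensus-seeded subject fits.
5. **Modular baseline** (`netblocks.modular`) — deterministic Newman
   leading-eigenvector modularity maximization with single-node
   refinement, a resolution (gamma) sweep, and k-matched VI-nearest
   selection.
6. **Generative evaluation** (`netblocks.generative`) — KS "energy" (mean of
   the KS statistics of degree, clustering, betweenness, and node
   Euclidean distance distributions) of sampled ensembles against an
   empirical network, with a permuted-parameter null.
7. **Community metrics** (`netblocks.metrics`) — participation coefficient,
   within-community z-score, node-level assortativity decomposition,
   hemispheric laterality KS, top-degree dispersion ICC(3,1) with
   bootstrap CI, spatial compactness, and across-subject versatility
   with permutation inference.
8. **Lifespan statistics** (`netblocks.lifespan`) — block-interaction
   strength extraction, three regression families with nuisance
   residualization, leave-one-out cross-validation with the uncentered
   R², permutation p-values, Bonferroni reporting, and block-vector
   cosine/city-block similarity trends.

## CLI

A `netblocks` console script exposes each stage:

```sh
netblocks synth --n-subjects 60 --n-nodes 40 --k 4 --seed 1 --out run/cohort
netblocks representative --matrices run/cohort --subjects run/cohort/subjects.csv \
    --nodes run/cohort/nodes.tsv --out run/rep.txt
netblocks select-k --matrix run/rep.txt --k-min 3 --k-max 6 --n-fits 20 \
    --seed 1 --out run/evidence.csv
netblocks consensus --matrix run/rep.txt --k 4 --n-fits 50 --seed 1 --out run/cons
netblocks modular-sweep --matrix run/rep.txt --out run/sweep \
    --match-k 4 --reference run/cons/consensus_partition.tsv
netblocks run-all --config config.yaml --out run/full
```

`run-all` drives the whole pipeline from a flat YAML config (see
`netblocks.pipeline.DEFAULTS` for keys); every stage writes a JSON
provenance record and reruns are reproducible given the global seed.

## File formats

Everything is plain text: dense whitespace/CSV or MatrixMarket adjacency
matrices, two-column TSV partitions (`node_id`, `block`, 1-based), a
`nodes.tsv` metadata table (id, hemisphere, x, y, z, name), and a
`subjects.csv` covariate table (id, age, sex, motion, total_strength).

## Conventions

* Node ids and block labels are 1-based in files, 0-based internally.
* Total network strength is the sum of upper-triangle weights (each
  undirected edge counted once).
* Edge presence follows a truncated-Poisson model: an edge exists when a
  Poisson draw with the block-pair rate is >= 1, so the presence
  probability is `1 - exp(-rate)`.
* The leave-one-out R² is uncentered (`1 - SSE / sum(y^2)`) and may be
  negative; it is deliberately not clamped.
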