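"""End-to-end pipeline: synthetic cohort -> representative matrix ->
k selection -> consensus -> modular baseline -> subject fits ->
generative evaluation -> community statistics -> lifespan trends.

Every stage writes its outputs plus a JSON provenance record (seed,
parameters) into the run directory.  A global seed deterministically
derives per-stage seeds, so a rerun with the same configuration
reproduces identical outputs.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus import consensus_loop, fit_subject, select_k
from .generative import evaluate_model, modular_as_generative, permuted_model
from .io import apply_input_filters, write_matrix, write_partition
from .lifespan import block_summary, consensus_vector, lifespan_pipeline
from .metrics import (
    laterality_ks,
    participation_coefficient,
    versatility,
    within_module_z,
    node_assortativity,
)
from .modular import gamma_sweep, match_to_k
from .representative import build_representative
from .synthetic import CohortConfig, TrendSpec, generate_cohort, write_cohort
from .types import AssignmentPrior, NoMatchingPartition, Partition
from .wsbm import fit_wsbm

DEFAULTS = {
    "n_subjects": 60,
    "n_nodes": 40,
    "k_planted": 4,
    "age_range": [6.0, 85.0],
    "seed": 0,
    "min_weight": 0.0,
    "density_cutoff": 0.0,
    "young_adult_range": [25.0, 35.0],
    "n_bins": 10,
    "k_range": [3, 6],
    "select_k_fits": 8,
    "consensus_fits": 12,
    "max_outer": 10,
    "subject_fits": 3,
    "subject_concentration": 3.0,
    "gamma_lo": 0.5,
    "gamma_hi": 4.0,
    "gamma_step": 0.05,
    "eval_replicates": 50,
    "n_perm": 200,
    "include_motion": False,
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
    merged = dict(DEFAULTS)
    merged.update(cfg)
    return merged


def _stage_seed(global_seed: int, stage: str) -> int:
    # stable per-stage derivation from the global seed (crc32 is
    # process-independent, unlike hash())
    import zlib

    h = np.random.SeedSequence([global_seed, zlib.crc32(stage.encode())])
    return int(h.generate_state(1)[0])


def _provenance(run_dir: Path, stage: str, seed, params: dict) -> None:
    rec = {
        "stage": stage,
        "seed": seed,
        "params": params,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(run_dir / f"provenance_{stage}.json", "w") as fh:
        json.dump(rec, fh, indent=2, default=str)


def run_pipeline(config, run_dir) -> Path:
    """Execute all stages; returns the run directory."""
    cfg = load_config(config)
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    gseed = int(cfg["seed"])

    # --- synthetic cohort -------------------------------------------------
    trend_spec = {}
    for key, spec in (cfg.get("trends") or {}).items():
        i, j = (int(x) for x in str(key).split("-"))
        trend_spec[(i, j)] = TrendSpec(**spec)
    ccfg = CohortConfig(
        n_subjects=int(cfg["n_subjects"]),
        n_nodes=int(cfg["n_nodes"]),
        k_planted=int(cfg["k_planted"]),
        age_range=tuple(cfg["age_range"]),
        trend_spec=trend_spec,
        rng_seed=_stage_seed(gseed, "synth"),
    )
    subjects, table = generate_cohort(ccfg)
    cohort_dir = run_dir / "cohort"
    write_cohort(subjects, table, cohort_dir)
    _provenance(run_dir, "synth", ccfg.rng_seed,
                {"n_subjects": ccfg.n_subjects, "n_nodes": ccfg.n_nodes,
                 "k_planted": ccfg.k_planted})

    # --- input filters ----------------------------------------------------
    kept = []
    for s in subjects:
        filtered, too_sparse = apply_input_filters(
            s.connectome, cfg["min_weight"], cfg["density_cutoff"]
        )
        if not too_sparse:
            s.connectome = filtered
            kept.append(s)
    table = table[table["id"].isin([s.subject_id for s in kept])].reset_index(
        drop=True
    )
    subjects = kept

    # --- representative matrix -------------------------------------------
    lo, hi = cfg["young_adult_range"]
    young = [s for s in subjects if lo <= s.age <= hi] or subjects
    rep, prov = build_representative(
        [s.connectome for s in young], n_bins=int(cfg["n_bins"])
    )
    write_matrix(run_dir / "representative.txt", rep.weights)
    _provenance(run_dir, "representative", None,
                {"n_subjects": len(young), "n_bins": cfg["n_bins"],
                 "per_bin_targets": prov.per_bin_targets.tolist()})

    # --- k selection ------------------------------------------------------
    kmin, kmax = cfg["k_range"]
    seed_k = _stage_seed(gseed, "select_k")
    best_k, evidence = select_k(
        rep, range(int(kmin), int(kmax) + 1),
        n_fits=int(cfg["select_k_fits"]), seed=seed_k,
    )
    pd.DataFrame(
        {"k": list(evidence), "mean_log_evidence": list(evidence.values())}
    ).to_csv(run_dir / "evidence.csv", index=False)
    _provenance(run_dir, "select_k", seed_k, {"best_k": best_k})

    # --- consensus --------------------------------------------------------
    seed_c = _stage_seed(gseed, "consensus")
    cons = consensus_loop(
        rep, best_k, n_fits=int(cfg["consensus_fits"]),
        max_outer=int(cfg["max_outer"]), seed=seed_c,
    )
    write_partition(run_dir / "consensus_partition.tsv", cons.partition)
    np.savetxt(run_dir / "frequency_prior.txt", cons.frequency_prior)
    _provenance(run_dir, "consensus", seed_c,
                {"k": best_k, "converged": cons.converged,
                 "n_outer": cons.n_outer_iterations})

    # --- modular baseline -------------------------------------------------
    sweep = gamma_sweep(
        rep, cfg["gamma_lo"], cfg["gamma_hi"], cfg["gamma_step"]
    )
    pd.DataFrame(
        {
            "gamma": [g for g, _ in sweep],
            "n_communities": [p.n_nonempty() for _, p in sweep],
        }
    ).to_csv(run_dir / "gamma_sweep.csv", index=False)
    try:
        gamma_star, modular_part = match_to_k(sweep, best_k, cons.partition)
        write_partition(run_dir / "modular_partition.tsv", modular_part)
    except NoMatchingPartition:
        gamma_star, modular_part = None, None
    _provenance(run_dir, "modular", None,
                {"gamma": gamma_star, "matched": modular_part is not None})

    # --- subject-level fits -----------------------------------------------
    seed_s = _stage_seed(gseed, "subjects")
    fits_dir = run_dir / "subject_partitions"
    fits_dir.mkdir(exist_ok=True)
    ss = np.random.SeedSequence(seed_s)
    subject_parts = []
    for s, sub_seed in zip(subjects, ss.spawn(len(subjects))):
        part = fit_subject(
            s.connectome, cons.partition,
            concentration=float(cfg["subject_concentration"]),
            n_fits=int(cfg["subject_fits"]), seed=sub_seed,
        )
        subject_parts.append(part)
        write_partition(fits_dir / f"subject_{s.subject_id:04d}.tsv", part)
    _provenance(run_dir, "subjects", seed_s, {"n_subjects": len(subjects)})

    # --- generative evaluation --------------------------------------------
    seed_g = _stage_seed(gseed, "generative")
    wsbm_prior = AssignmentPrior.concentrated(cons.partition, 1e6)
    wsbm_post = fit_wsbm(rep, best_k, prior=wsbm_prior, seed=seed_g)
    reps = int(cfg["eval_replicates"])
    results = {
        "wsbm": evaluate_model(
            wsbm_post.params, cons.partition, rep, reps, seed=seed_g
        ),
        "wsbm_permuted": evaluate_model(
            permuted_model(wsbm_post.params, seed=seed_g),
            cons.partition, rep, reps, seed=seed_g + 1,
        ),
    }
    if modular_part is not None:
        mparams, _ = modular_as_generative(rep, modular_part)
        results["modular"] = evaluate_model(
            mparams, modular_part, rep, reps, seed=seed_g + 2
        )
    rows = []
    for name, res in results.items():
        for i in range(res.n_replicates):
            rows.append(
                {
                    "model": name, "replicate": i,
                    "ks_degree": res.ks_degree[i],
                    "ks_clustering": res.ks_clustering[i],
                    "ks_betweenness": res.ks_betweenness[i],
                    "ks_distance": res.ks_distance[i],
                    "energy": res.energy[i],
                }
            )
    pd.DataFrame(rows).to_csv(run_dir / "generative_eval.csv", index=False)
    _provenance(run_dir, "generative", seed_g, {"replicates": reps})

    # --- community statistics ---------------------------------------------
    hemis = subjects[0].connectome.hemispheres
    stat_rows = []
    for s, part in zip(subjects, subject_parts):
        for stat_name, fn in [
            ("participation", participation_coefficient),
            ("within_z", within_module_z),
            ("assortativity", node_assortativity),
        ]:
            vals = fn(s.connectome, part)
            for node, v in enumerate(vals, start=1):
                stat_rows.append(
                    {"subject": s.subject_id, "node": node,
                     "statistic": stat_name, "value": v}
                )
            stat_rows.append(
                {"subject": s.subject_id, "node": 0,
                 "statistic": f"laterality_ks_{stat_name}",
                 "value": laterality_ks(vals, hemis)}
            )
    pd.DataFrame(stat_rows).to_csv(run_dir / "community_stats.csv", index=False)
    assign = np.column_stack([p.labels for p in subject_parts])
    np.savetxt(run_dir / "versatility.txt", versatility(assign))
    _provenance(run_dir, "community_stats", None, {})

    # --- lifespan trends ---------------------------------------------------
    seed_l = _stage_seed(gseed, "lifespan")
    cvec = consensus_vector(wsbm_post.params)
    blocks, subj_sim = lifespan_pipeline(
        [s.connectome for s in subjects],
        subject_parts,
        cvec,
        table,
        n_perm=int(cfg["n_perm"]),
        seed=seed_l,
        include_motion=bool(cfg["include_motion"]),
    )
    blocks.to_csv(run_dir / "block_trends.csv", index=False)
    subj_sim.to_csv(run_dir / "subject_similarity.csv", index=False)
    _provenance(run_dir, "lifespan", seed_l,
                {"n_perm": cfg["n_perm"],
                 "bonferroni_alpha": blocks.attrs.get("bonferroni_alpha")})
    return run_dir
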