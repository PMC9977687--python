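"""End-to-end orchestration: simulate -> normalize -> cluster -> overlap
-> jsd -> enrich, with deterministic per-stage seeds and a run manifest.

All randomness flows from one root seed, split per stage; every output
table carries a header comment naming the producing version and seed,
and numeric cells are written with fixed 6-significant-digit formatting
so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

import devcomp
from devcomp.clustering import (
    fuzzy_cmeans,
    harden_assignments,
    min_centroid_distance,
    select_k_elbow,
    standardize_profiles,
)
from devcomp.enrichment import label_enrichment
from devcomp.expression import average_replicates, size_factor_normalize
from devcomp.jsd import (
    bootstrap_jsd,
    gene_wise_jsd,
    normalize_jsd,
    prepare_for_jsd,
    similarity_drivers,
    stage_distribution,
)
from devcomp.overlap import (
    QuadrantSpec,
    direction_pattern,
    pairwise_overlap_tests,
    quadrant_relative_similarity,
    shifted_gene_sets,
    to_orthogroup_sets,
)
from devcomp.simulate import SimulationConfig, default_config, simulate_dataset, write_bundle

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


def write_table(df: pd.DataFrame, path, seed: int, index: bool = False,
                index_label: str | None = None) -> None:
    """TSV writer with a provenance header comment and fixed precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# devcomp {devcomp.__version__} seed={seed}\n")
        df.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT, index=index,
                  index_label=index_label)


def stage_seeds(root_seed: int, stages=("simulate", "cluster", "overlap", "jsd", "enrich")):
    """Split one root seed into independent per-stage integer seeds."""
    rng = np.random.default_rng(root_seed)
    return {stage: int(rng.integers(0, 2**31 - 1)) for stage in stages}


def quadrants_from_centroids(models: dict, late_from: dict[str, int]) -> QuadrantSpec:
    """Classify clusters early/late by the centroid's peak stage ordinal."""
    early: dict[str, set] = {}
    late: dict[str, set] = {}
    for species, model in models.items():
        boundary = late_from[species]
        early[species], late[species] = set(), set()
        peaks = model.centroids.to_numpy().argmax(axis=1)
        for cluster, peak in zip(model.centroids.index, peaks):
            (late if peak >= boundary else early)[species].add(cluster)
    return QuadrantSpec(early=early, late=late)


def run_pipeline(config: dict | None = None, out_dir="devcomp_run", seed: int = 0) -> dict:
    """Execute the full synthetic-data analysis; returns the run manifest.

    ``config`` keys (all optional): ``simulate`` (a
    :class:`SimulationConfig` dict), ``k`` or ``k_range``, ``fuzzifier``,
    ``restarts``, ``expressed_threshold``, ``bootstrap``, ``scope``,
    ``driver_stage_pairs`` (list of [stageA, stageB]).
    """
    config = dict(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed)
    manifest: dict = {
        "version": devcomp.__version__,
        "root_seed": seed,
        "stage_seeds": seeds,
        "stages": [],
        "outputs": [],
    }

    def record(stage: str, *paths) -> None:
        manifest["stages"].append(stage)
        manifest["outputs"].extend(str(Path(p).relative_to(out)) for p in paths)

    # -- simulate ---------------------------------------------------
    sim_cfg = config.get("simulate")
    sim_config = (
        SimulationConfig.from_dict({**sim_cfg, "seed": seeds["simulate"]})
        if sim_cfg
        else default_config(seed=seeds["simulate"])
    )
    matrices, orthology, annotation, truth = simulate_dataset(sim_config)
    write_bundle(matrices, orthology, annotation, truth, sim_config, out / "data")
    record("simulate", *(out / "data").iterdir())

    species_names = [s.name for s in sim_config.species]
    late_from = {
        s.name: (s.late_from if s.late_from is not None else s.n_stages // 2)
        for s in sim_config.species
    }

    # -- normalize + cluster ----------------------------------------
    models = {}
    assignments = {}
    for i, species in enumerate(species_names):
        norm = size_factor_normalize(matrices[species]["counts"])
        z = standardize_profiles(
            norm, expressed_threshold=float(config.get("expressed_threshold", 2.0))
        )
        cluster_seed = seeds["cluster"] + i
        restarts = int(config.get("restarts", 3))
        fuzzifier = config.get("fuzzifier")
        if "k" in config:
            k = int(config["k"])
        else:
            lo, hi = config.get("k_range", [2, min(9, z.n_genes - 1)])
            series = min_centroid_distance(
                z, range(int(lo), int(hi) + 1), m=fuzzifier,
                seed=cluster_seed, restarts=restarts,
            )
            write_table(
                pd.DataFrame(series, columns=["k", "d_min"]),
                out / f"cluster/{species}.dmin.tsv", seed,
            )
            k = select_k_elbow(series)
            logger.info("%s: elbow selected k=%d", species, k)
        model = fuzzy_cmeans(z, k=k, m=fuzzifier, seed=cluster_seed, restarts=restarts)
        models[species] = model
        assignments[species] = harden_assignments(
            model, min_membership=config.get("min_membership")
        )
        write_table(model.membership, out / f"cluster/{species}.membership.tsv",
                    seed, index=True, index_label="gene")
        write_table(model.centroids, out / f"cluster/{species}.centroids.tsv",
                    seed, index=True, index_label="cluster")
        write_table(assignments[species].to_frame(),
                    out / f"cluster/{species}.assignments.tsv",
                    seed, index=True, index_label="gene")
    record("cluster", *(out / "cluster").iterdir())

    quadrants = quadrants_from_centroids(models, late_from)

    # -- overlap ----------------------------------------------------
    shifted_truth_counts = {}
    for a_i in range(len(species_names)):
        for b_i in range(a_i + 1, len(species_names)):
            sp_a, sp_b = species_names[a_i], species_names[b_i]
            sets_a = to_orthogroup_sets(assignments[sp_a], orthology, sp_a)
            sets_b = to_orthogroup_sets(assignments[sp_b], orthology, sp_b)
            universe = len(
                set().union(*sets_a.values()) & set().union(*sets_b.values())
            )
            table = pairwise_overlap_tests(sets_a, sets_b, universe)
            rs = quadrant_relative_similarity(table, quadrants, sp_a, sp_b)
            pair = f"{sp_a}__vs__{sp_b}"
            write_table(table, out / f"overlap/{pair}.overlap.tsv", seed)
            write_table(rs, out / f"overlap/{pair}.rs.tsv", seed)
            for direction in ("earlyA_lateB", "lateA_earlyB"):
                pairs = shifted_gene_sets(
                    assignments, orthology, quadrants,
                    direction_pattern(direction, sp_a, sp_b),
                )
                write_table(
                    pd.DataFrame(pairs, columns=[sp_a, sp_b]),
                    out / f"overlap/{pair}.shifted.{direction}.tsv", seed,
                )
                shifted_truth_counts[f"{pair}:{direction}"] = len(pairs)
    record("overlap", *(out / "overlap").iterdir())

    # -- jsd --------------------------------------------------------
    jsd_matrices = []
    prepared = {}
    for a_i in range(len(species_names)):
        for b_i in range(a_i + 1, len(species_names)):
            sp_a, sp_b = species_names[a_i], species_names[b_i]
            pairs = orthology.one_to_one(sp_a, sp_b)
            qa = prepare_for_jsd(matrices[sp_a]["tpm"], [a for a, _ in pairs])
            qb = prepare_for_jsd(matrices[sp_b]["tpm"], [b for _, b in pairs])
            prepared[(sp_a, sp_b)] = (qa, qb, pairs)
            jsd_matrices.append(
                bootstrap_jsd(qa, qb, pairs,
                              n_boot=int(config.get("bootstrap", 100)),
                              seed=seeds["jsd"])
            )
    jsd_matrices = normalize_jsd(jsd_matrices, scope=config.get("scope", "global"))
    for m in jsd_matrices:
        for grid_name in ("raw", "boot_mean", "boot_sd", "adjusted", "normalized", "relative"):
            grid = getattr(m, grid_name)
            if grid is not None:
                write_table(grid, out / f"jsd/{m.label}.{grid_name}.tsv",
                            seed, index=True, index_label="stage")
    # similarity drivers for configured stage pairs (default: matched mid-stage)
    for (sp_a, sp_b), (qa, qb, pairs) in prepared.items():
        default_pair = [[qa.stages[len(qa.stages) // 2], qb.stages[len(qb.stages) // 2]]]
        for st_a, st_b in config.get("driver_stage_pairs", default_pair):
            p = stage_distribution(qa, [a for a, _ in pairs], st_a)
            q = stage_distribution(qb, [b for _, b in pairs], st_b)
            g = similarity_drivers(gene_wise_jsd(p, q))
            write_table(
                pd.DataFrame({"gene_a": [a for a, _ in pairs],
                              "gene_b": [b for _, b in pairs],
                              "gwjsd": g.values,
                              "driver": [a in set(g.drivers) for a, _ in pairs]}),
                out / f"jsd/{sp_a}__vs__{sp_b}.{st_a}_{st_b}.drivers.tsv", seed,
            )
    record("jsd", *(out / "jsd").iterdir())

    # -- enrich -----------------------------------------------------
    for species in species_names:
        for kind in ("tf", "phylostratum"):
            table = label_enrichment(assignments[species], annotation, label_kind=kind,
                                     correction=config.get("correction", "BH"))
            write_table(table, out / f"enrich/{species}.{kind}.tsv", seed)
    record("enrich", *(out / "enrich").iterdir())

    manifest["outputs"] = sorted(manifest["outputs"])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
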