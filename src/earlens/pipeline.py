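"""End-to-end orchestration: simulate -> preprocess -> every analysis stage.

``run_all`` drives the whole pipeline from a single YAML config (or config
dict), writes each stage's outputs under an output directory and finishes
with a run manifest (config snapshot, seed, stage timings, sha256 digests
of every output).  A single global seed is fanned out to stages by fixed
offsets so each stage is independently re-runnable; identical config+seed
reproduce every numeric output bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import GeneSet, SyntheticTruth, write_bed, write_expression, write_fasta, write_gmt, write_network
from .simulate import SimulationConfig, generate_dataset, generate_twirler
from .preprocess import collapse_probes, condition_means, filter_detected, log2_transform, quantile_normalize
from .signatures import define_markers, hierarchical_samples, kmeans_genes, standardize_rows, two_way_anova
from .mirna import activity_table, relative_levels
from .motifs import discover, find_sites
from .enrich import genotype_contrast, rank_set_test, zeb1_target_candidates
from .netmod import find_modules, similarity_matrix
from .loci import prioritize

log = logging.getLogger("earlens")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def simulation_config(cfg: dict, seed: int | None = None) -> SimulationConfig:
    sim = dict(cfg.get("simulate", {}))
    sim.pop("enabled", None)
    if seed is not None:
        sim["seed"] = seed
    known = {f.name for f in fields(SimulationConfig)}
    unknown = set(sim) - known
    if unknown:
        raise ValueError(f"unknown simulate config keys: {sorted(unknown)}")
    return SimulationConfig(**sim)


def run_all(config: str | Path | dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run the full pipeline; returns (and writes) the run manifest."""
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg, "version": __version__, "stages": {}, "outputs": {}}
    t_start = time.time()
    stage_name = "init"

    def stage(name):
        nonlocal stage_name
        stage_name = name
        log.info("stage %s", name)
        return time.time()

    def done(name, t0, *paths: Path):
        manifest["stages"][name] = round(time.time() - t0, 3)
        for p in paths:
            manifest["outputs"][str(p.relative_to(out))] = _digest(p)

    try:
        # ---- simulate ----------------------------------------------------
        t0 = stage("simulate")
        sim_cfg = simulation_config(cfg, seed=seed)
        manifest["seed"] = sim_cfg.seed
        ds = generate_dataset(sim_cfg)
        paths = {
            "matrix": out / "expression.tsv",
            "sheet": out / "samples.tsv",
            "detection": out / "detection_p.tsv",
            "promoters": out / "promoters.fasta",
            "targets": out / "mirna_targets.gmt",
            "network": out / "ppi.tsv",
            "loci": out / "loci.bed",
            "genes": out / "genes.bed",
            "truth": out / "truth.json",
        }
        write_expression(ds.matrix, paths["matrix"], paths["sheet"], paths["detection"])
        write_fasta(ds.promoters.sequences, paths["promoters"])
        write_gmt(ds.mirna_targets, paths["targets"])
        write_network(ds.network, paths["network"])
        write_bed(ds.loci, paths["loci"])
        write_bed(ds.gene_locations, paths["genes"])
        twirler = generate_twirler(sim_cfg, ds.truth)
        write_expression(twirler, out / "twirler_expression.tsv", out / "twirler_samples.tsv")
        ds.truth.to_json(paths["truth"])
        done("simulate", t0, *paths.values(),
             out / "twirler_expression.tsv", out / "twirler_samples.tsv")

        # ---- preprocess --------------------------------------------------
        t0 = stage("preprocess")
        filtered = filter_detected(ds.matrix)
        normalized = quantile_normalize(filtered)
        log2m = log2_transform(normalized)
        gene_level = collapse_probes(log2m)
        gene_linear = collapse_probes(normalized)
        profile = condition_means(gene_level)
        p = out / "gene_log2.tsv"
        gene_level.values.to_csv(p, sep="\t", float_format="%.6g")
        done("preprocess", t0, p)

        # ---- differential expression + clustering ------------------------
        t0 = stage("diffexp")
        anova = two_way_anova(gene_level)
        p = out / "anova.tsv"
        anova.table.to_csv(p, sep="\t", float_format="%.6g")
        done("diffexp", t0, p)

        t0 = stage("cluster")
        dendro = hierarchical_samples(gene_level)
        diff_profile = profile.means.loc[[g for g in anova.differential_genes
                                          if g in profile.means.index]]
        from .io import ConditionProfile
        std = standardize_rows(ConditionProfile(means=diff_profile))
        k = int(cfg.get("cluster", {}).get("k", 8))
        clusters = kmeans_genes(std, k=k, seed=sim_cfg.seed + 1,
                                restarts=int(cfg.get("cluster", {}).get("restarts", 20)))
        p1, p2 = out / "clusters.tsv", out / "cluster_patterns.json"
        clusters.assignments.to_csv(p1, sep="\t")
        p2.write_text(json.dumps({
            "k": clusters.k, "inertia": clusters.inertia,
            "patterns": {str(c): clusters.patterns.loc[c].tolist()
                         for c in clusters.patterns.index},
            "dendrogram_4cut": dendro.cut(4),
        }, indent=1))
        done("cluster", t0, p1, p2)

        # ---- markers -----------------------------------------------------
        t0 = stage("markers")
        markers = define_markers(gene_linear,
                                 ratio=float(cfg.get("markers", {}).get("ratio", 1.5)))
        p = out / "markers.tsv"
        markers.table.dropna(subset=["cell_type"]).to_csv(p, sep="\t", float_format="%.6g")
        marker_sets = markers.as_dict()
        done("markers", t0, p)

        # ---- miRNA activity ----------------------------------------------
        t0 = stage("mirna")
        rel = relative_levels(profile)
        expressed_targets = ds.mirna_targets.restricted_to(profile.gene_ids)
        activity = activity_table(rel, expressed_targets)
        p = out / "mirna_activity.tsv"
        activity.summary().to_csv(p, sep="\t", index=False, float_format="%.6g")
        done("mirna", t0, p)

        # ---- motif discovery ---------------------------------------------
        t0 = stage("motifs")
        from .io import GeneSetCollection
        marker_coll = GeneSetCollection(
            [GeneSet(ct, f"{ct} markers", tuple(sorted(genes)))
             for ct, genes in marker_sets.items()],
            universe=profile.gene_ids,
        )
        expressed_promoters = ds.promoters.subset(profile.gene_ids)
        k_range = tuple(cfg.get("motifs", {}).get("k_range", [8]))
        motif_results = discover(marker_coll, expressed_promoters, k_range=k_range,
                                 alpha=float(cfg.get("motifs", {}).get("alpha", 1e-4)))
        p = out / "motifs.meme"
        blocks = ["MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n"]
        motif_rows = []
        for set_name, motifs in motif_results.items():
            for mi, mr in enumerate(motifs):
                if mr.pwm is not None:
                    blocks.append(mr.to_meme(name=f"{set_name}_{mi + 1}_{mr.seed.kmer}"))
                motif_rows.append({"set": set_name, "kmer": mr.seed.kmer,
                                   "p_hyper": mr.seed.p_hyper,
                                   "p_corrected": mr.seed.p_corrected,
                                   "significant": mr.significant})
        p.write_text("\n".join(blocks))
        p2 = out / "motifs.tsv"
        pd.DataFrame(motif_rows).to_csv(p2, sep="\t", index=False, float_format="%.6g")
        done("motifs", t0, p, p2)

        # ---- network modules ----------------------------------------------
        t0 = stage("modules")
        sim_mat = similarity_matrix(profile, genes=sorted(ds.network.nodes))
        modules = find_modules(ds.network, sim_mat,
                               seed_threshold=float(cfg.get("modules", {}).get("seed_threshold", 0.8)))
        p = out / "modules.json"
        p.write_text(json.dumps([
            {"front": m.front, "back": m.back, "score": m.score}
            for m in modules
        ], indent=1))
        done("modules", t0, p)

        # ---- loci candidates ----------------------------------------------
        t0 = stage("loci")
        expressed = set(profile.gene_ids)
        reports = []
        for locus in ds.loci:
            expected_ct = ds.truth.planted_locus_causal.get(locus.name, (None, None))[1]
            rep = prioritize(locus, ds.gene_locations, expressed, markers,
                             modules=modules, expected_cell_type=expected_ct)
            reports.append({"locus": rep.locus, "n_genes": len(rep.genes_in_locus),
                            "n_expressed": len(rep.expressed),
                            "top": rep.top(3)})
        p = out / "loci_candidates.json"
        p.write_text(json.dumps(reports, indent=1))
        done("loci", t0, p)

        # ---- Twirler contrast ----------------------------------------------
        t0 = stage("twirler")
        mut = twirler.subset_samples(["Tw_hom_cochlea_CD326neg", "Tw_hom_vestibule_CD326neg"])
        ctl = twirler.subset_samples(["wt_cochlea_CD326neg", "wt_vestibule_CD326neg"])
        fc = genotype_contrast(mut, ctl)
        epi = GeneSet("epithelial", "sensory markers",
                      tuple(sorted(ds.truth.planted_markers.get("sensory", set()))))
        res = rank_set_test(fc, epi)
        motif_hit_genes = {g for g, _, _ in find_sites(ds.truth.planted_motif, ds.promoters)}
        candidates = zeb1_target_candidates(fc, epi, motif_hit_genes)
        p = out / "twirler.json"
        p.write_text(json.dumps({
            "epithelial_p": res.p, "epithelial_direction": res.direction,
            "n_markers": res.n_markers,
            "candidates": candidates["gene"].tolist(),
        }, indent=1))
        done("twirler", t0, p)
    except Exception as e:
        manifest["failed_stage"] = stage_name
        manifest["error"] = str(e)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage_name!r}: {e}") from e

    manifest["total_seconds"] = round(time.time() - t_start, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
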