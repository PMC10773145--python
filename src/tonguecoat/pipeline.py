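"""End-to-end pipeline: simulate -> reduce -> annotate -> quantify -> stats -> model.

The pipeline is a pure function of (config, seed): every stage derives its
own seed from the global one by a fixed stage-name hash, writes its outputs
under the output directory, and records a manifest of output hashes so two
runs with the same config can be compared byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import database, simulate, stats
from .model import ModelConfig, embedding_diagnostics, rank_features, split_cohort, train_and_evaluate
from .peptides import annotate_peptides, build_peptide_index
from .quantify import QuantTable, aggregate, cohort_overlap_report, host_microbe_ratio, qc_filter
from .simulate import GeneratorConfig

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "reduce_db", "annotate", "quantify", "stats", "model")


@dataclass
class PipelineConfig:
    """Everything a full synthetic run needs, with study-scale defaults.

    QC thresholds default to values proportionate to the synthetic
    database size (the full-scale survey thresholds are 800 human / 2000
    microbial identified proteins; the generator's default database is
    about a tenth of that scale).
    """

    outdir: str = "tonguecoat_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    qc_min_human: int = 60
    qc_min_microbial: int = 600
    q_cutoff: float = 0.01
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    adjust: str = "none"
    max_missed: int = 2
    broad_mode: str = "lca"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        model = ModelConfig(**raw.pop("model", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(generator=gen, model=model, **raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: fixed derivation from the stage name, < 2**31."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "config": _config_dict(config)}
    state: dict = {}

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        runner = _STAGE_RUNNERS[stage]
        missing = [dep for dep in _STAGE_DEPS[stage] if dep not in state.get("done", set())]
        if missing:
            raise RuntimeError(
                f"stage {stage!r} requires stage(s) {missing} which did not run"
            )
        outputs = runner(config, outdir, state)
        state.setdefault("done", set()).add(stage)
        manifest["stages"][stage] = {
            "seed": stage_seed(config.seed, stage),
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": {name: _sha256(outdir / name) for name in outputs},
        }
        logger.info("stage %s finished in %.2fs", stage, manifest["stages"][stage]["seconds"])

    _write_json(
        {k: manifest[k] for k in ("seed", "stages", "config")}, outdir / "manifest.json"
    )
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["stages"] = list(config.stages)
    return d


# --- stages ------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, outdir: Path, state: dict) -> list[str]:
    seed = stage_seed(config.seed, "simulate")
    gen = GeneratorConfig(**{**asdict(config.generator), "seed": seed})
    reference = simulate.generate_reference(gen)
    reference.write_fasta(outdir / "microbial.fasta", outdir / "human.fasta")
    reference.write_taxonomy(outdir / "taxonomy.tsv")
    reference.write_annotations(outdir / "annotations.tsv")

    outputs = ["microbial.fasta", "human.fasta", "taxonomy.tsv", "annotations.tsv"]
    cohorts = {}
    truths = {}
    for design in simulate.COHORT_DESIGNS:
        meta = simulate.generate_cohort(design, seed)
        sim = simulate.simulate_intensities(
            reference, meta, gen, emit_peptides=(design != "time_series")
        )
        meta.write_tsv(outdir / f"{design}.metadata.tsv")
        sim.protein_table.write_wide(outdir / f"{design}.proteins.tsv")
        outputs += [f"{design}.metadata.tsv", f"{design}.proteins.tsv"]
        if sim.peptide_table is not None:
            sim.peptide_table.write_wide(outdir / f"{design}.peptides.tsv")
            outputs.append(f"{design}.peptides.tsv")
        cohorts[design] = (meta, sim)
        truths[design] = sim.truth
    psms, truly_sampled = simulate.emit_psm_table(reference, seed)
    psms.to_csv(outdir / "psms.tsv", sep="\t", index=False)
    _write_json(
        {"cohorts": truths, "psm_truly_sampled": sorted(truly_sampled)},
        outdir / "truth.json",
    )
    outputs += ["psms.tsv", "truth.json"]
    state.update(reference=reference, cohorts=cohorts, psms=psms, truly_sampled=truly_sampled)
    return outputs


def _stage_reduce_db(config: PipelineConfig, outdir: Path, state: dict) -> list[str]:
    psms = state["psms"]
    combined_source = outdir / "combined_source.fasta"
    # first-pass search database = microbial + host
    ref = state["reference"]
    with open(combined_source, "w") as fh:
        for p in ref.proteins:
            fh.write(f">{p.fasta_header()}\n{p.sequence}\n")
    per_run = [
        database.simplify_database(psms[psms["run"] == run], combined_source, config.q_cutoff)
        for run in sorted(psms["run"].unique())
    ]
    merged = database.merge_databases(per_run, outdir / "human.fasta")
    database.write_fasta(merged, outdir / "combined.fasta")
    state["combined_records"] = merged
    return ["combined_source.fasta", "combined.fasta"]


def _stage_annotate(config: PipelineConfig, outdir: Path, state: dict) -> list[str]:
    ref = state["reference"]
    index = build_peptide_index(
        [(outdir / "human.fasta", "human"), (outdir / "microbial.fasta", "microbial")],
        max_missed=config.max_missed,
    )
    _, sim = state["cohorts"]["zjc_like"]
    peptides = sorted({f.split(":", 1)[1] for f in sim.peptide_table.features})
    assigned = annotate_peptides(peptides, index, ref.tree, broad_mode=config.broad_mode)
    rows = []
    for pep, taxon in assigned.items():
        if taxon is None:
            rows.append((pep, "unassigned", "", "", ""))
        else:
            rows.append(
                (
                    pep,
                    "microbial",
                    taxon,
                    ref.tree.rank_of(taxon),
                    ref.tree.lineage_names(taxon),
                )
            )
    pd.DataFrame(rows, columns=["peptide", "origin", "taxon_id", "rank", "lineage"]).to_csv(
        outdir / "peptide_annotation.tsv", sep="\t", index=False
    )
    state["peptide_index"] = index
    return ["peptide_annotation.tsv"]


def _stage_quantify(config: PipelineConfig, outdir: Path, state: dict) -> list[str]:
    report: dict = {}
    kept_tables: dict = {}
    for design, (meta, sim) in state["cohorts"].items():
        kept, qc = qc_filter(sim.protein_table, config.qc_min_human, config.qc_min_microbial)
        qc.to_csv(outdir / f"{design}.qc.tsv", sep="\t", index_label="sample")
        table = sim.protein_table.subset_samples(kept)
        ratios = {s: host_microbe_ratio(table, s) for s in kept}
        report[design] = {
            "n_samples": len(sim.protein_table.samples),
            "n_kept": len(kept),
            "host_microbe_ratio_mean": float(np.mean(list(ratios.values()))),
        }
        kept_tables[design] = (meta.subset(kept), table)
    zjc = kept_tables["zjc_like"][1]
    mc = kept_tables["multicenter_like"][1]
    ident_z = set(zjc.values.index[zjc.identified().any(axis=1)])
    ident_m = set(mc.values.index[mc.identified().any(axis=1)])
    report["overlap_proteins_zjc_vs_multicenter"] = cohort_overlap_report(ident_z, ident_m)
    _write_json(report, outdir / "quantify_report.json")
    state["kept"] = kept_tables
    return [f"{d}.qc.tsv" for d in state["cohorts"]] + ["quantify_report.json"]


def _stage_stats(config: PipelineConfig, outdir: Path, state: dict) -> list[str]:
    ref = state["reference"]
    outputs = []
    # stability on the time-series cohort
    meta_ts, table_ts = state["kept"]["time_series"]
    origin = table_ts.annotations["origin"]
    frames = []
    for layer, sel in (("human_protein", origin == "human"), ("microbial_protein", origin == "microbial")):
        sub = table_ts.subset_features(table_ts.values.index[sel])
        frames.append(stats.stability_summary(sub, meta_ts, layer))
    phylum_table, _ = aggregate(table_ts, "phylum", ref.tree)
    frames.append(stats.stability_summary(phylum_table, meta_ts, "phylum"))
    cog_table, _ = aggregate(table_ts, "cog")
    frames.append(stats.stability_summary(cog_table, meta_ts, "cog"))
    frames = [f for f in frames if not f.empty]  # degenerate layers drop out
    pd.concat(frames, ignore_index=True).to_csv(outdir / "stability.tsv", sep="\t", index=False)
    outputs.append("stability.tsv")

    # differential proteins + COG enrichment + species risk on the ZJC-like cohort
    meta_z, table_z = state["kept"]["zjc_like"]
    deps = stats.differential_proteins(
        table_z, meta_z, config.lfc_threshold, config.alpha, config.adjust
    )
    deps.to_csv(outdir / "differential_proteins.tsv", sep="\t", index_label="feature")
    outputs.append("differential_proteins.tsv")

    cog_map = table_z.annotations["cog_id"].dropna().to_dict()
    background = set(cog_map)
    foreground = set(deps.index[deps["significant"]]) & background
    if foreground:
        enr = stats.fisher_enrichment(foreground, background, cog_map, config.alpha)
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index_label="category")
        outputs.append("enrichment.tsv")

    species_table, _ = aggregate(table_z, "species", ref.tree)
    risk = stats.species_risk(species_table, meta_z)
    risk.to_csv(outdir / "species_risk.tsv", sep="\t", index_label="taxon")
    outputs.append("species_risk.tsv")
    return outputs


def _stage_model(config: PipelineConfig, outdir: Path, state: dict) -> list[str]:
    seed = stage_seed(config.seed, "model")
    mc = ModelConfig(**{**asdict(config.model), "seed": seed})
    meta_z, table_z = state["kept"]["zjc_like"]
    meta_m, table_m = state["kept"]["multicenter_like"]
    origin = table_z.annotations["origin"]
    microbial = list(table_z.values.index[origin == "microbial"])
    table_z = table_z.subset_features(microbial)
    table_m = table_m.subset_features(microbial)

    train_ids, test_ids = split_cohort(meta_z, mc.train_fraction, seed)
    train_table = table_z.subset_samples(train_ids)
    ranking = rank_features(train_table, meta_z.subset(train_ids), mc)
    top = list(ranking.index[: mc.top_k])
    ranking.head(mc.top_k).to_csv(outdir / "feature_ranking.tsv", sep="\t", index_label="feature")

    est, reports = train_and_evaluate(
        train_table,
        meta_z.subset(train_ids),
        top,
        {
            "train": (train_table, meta_z.subset(train_ids)),
            "test": (table_z.subset_samples(test_ids), meta_z.subset(test_ids)),
            "multicenter": (table_m, meta_m),
        },
        mc,
    )
    _write_json(
        {name: rep.to_dict() for name, rep in reports.items()}, outdir / "evaluation.json"
    )

    coords, dist, group_dist = embedding_diagnostics(
        table_z.subset_features(top), meta_z, seed=seed
    )
    coords.to_csv(outdir / "tsne.tsv", sep="\t", index_label="sample")
    _write_json(group_dist, outdir / "group_distances.json")
    state["evaluation"] = reports
    return ["feature_ranking.tsv", "evaluation.json", "tsne.tsv", "group_distances.json"]


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "reduce_db": _stage_reduce_db,
    "annotate": _stage_annotate,
    "quantify": _stage_quantify,
    "stats": _stage_stats,
    "model": _stage_model,
}

_STAGE_DEPS = {
    "simulate": [],
    "reduce_db": ["simulate"],
    "annotate": ["simulate"],
    "quantify": ["simulate"],
    "stats": ["quantify"],
    "model": ["quantify"],
}
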