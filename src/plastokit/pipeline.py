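"""End-to-end orchestration: simulate -> partition -> junctions -> census
-> variants -> codons -> kaks -> phylogeny, driven by one configuration.

Every stage writes a TSV (or Newick) artifact into the output directory,
and a run log captures versions, seeds and the parameter echo so a run
is reproducible from the log alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .census import census_table, gain_loss, intron_table
from .codon import cluster_usage, genome_usage, usage_long_table
from .io import load_plastome, write_plastome, write_tables
from .junctions import ir_extensions, junction_genes
from .kaks import kaks_scan
from .model import Plastome, PlastomeError, RegionPartition
from .phylo import bootstrap, build_supermatrix, shared_genes, write_newick
from .quadripartite import detect_inverted_repeats, normalize, summary_table
from .simulate import CohortConfig, default_cohort_config, generate_cohort
from .variants import call_variants, pairwise_align, variant_summary

log = logging.getLogger("plastokit")


@dataclass
class PipelineConfig:
    outdir: Path = Path("plastokit_out")
    seed: int = 0
    simulate: Optional[CohortConfig] = None
    genomes: list[tuple[Path, Path]] = field(default_factory=list)  # (fasta, gff3)
    reference: Optional[str] = None  # default: first genome
    min_ir_len: int = 1000
    min_indel_len: int = 5
    min_cds_len: int = 300
    bootstrap_reps: int = 100
    distance_model: str = "poisson"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        for name, value in (
            ("min_ir_len", self.min_ir_len),
            ("min_indel_len", self.min_indel_len),
            ("min_cds_len", self.min_cds_len),
            ("bootstrap_reps", self.bootstrap_reps),
        ):
            if value <= 0:
                raise PlastomeError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        genomes = [
            (Path(g["fasta"]), Path(g["gff3"])) for g in raw.pop("genomes", [])
        ]
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__},
                  genomes=genomes)
        if sim is not None:
            if sim is True or sim == "default":
                cfg.simulate = default_cohort_config(cfg.seed)
            else:
                cfg.simulate = CohortConfig(**sim)
        return cfg


def _load_cohort(config: PipelineConfig):
    manifests = []
    if config.simulate is not None:
        cohort, manifests = generate_cohort(config.simulate)
    elif config.genomes:
        cohort = [load_plastome(f, g) for f, g in config.genomes]
    else:
        raise PlastomeError("config provides neither a simulation block nor genomes")
    if config.reference:
        names = [g.name for g in cohort]
        if config.reference not in names:
            raise PlastomeError(f"reference {config.reference!r} not in cohort")
        i = names.index(config.reference)
        cohort = [cohort[i]] + cohort[:i] + cohort[i + 1 :]
    return cohort, manifests


def run_all(config: PipelineConfig) -> dict[str, str]:
    """Execute every stage; returns a manifest of output files."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def emit(key: str, df: pd.DataFrame, filename: str) -> None:
        path = out / filename
        write_tables(df, path)
        artifacts[key] = str(path)

    stage = "simulate/load"
    try:
        cohort, manifests = _load_cohort(config)
        if config.simulate is not None:
            for g in cohort:
                write_plastome(g, out / f"{g.name}.fasta", out / f"{g.name}.gff3")
            if manifests:
                truth = pd.concat([m.variants for m in manifests], ignore_index=True)
                emit("truth_manifest", truth, "truth_manifest.tsv")

        stage = "partition"
        normalized = []
        for g in cohort:
            part = detect_inverted_repeats(g.sequence, min_ir_len=config.min_ir_len)
            if part.lsc[0] % len(g) == 0:
                # already in LSC-first coordinates: keep them (the truth
                # manifest of a simulated cohort lives in these coordinates)
                g.partition = RegionPartition.from_lengths(
                    part.lsc_len, part.ir_len, part.ssc_len
                )
                normalized.append(g)
            else:
                normalized.append(normalize(g, part))
        cohort = normalized
        emit("region_summary", summary_table(cohort), "region_summary.tsv")

        stage = "junctions"
        jn = pd.concat(
            [
                junction_genes(g).table.assign(genome=g.name)
                for g in cohort
            ],
            ignore_index=True,
        )
        emit("junctions", jn, "junctions.tsv")
        ext = pd.concat(
            [
                ir_extensions(junction_genes(g)).assign(genome=g.name)
                for g in cohort
            ],
            ignore_index=True,
        )
        emit("ir_extensions", ext, "ir_extensions.tsv")

        stage = "census"
        emit("gene_census", census_table(cohort), "gene_census.tsv")
        emit("intron_table", intron_table(cohort), "intron_table.tsv")
        emit("gain_loss", gain_loss(cohort).as_table(), "gain_loss.tsv")

        stage = "variants"
        ref = cohort[0]
        var_frames = []
        small_counts = {}
        for alt in cohort[1:]:
            aln = pairwise_align(ref.sequence, alt.sequence)
            aln.ids = [ref.name, alt.name]
            table = call_variants(aln, 0, ref, min_indel_len=config.min_indel_len)
            var_frames.append(table.variants)
            small_counts[alt.name] = table.small_indel_count
        variants = pd.concat(var_frames, ignore_index=True)
        emit("variants", variants, "variants.tsv")
        from .variants import VariantTable

        summary = variant_summary(VariantTable(variants=variants))
        emit(
            "variant_summary",
            summary["by_type_region"],
            "variant_summary.tsv",
        )

        stage = "codons"
        usage = [genome_usage(g, min_len=config.min_cds_len) for g in cohort]
        emit("codon_usage", usage_long_table(usage), "codon_usage.tsv")
        clustering = cluster_usage(usage)
        gc3 = pd.DataFrame(
            [
                dict(genome=t.name, gc3=t.gc3, total_codons=t.total_codons)
                for t in usage
            ]
        )
        emit("codon_summary", gc3, "codon_summary.tsv")
        (out / "codon_clustering.txt").write_text(
            "leaf order: " + ", ".join(clustering.leaf_order) + "\n"
        )
        artifacts["codon_clustering"] = str(out / "codon_clustering.txt")

        stage = "kaks"
        kaks = pd.concat(
            [kaks_scan(ref, alt) for alt in cohort[1:]], ignore_index=True
        )
        emit("kaks", kaks, "kaks.tsv")

        stage = "phylogeny"
        genes = shared_genes(cohort)
        matrix = build_supermatrix(cohort, genes)
        tree = bootstrap(
            matrix,
            reps=config.bootstrap_reps,
            seed=config.seed,
            model=config.distance_model,
        )
        tree_path = out / "nj_tree.nwk"
        write_newick(tree, tree_path)
        artifacts["nj_tree"] = str(tree_path)
        pd.DataFrame({"gene": genes}).to_csv(
            out / "shared_genes.tsv", sep="\t", index=False
        )
        artifacts["shared_genes"] = str(out / "shared_genes.tsv")
    except Exception as exc:
        raise PlastomeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage_log = dict(
        version=__version__,
        seed=config.seed,
        parameters=dict(
            min_ir_len=config.min_ir_len,
            min_indel_len=config.min_indel_len,
            min_cds_len=config.min_cds_len,
            bootstrap_reps=config.bootstrap_reps,
            distance_model=config.distance_model,
            simulated=config.simulate is not None,
        ),
        small_indel_counts=small_counts,
        artifacts=sorted(artifacts),
    )
    (out / "run_log.json").write_text(json.dumps(stage_log, indent=2) + "\n")
    artifacts["run_log"] = str(out / "run_log.json")
    return artifacts
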