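"""Gene complements: category counts, intron statistics and cross-genome
gain-loss (copy-number) matrices.

Gene identity for gain-loss is the exact gene name, case-insensitive;
tRNA isoacceptors with different anticodons stay distinct.  Pseudogenes
count toward the total gene number (the category breakdown is reported
alongside, so nothing is hidden by that convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import CATEGORIES, Plastome, PlastomeError
from .quadripartite import _majority_region


@dataclass(frozen=True)
class GeneCensus:
    name: str
    counts: dict[str, int]
    total: int
    ir_gene_count: int | None
    introns: pd.DataFrame  # gene, copy_tag, strand, n_introns, intron_lengths

    def as_row(self) -> dict:
        row = {"name": self.name, "total": self.total}
        row.update(self.counts)
        row["ir_genes"] = self.ir_gene_count
        row["intron_genes"] = int((self.introns["n_introns"] > 0).sum())
        return row


def census(plastome: Plastome) -> GeneCensus:
    """Category counts (IR duplicates counted individually) and per-gene
    intron statistics; intron count per gene = exons - 1."""
    counts = plastome.annotations.category_counts()
    total = len(plastome.annotations)
    if total != sum(counts.values()):
        raise PlastomeError("category counts do not sum to the feature count")
    ir_count = None
    if plastome.partition is not None:
        ir_count = sum(
            1
            for f in plastome.annotations
            if _majority_region(f, plastome.partition) in ("IRb", "IRa")
        )
    introns = pd.DataFrame(
        [
            dict(
                gene=f.gene_name,
                copy_tag=f.copy_tag,
                strand=f.strand,
                category=f.category,
                n_introns=len(f.exons) - 1,
                intron_lengths=",".join(str(x) for x in f.intron_lengths),
            )
            for f in plastome.annotations
        ],
        columns=["gene", "copy_tag", "strand", "category", "n_introns",
                 "intron_lengths"],
    )
    return GeneCensus(
        name=plastome.name, counts=counts, total=total,
        ir_gene_count=ir_count, introns=introns,
    )


def census_table(cohort: list[Plastome]) -> pd.DataFrame:
    return pd.DataFrame([census(p).as_row() for p in cohort])


def intron_table(cohort: list[Plastome]) -> pd.DataFrame:
    """Intron presence/length per (gene, strand) across the cohort.

    Cells hold the comma-joined intron lengths of the intron-bearing copy
    (empty string when the genome's copies are intron-free or the gene is
    absent).  The final row counts intron-bearing gene entries per genome.
    """
    if not cohort:
        raise PlastomeError("intron_table needs at least one genome")
    keys: list[tuple[str, str]] = []
    for g in cohort:
        for f in g.annotations:
            if len(f.exons) > 1 and (f.gene_name, f.strand) not in keys:
                keys.append((f.gene_name, f.strand))
    rows = []
    for gene, strand in sorted(keys):
        row: dict = {"gene": gene, "strand": strand}
        for g in cohort:
            best = ""
            for f in g.annotations:
                if (f.gene_name.lower(), f.strand) == (gene.lower(), strand):
                    if len(f.exons) > 1:
                        best = ",".join(str(x) for x in f.intron_lengths)
                        break
            row[g.name] = best
        rows.append(row)
    df = pd.DataFrame(rows, columns=["gene", "strand"] + [g.name for g in cohort])
    totals: dict = {"gene": "Total", "strand": ""}
    for g in cohort:
        totals[g.name] = str(
            sum(1 for f in g.annotations if len(f.exons) > 1)
        )
    return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)


@dataclass
class GainLossMatrix:
    """Gene-by-genome copy numbers with per-gene missing counts."""

    matrix: pd.DataFrame  # rows: gene names; columns: genome names
    missing_count: pd.Series

    def as_table(self) -> pd.DataFrame:
        out = self.matrix.copy()
        out["missing_count"] = self.missing_count
        return out.reset_index(names="gene")


def gain_loss(cohort: list[Plastome]) -> GainLossMatrix:
    """Copy-number matrix: cell = number of features carrying the gene
    name; missing_count = genomes with copy number zero."""
    if len(cohort) < 2:
        raise PlastomeError("gain_loss needs at least two genomes")
    names: dict[str, str] = {}  # lower -> display
    for g in cohort:
        for f in g.annotations:
            names.setdefault(f.gene_name.lower(), f.gene_name)
    rows = {}
    for low, display in sorted(names.items()):
        rows[display] = {
            g.name: sum(1 for f in g.annotations if f.gene_name.lower() == low)
            for g in cohort
        }
    matrix = pd.DataFrame.from_dict(rows, orient="index")[[g.name for g in cohort]]
    missing = (matrix == 0).sum(axis=1)
    if (missing > len(cohort)).any():
        raise PlastomeError("missing count exceeds genome count")
    return GainLossMatrix(matrix=matrix, missing_count=missing)
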