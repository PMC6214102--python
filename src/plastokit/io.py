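"""Reading and writing the standard formats the pipeline touches.

FASTA (one record per genome), GFF3 (1-based inclusive, converted to the
internal 0-based half-open convention at this boundary), aligned FASTA and
TSV tables.  GenBank flat files, BED and compressed archives are out of
scope.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Union

import gffutils
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    Alignment,
    AnnotationSet,
    GeneFeature,
    Plastome,
    PlastomeError,
)

PathLike = Union[str, os.PathLike]

# GFF3 child feature type -> internal category
_TYPE_TO_CATEGORY = {"CDS": "protein_coding", "tRNA": "tRNA", "rRNA": "rRNA"}
_CATEGORY_TO_TYPE = {v: k for k, v in _TYPE_TO_CATEGORY.items()}


def load_plastome(fasta_path: PathLike, gff3_path: PathLike) -> Plastome:
    """Load a single-record FASTA plus its GFF3 annotation.

    GFF3 coordinates (1-based inclusive) are converted to 0-based
    half-open.  Category is inferred from the child feature type
    (CDS -> protein_coding, tRNA, rRNA); a ``pseudo=true`` attribute on the
    gene marks a pseudogene.  A feature wrapping past the sequence end is
    split at the origin.
    """
    try:
        record = SeqIO.read(str(fasta_path), "fasta")
    except ValueError as exc:
        raise PlastomeError(f"{fasta_path}: {exc}") from exc
    seq = str(record.seq).upper()
    n = len(seq)

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[GeneFeature] = []
    copy_counter: dict[str, int] = {}
    for gene in db.features_of_type("gene", order_by="start"):
        if gene.seqid != record.id:
            raise PlastomeError(
                f"{gff3_path}: feature {gene.id} references sequence "
                f"{gene.seqid!r}, FASTA record is {record.id!r}"
            )
        name = gene.attributes.get("Name", [gene.id])[0]
        pseudo = gene.attributes.get("pseudo", ["false"])[0].lower() == "true"
        children = [
            c
            for c in db.children(gene, order_by="start")
            if c.featuretype in ("CDS", "tRNA", "rRNA", "exon")
        ]
        if children:
            exons = sorted({(c.start - 1, c.end) for c in children})
            child_types = {c.featuretype for c in children} - {"exon"}
        else:
            exons = [(gene.start - 1, gene.end)]
            child_types = set()
        if pseudo:
            category = "pseudogene"
        else:
            category = "protein_coding"
            for t in ("CDS", "tRNA", "rRNA"):
                if t in child_types:
                    category = _TYPE_TO_CATEGORY[t]
                    break
        if "copy_tag" in gene.attributes:
            copy_tag = int(gene.attributes["copy_tag"][0])
        else:
            copy_tag = copy_counter.get(name.lower(), 0)
            copy_counter[name.lower()] = copy_tag + 1
        for s, e in exons:
            if e > n:
                raise PlastomeError(
                    f"{gff3_path}: feature {name} interval ({s + 1}, {e}) exceeds "
                    f"sequence length {n}"
                )
        features.append(
            GeneFeature(
                gene_name=name,
                category=category,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=tuple(exons),
                copy_tag=copy_tag,
            )
        )
    return Plastome(name=record.id, sequence=seq, annotations=AnnotationSet(features))


def write_plastome(
    plastome: Plastome, fasta_path: PathLike, gff3_path: PathLike
) -> None:
    """Write a genome back out as single-record FASTA + GFF3."""
    record = SeqRecord(Seq(plastome.sequence), id=plastome.name, description="")
    SeqIO.write([record], str(fasta_path), "fasta")

    lines = ["##gff-version 3", f"##sequence-region {plastome.name} 1 {len(plastome)}"]
    for f in sorted(plastome.annotations, key=lambda f: (f.start, f.key)):
        gid = f"gene-{f.gene_name}-{f.copy_tag}"
        attrs = f"ID={gid};Name={f.gene_name};copy_tag={f.copy_tag}"
        if f.category == "pseudogene":
            attrs += ";pseudo=true"
        lines.append(
            "\t".join(
                [
                    plastome.name,
                    "plastokit",
                    "gene",
                    str(f.start + 1),
                    str(f.end),
                    ".",
                    f.strand,
                    ".",
                    attrs,
                ]
            )
        )
        child_type = _CATEGORY_TO_TYPE.get(f.category, "CDS")
        for i, (s, e) in enumerate(f.exons):
            lines.append(
                "\t".join(
                    [
                        plastome.name,
                        "plastokit",
                        child_type,
                        str(s + 1),
                        str(e),
                        ".",
                        f.strand,
                        "0" if child_type == "CDS" else ".",
                        f"ID={gid}.{child_type.lower()};Parent={gid}",
                    ]
                )
            )
    Path(gff3_path).write_text("\n".join(lines) + "\n")


def write_tables(result: pd.DataFrame, path: PathLike) -> None:
    """Write a tabular result as TSV with a header row.

    Floats are printed with 4 decimals, except percentage columns (names
    ending in ``_pct`` or ``(%)``) which use 2 decimals.
    """
    df = result.copy()
    for col in df.columns:
        if pd.api.types.is_float_dtype(df[col]):
            digits = 2 if str(col).endswith(("_pct", "(%)")) else 4
            df[col] = df[col].map(
                lambda x, d=digits: "" if pd.isna(x) else f"{x:.{d}f}"
            )
    df.to_csv(path, sep="\t", index=False)


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_alignment(path: PathLike) -> Alignment:
    """Load an aligned FASTA; rows must share one length, case folds up."""
    try:
        msa = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise PlastomeError(f"{path}: {exc}") from exc
    return Alignment(
        ids=[rec.id for rec in msa], seqs=[str(rec.seq).upper() for rec in msa]
    )


def write_alignment(alignment: Alignment, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(alignment.ids, alignment.seqs):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
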