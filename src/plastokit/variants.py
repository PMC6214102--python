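"""Substitution and indel scanning between genome pairs.

Variants are extracted from a pairwise (or multiple) alignment against a
reference genome: mismatched columns become SNPs, maximal gap runs become
insertions or deletions anchored at the last reference base before the
event (VCF-like, left-aligned).  Indels shorter than the screening
threshold (5 bp by default) are excluded from the indel table but counted
separately.  Each retained event is classified by region (from the
reference partition) and genic context.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._pairwise import AlignmentError, align_dna, anchored_align_dna
from .model import Alignment, Plastome, PlastomeError

VARIANT_COLUMNS = [
    "sample", "type", "ref_position", "length", "ref_allele", "alt_allele",
    "region", "context", "flank_left", "flank_right",
]


def classify_position(plastome: Plastome, pos: int) -> tuple[str, str, str]:
    """(context, flank_left, flank_right) for a reference position.

    genic = overlapping any exon; intronic = inside a gene span but only in
    introns; otherwise intergenic, with the nearest gene on each side named
    (circular at the ends).
    """
    feats = plastome.annotations.features
    in_span = []
    for f in feats:
        if f.start <= pos < f.end:
            in_span.append(f)
    for f in in_span:
        if any(s <= pos < e for s, e in f.exons):
            return "genic", f.gene_name, f.gene_name
    if in_span:
        f = in_span[0]
        return "intronic", f.gene_name, f.gene_name
    left = max(
        (f for f in feats if f.end <= pos),
        key=lambda f: f.end,
        default=max(feats, key=lambda f: f.end, default=None) if feats else None,
    )
    right = min(
        (f for f in feats if f.start > pos),
        key=lambda f: f.start,
        default=min(feats, key=lambda f: f.start, default=None) if feats else None,
    )
    return (
        "intergenic",
        left.gene_name if left else "",
        right.gene_name if right else "",
    )


def pairwise_align(ref: str, alt: str, band: int = 2000) -> Alignment:
    """Global affine alignment of two near-identical genomes.

    Scores: match +2, mismatch -3, gap open -5, gap extend -2 (a gap of
    length g costs open + g*extend), deterministic tie-breaking preferring
    match/mismatch over deletion over insertion.  Sequences whose lengths
    differ by more than ``band`` are rejected — supply an external
    alignment instead.  Long sequences are aligned via unique k-mer
    anchoring with full dynamic programming between anchors.
    """
    ref, alt = ref.upper(), alt.upper()
    if abs(len(ref) - len(alt)) > band:
        raise AlignmentError(
            f"length difference {abs(len(ref) - len(alt))} exceeds band {band}; "
            "supply an external alignment"
        )
    if max(len(ref), len(alt)) <= 4000:
        a, b, _ = align_dna(ref, alt)
    else:
        a, b = anchored_align_dna(ref, alt)
    return Alignment(ids=["ref", "alt"], seqs=[a, b])


def left_normalize(ref: str, start: int, length: int, kind: str,
                   inserted: str = "") -> tuple[int, str]:
    from .simulate import left_align_indel

    return left_align_indel(ref, start, length, kind, inserted)


@dataclass
class VariantTable:
    """Called variants plus the count of sub-threshold indels."""

    variants: pd.DataFrame
    small_indels: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=VARIANT_COLUMNS)
    )

    @property
    def small_indel_count(self) -> int:
        return len(self.small_indels)


def call_variants(
    alignment: Alignment,
    reference_index: int,
    plastome: Plastome,
    min_indel_len: int = 5,
) -> VariantTable:
    """Extract SNPs and indels from an alignment against the reference.

    The reference row (``reference_index``) must equal the plastome
    sequence once gaps are removed.  Maximal gap runs in a sample row are
    deletions; gap runs in the reference row are insertions, anchored at
    the preceding reference base and left-aligned.  Runs shorter than
    ``min_indel_len`` go to the small-indel side table.
    """
    ref_row = alignment.seqs[reference_index]
    ref = ref_row.replace("-", "")
    if ref != plastome.sequence:
        raise PlastomeError(
            "alignment reference row does not match the plastome sequence"
        )
    part = plastome.partition

    def annotate(pos: int) -> tuple[str, str, str, str]:
        region = part.region_of(pos) if part is not None else ""
        ctx, fl, fr = classify_position(plastome, pos)
        return region, ctx, fl, fr

    kept_rows = []
    small_rows = []
    for row_i, (sample, row) in enumerate(zip(alignment.ids, alignment.seqs)):
        if row_i == reference_index:
            continue
        ref_pos = 0
        col = 0
        width = alignment.width
        while col < width:
            r, a = ref_row[col], row[col]
            if r != "-" and a != "-":
                if r != a and r != "N" and a != "N":
                    region, ctx, fl, fr = annotate(ref_pos)
                    kept_rows.append(
                        dict(sample=sample, type="SNP", ref_position=ref_pos,
                             length=1, ref_allele=r, alt_allele=a, region=region,
                             context=ctx, flank_left=fl, flank_right=fr)
                    )
                ref_pos += 1
                col += 1
                continue
            if a == "-" and r != "-":
                start = ref_pos
                run = 0
                while col < width and row[col] == "-" and ref_row[col] != "-":
                    run += 1
                    ref_pos += 1
                    col += 1
                anchor, allele = left_normalize(ref, start, run, "del")
                site = anchor + 1
                region, ctx, fl, fr = annotate(site)
                rec = dict(sample=sample, type="deletion", ref_position=anchor,
                           length=run, ref_allele=allele, alt_allele="",
                           region=region, context=ctx, flank_left=fl,
                           flank_right=fr)
                (kept_rows if run >= min_indel_len else small_rows).append(rec)
                continue
            if r == "-" and a != "-":
                inserted = []
                while col < width and ref_row[col] == "-":
                    if row[col] != "-":
                        inserted.append(row[col])
                    col += 1
                run = len(inserted)
                if run:
                    anchor, allele = left_normalize(
                        ref, ref_pos, run, "ins", "".join(inserted)
                    )
                    site = max(anchor, 0)
                    region, ctx, fl, fr = annotate(site)
                    rec = dict(sample=sample, type="insertion",
                               ref_position=anchor, length=run, ref_allele="",
                               alt_allele=allele, region=region, context=ctx,
                               flank_left=fl, flank_right=fr)
                    (kept_rows if run >= min_indel_len else small_rows).append(rec)
                continue
            # both gaps: skip the column
            col += 1

    def frame(rows: list[dict]) -> pd.DataFrame:
        df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
        return df.sort_values(
            ["sample", "ref_position", "type"], kind="stable"
        ).reset_index(drop=True)

    return VariantTable(variants=frame(kept_rows), small_indels=frame(small_rows))


def variant_summary(table: VariantTable) -> dict[str, pd.DataFrame]:
    """Marginal counts by type, region, context and per-sample totals."""
    df = table.variants
    out: dict[str, pd.DataFrame] = {}
    if df.empty:
        empty = pd.DataFrame(columns=["count"])
        return {
            "by_type": empty, "by_region": empty, "by_context": empty,
            "by_sample": empty,
            "by_type_region": pd.DataFrame(columns=["type", "region", "count"]),
        }
    out["by_type"] = df.groupby("type").size().to_frame("count")
    out["by_region"] = df.groupby("region").size().to_frame("count")
    out["by_context"] = df.groupby("context").size().to_frame("count")
    out["by_sample"] = df.groupby("sample").size().to_frame("count")
    out["by_type_region"] = (
        df.groupby(["type", "region"]).size().to_frame("count").reset_index()
    )
    return out
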