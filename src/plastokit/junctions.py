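"""IR boundary (junction) analysis.

For each of the four region junctions (LSC/IRb, IRb/SSC, SSC/IRa,
IRa/LSC, in normalized order) this reports the genes that span the
boundary — with the number of bases on each side — and the genes lying
within a window of the boundary, with their distance to it.  Gene extent
is the full genomic span from first exon start to last exon end, introns
included: boundary expansion/contraction is a statement about gene
bodies, not exon structure.

The IRa/LSC junction coincides with the normalized origin; a gene split
at the origin on load (two features sharing a name, one ending at the
sequence end and one starting at 0) is re-joined circularly for
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import Plastome, PlastomeError

JUNCTION_COLUMNS = [
    "junction", "gene", "spans", "left_region", "right_region",
    "bases_left", "bases_right", "distance",
]


@dataclass
class JunctionReport:
    table: pd.DataFrame


def _gene_spans(plastome: Plastome) -> list[tuple[str, int, int]]:
    """(name, start, end) spans; origin-split gene halves re-joined, the
    joined span expressed with end > genome length."""
    n = len(plastome)
    feats = list(plastome.annotations)
    spans = [(f.gene_name, f.start, f.end, f.copy_tag) for f in feats]
    by_name: dict[str, list[tuple[int, int, int]]] = {}
    for name, s, e, tag in spans:
        by_name.setdefault(name.lower(), []).append((s, e, tag))
    out = []
    joined: set[tuple[str, int]] = set()
    for name, s, e, tag in spans:
        partners = by_name[name.lower()]
        if e == n:
            head = [p for p in partners if p[0] == 0 and p[1] < n]
            if head:
                hs, he, htag = head[0]
                out.append((name, s, n + he))
                joined.add((name.lower(), htag))
                continue
        out.append((name, s, e))
    return [
        (name, s, e)
        for (name, s, e) in out
        if not (s == 0 and (name.lower(), _tag_of(plastome, name, s)) in joined)
    ]


def _tag_of(plastome: Plastome, name: str, start: int) -> int:
    for f in plastome.annotations:
        if f.gene_name == name and f.start == start:
            return f.copy_tag
    return -1


def junction_genes(plastome: Plastome, window: int = 2000) -> JunctionReport:
    """Genes spanning or near each junction of a normalized plastome.

    A spanning gene is reported with the bases falling on each side
    (which sum to its genomic span); a gene within ``window`` of a
    junction but not spanning it is reported with its distance to the
    junction.  Distances are circular at the origin.
    """
    p = plastome.partition
    if p is None:
        raise PlastomeError(f"{plastome.name}: partition required")
    if not p.is_normalized:
        raise PlastomeError(f"{plastome.name}: normalize before junction analysis")
    n = len(plastome)
    region_pairs = {
        "LSC/IRb": ("LSC", "IRb"),
        "IRb/SSC": ("IRb", "SSC"),
        "SSC/IRa": ("SSC", "IRa"),
        "IRa/LSC": ("IRa", "LSC"),
    }
    rows = []
    for jname, jpos in p.junctions():
        left_r, right_r = region_pairs[jname]
        for gene, s, e in _gene_spans(plastome):
            # circular coordinates relative to the junction
            if s < jpos < e:
                rows.append(
                    dict(junction=jname, gene=gene, spans=True,
                         left_region=left_r, right_region=right_r,
                         bases_left=jpos - s, bases_right=e - jpos, distance=0)
                )
                continue
            # distance from the gene span to the junction on the circle
            d_after = (s - jpos) % n      # junction ... gene start
            d_before = (jpos - e) % n     # gene end ... junction
            d = min(d_after, d_before)
            if 0 <= d <= window:
                side = right_r if d_after <= d_before else left_r
                rows.append(
                    dict(junction=jname, gene=gene, spans=False,
                         left_region=side, right_region=side,
                         bases_left=0, bases_right=0, distance=int(d))
                )
    table = (
        pd.DataFrame(rows, columns=JUNCTION_COLUMNS)
        .sort_values(["junction", "distance", "gene"], kind="stable")
        .reset_index(drop=True)
    )
    return JunctionReport(table=table)


def ir_extensions(report: JunctionReport) -> pd.DataFrame:
    """Bases of each junction-spanning gene lying inside the repeat."""
    df = report.table
    spans = df[df["spans"]].copy()
    ir_side = []
    for r in spans.itertuples():
        if r.left_region in ("IRb", "IRa"):
            ir_side.append(r.bases_left)
        elif r.right_region in ("IRb", "IRa"):
            ir_side.append(r.bases_right)
        else:
            ir_side.append(0)
    spans["ir_bases"] = ir_side
    return spans[["junction", "gene", "ir_bases"]].reset_index(drop=True)
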