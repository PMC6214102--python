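"""Codon usage statistics from annotated CDS.

Counts, per-mille usage frequencies, relative synonymous codon usage
(RSCU) and third-position GC (GC3), with the full-length CDS screen
(< 300 nt excluded) applied before counting.  The plastid code is
translation table 11; the start codon is counted as its literal codon
and stop codons form their own family, excluded from RSCU.  Genomes are
clustered by their 64-dimensional usage profiles with average-linkage
hierarchical clustering on Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .model import Plastome, PlastomeError, splice

_BASES = "TCAG"
ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_STOPS = ("TAA", "TAG", "TGA")


def _codon_families() -> dict[str, list[str]]:
    """Synonymous families of the plastid (table 11) genetic code."""
    from Bio.Seq import Seq

    fams: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        aa = "*" if codon in _STOPS else str(Seq(codon).translate(table=11))
        fams.setdefault(aa, []).append(codon)
    return fams


FAMILIES = _codon_families()
_FAMILY_OF = {c: aa for aa, members in FAMILIES.items() for c in members}


@dataclass
class CDSRecord:
    gene_name: str
    sequence: str


@dataclass
class CDSExtraction:
    kept: list[CDSRecord]
    excluded: list[tuple[str, str]]  # (gene, reason)


def extract_cds(plastome: Plastome, min_len: int = 300) -> CDSExtraction:
    """Spliced coding sequences passing the quality screens.

    Exons are concatenated in strand order (reverse-complemented for
    minus-strand genes).  A CDS is excluded — with a logged reason — when
    shorter than ``min_len``, not a multiple of 3, containing an internal
    stop codon, or containing any N.
    """
    from Bio.Seq import Seq

    kept: list[CDSRecord] = []
    excluded: list[tuple[str, str]] = []
    for f in plastome.annotations:
        if f.category != "protein_coding":
            continue
        seq = splice(plastome.sequence, f)
        label = f"{f.gene_name}.{f.copy_tag}"
        if len(seq) < min_len:
            excluded.append((label, f"length {len(seq)} < {min_len}"))
            continue
        if len(seq) % 3:
            excluded.append((label, "length not a multiple of 3"))
            continue
        if "N" in seq:
            excluded.append((label, "contains N"))
            continue
        aa = str(Seq(seq).translate(table=11))
        if "*" in aa[:-1]:
            excluded.append((label, "internal stop codon"))
            continue
        kept.append(CDSRecord(gene_name=label, sequence=seq))
    return CDSExtraction(kept=kept, excluded=excluded)


@dataclass
class CodonUsageTable:
    """Per-codon counts, per-mille frequencies and RSCU for one genome."""

    name: str
    table: pd.DataFrame  # index: codon; columns: amino_acid, count, freq_permille, rscu
    gc3: float
    total_codons: int

    @property
    def frequency_vector(self) -> np.ndarray:
        return self.table["freq_permille"].to_numpy(dtype=float)

    @property
    def rscu_vector(self) -> np.ndarray:
        return self.table["rscu"].to_numpy(dtype=float)


def usage_table(cds_list: Iterable[CDSRecord], name: str = "") -> CodonUsageTable:
    """Codon counts over a CDS set.

    RSCU(c) = count(c) * family_size / family_total within each synonymous
    family (0 when the family is unused); stop codons are counted and
    reported but excluded from RSCU.  GC3 is the G+C fraction at third
    positions over all counted codons.
    """
    counts = {c: 0 for c in ALL_CODONS}
    total = 0
    gc3_hits = 0
    for rec in cds_list:
        seq = rec.sequence.upper()
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            if codon not in counts:
                continue  # codons containing N are not counted
            counts[codon] += 1
            total += 1
            if codon[2] in "GC":
                gc3_hits += 1
    if total == 0:
        raise PlastomeError("no codons to count")
    rows = []
    for codon in ALL_CODONS:
        aa = _FAMILY_OF[codon]
        family = FAMILIES[aa]
        fam_total = sum(counts[c] for c in family)
        if aa == "*" or fam_total == 0:
            rscu = 0.0
        else:
            rscu = counts[codon] * len(family) / fam_total
        rows.append(
            dict(codon=codon, amino_acid=aa, count=counts[codon],
                 freq_permille=1000 * counts[codon] / total, rscu=rscu)
        )
    table = pd.DataFrame(rows).set_index("codon")
    return CodonUsageTable(
        name=name, table=table, gc3=gc3_hits / total, total_codons=total
    )


def genome_usage(plastome: Plastome, min_len: int = 300) -> CodonUsageTable:
    extraction = extract_cds(plastome, min_len=min_len)
    return usage_table(extraction.kept, name=plastome.name)


@dataclass
class UsageClustering:
    names: list[str]          # input order (sorted)
    linkage: np.ndarray       # scipy linkage matrix
    leaf_order: list[str]     # dendrogram leaf order


def cluster_usage(
    tables: list[CodonUsageTable], use_rscu: bool = False
) -> UsageClustering:
    """Average-linkage hierarchical clustering of genomes on their
    64-dimensional codon frequency (or RSCU) vectors; ties broken by
    genome name via a deterministic pre-sort."""
    if len(tables) < 2:
        raise PlastomeError("clustering needs at least two genomes")
    tables = sorted(tables, key=lambda t: t.name)
    names = [t.name for t in tables]
    vectors = np.vstack(
        [t.rscu_vector if use_rscu else t.frequency_vector for t in tables]
    )
    linkage = hierarchy.linkage(vectors, method="average", metric="euclidean")
    leaves = hierarchy.leaves_list(linkage)
    return UsageClustering(
        names=names, linkage=linkage, leaf_order=[names[i] for i in leaves]
    )


def usage_long_table(tables: list[CodonUsageTable]) -> pd.DataFrame:
    """One row per (genome, codon) for TSV output."""
    frames = []
    for t in tables:
        df = t.table.reset_index()
        df.insert(0, "genome", t.name)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
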