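"""Synthetic plastome cohorts with planted, fully known divergence.

The generator emits circular genomes with the canonical quadripartite
layout LSC + IRb + SSC + IRa, where IRa is the exact reverse complement
of IRb, a gene complement laid out from a configurable plan, and — for
each non-reference genotype — planted SNPs and indels recorded in a truth
manifest.  Every downstream stage of the pipeline can therefore be tested
round-trip against known truth without external data.

Default geometry and composition follow a typical pear (Pyrus) plastome:
159,935 bp total (LSC 87,962 / SSC 19,201 / IR 26,386), GC 36.59%, and a
118-gene complement (77 protein-coding, 31 tRNA, 8 rRNA, 2 pseudogenes,
32 genes resident in the IRs).  Single-copy regions mutate faster than
the IRs, whose edits are mirrored between IRb and IRa so the repeat
identity is preserved structurally.

Genes extending across the single-copy/IR boundaries are planted with
fixed extensions (rps19-like 120 bp, ndhF-like 12 bp, ycf1-like 1074 bp
into the repeat).  Because IRa mirrors IRb, the ycf1 tail necessarily
overlaps the planted ndhF 3' end — the classic ndhF/ΨYcf1 overlap — so
the generated ndhF carries no terminal stop codon (it remains free of
internal stops and passes the CDS quality screens).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    AnnotationSet,
    GeneFeature,
    Plastome,
    PlastomeError,
    RegionPartition,
    revcomp,
    splice,
)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE = [
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if a + b + c not in _STOPS
]

# minimal codon -> amino acid map (translation table 11 assignments)
_CODON_AA: dict[str, str] = {}


def _aa(codon: str) -> str:
    if not _CODON_AA:
        from Bio.Seq import Seq

        for a in "TCAG":
            for b in "TCAG":
                for c in "TCAG":
                    cod = a + b + c
                    _CODON_AA[cod] = (
                        "*" if cod in _STOPS else str(Seq(cod).translate(table=11))
                    )
    return _CODON_AA[codon]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class GenePlanEntry:
    """One gene to place wholly inside a region."""

    gene_name: str
    category: str
    region: str  # LSC | SSC | IR
    exon_lengths: tuple[int, ...]
    strand: str = "+"
    intron_lengths: tuple[int, ...] = ()

    @property
    def span(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)


@dataclass(frozen=True)
class IndelEvent:
    """A planted indel: ``offset`` is relative to the region start; for a
    deletion the removed bases are reference content, for an insertion the
    content is drawn at generation time."""

    region: str
    offset: int
    kind: str  # "ins" | "del"
    length: int


@dataclass
class DivergenceConfig:
    """Per-genotype divergence from the reference.

    SNPs are Bernoulli draws per base (single-copy vs IR rates; IR edits
    are applied to IRb and mirrored into IRa).  ``syn_bias`` is the
    probability that a SNP landing in a protein-coding exon is steered to
    a synonymous change when one exists — the generator's stand-in for
    purifying selection.  ``indel_plan`` entries are (region, kind,
    length, context) with positions drawn from matching reference
    context; explicit ``indel_events`` override the plan.
    """

    snp_rate_sc: float = 5e-4
    snp_rate_ir: float = 5e-5
    indel_events: Optional[list[IndelEvent]] = None
    indel_plan: list[tuple[str, str, int, str]] = field(default_factory=list)
    syn_bias: float = 0.7
    seed: int = 0
    # (rate_sc, rate_ir, seed) components drawn with their own generator:
    # genotypes listing the same component inherit (near-)identical edits,
    # which is how shared ancestry / internal tree branches are planted
    shared_components: tuple[tuple[float, float, int], ...] = ()

    def __post_init__(self) -> None:
        for r in (self.snp_rate_sc, self.snp_rate_ir):
            if not 0 <= r <= 1:
                raise PlastomeError(f"SNP rate {r} outside [0, 1]")


@dataclass
class TruthManifest:
    """Planted truth for one mutated genotype."""

    sample: str
    variants: pd.DataFrame
    region_lengths: dict[str, int]
    gene_complement: list[str]


@dataclass
class CohortConfig:
    lsc_len: int = 87_962
    ssc_len: int = 19_201
    ir_len: int = 26_386
    gc_target: float = 0.3659
    gene_plan: Optional[list[GenePlanEntry]] = None
    junction_spanners: bool = True
    at_only_third: bool = False
    n_genotypes: int = 5
    names: Optional[list[str]] = None
    divergence: Optional[list[DivergenceConfig]] = None
    gene_deletions: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0

    @property
    def total_len(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len

    def genotype_names(self) -> list[str]:
        if self.names:
            if len(self.names) != self.n_genotypes:
                raise PlastomeError("names/n_genotypes mismatch")
            return list(self.names)
        return [f"G{i + 1:02d}" for i in range(self.n_genotypes)]


# ---------------------------------------------------------------------------
# default gene plan (a pear-like 118-gene complement)

_LSC_PROTEIN = [
    ("psbA", 1062), ("rps16", 261), ("psbK", 186), ("psbI", 111),
    ("atpA", 1524), ("atpH", 246), ("atpI", 744), ("rps2", 711),
    ("rpoC2", 4140), ("rpoC1", 1617), ("rpoB", 3213), ("petN", 90),
    ("psbM", 105), ("psbD", 1062), ("psbC", 1386), ("psbZ", 189),
    ("rps14", 303), ("psaB", 2205), ("psaA", 2253), ("ycf3", 507),
    ("rps4", 606), ("ndhJ", 477), ("ndhK", 678), ("ndhC", 363),
    ("atpE", 402), ("atpB", 1497), ("rbcL", 1428), ("accD", 1467),
    ("psaI", 111), ("ycf4", 555), ("cemA", 690), ("petA", 963),
    ("psbJ", 123), ("psbL", 117), ("psbF", 120), ("psbE", 252),
    ("petL", 96), ("petG", 114), ("psaJ", 129), ("rpl33", 201),
    ("rps18", 306), ("rpl20", 354), ("rps12", 372), ("psbB", 1527),
    ("psbT", 108), ("psbN", 132), ("psbH", 222), ("petB", 648),
    ("petD", 483), ("rpoA", 1014), ("rps11", 417), ("rpl16", 408),
    ("rpl22", 399), ("rps8", 405),
]
_LSC_INTRONS = {"rpoC1": (738,), "ycf3": (711, 738), "rpl22": (63,)}
_LSC_MINUS = {"psbA", "rpoC2", "rpoC1", "rpoB", "petN", "psaB", "psaA",
              "ycf3", "rps4", "rps14", "rpl20", "rps12", "rpoA", "rps11",
              "rpl16", "rpl22", "rps8"}
_LSC_TRNA = [
    "trnH-GTG", "trnK-TTT", "trnQ-TTG", "trnS-GCT", "trnG-GCC", "trnR-TCT",
    "trnC-GCA", "trnD-GTC", "trnY-GTA", "trnE-TTC", "trnT-GGT", "trnS-TGA",
    "trnF-GAA", "trnM-CAT", "trnW-CCA", "trnP-TGG",
]
_LSC_TRNA_INTRONS = {"trnK-TTT": (945,)}
_LSC_PSEUDO = [("atpF", 555), ("clpP", 591)]
_SSC_PROTEIN = [
    ("ndhD", 1503), ("psaC", 246), ("ndhE", 306), ("ndhG", 531),
    ("ndhI", 504), ("ndhA", 1092), ("ndhH", 1182), ("rps15", 273),
    ("rpl32", 171), ("ccsA", 960),
]
_SSC_INTRONS = {"ndhA": (1125,)}
_SSC_MINUS = {"ndhD", "ndhE", "ndhG", "ndhI", "ndhA", "ndhH", "rpl32"}
_SSC_TRNA = ["trnL-TAG"]
_IR_PROTEIN = [
    ("rpl2", 825), ("rpl23", 282), ("ycf2", 6621), ("ndhB", 1533),
    ("rps7", 468),
]
_IR_INTRONS = {"rpl2": (660,), "ndhB": (679,)}
_IR_TRNA = [
    "trnI-CAT", "trnL-CAA", "trnV-GAC", "trnI-GAT", "trnA-TGC",
    "trnR-ACG", "trnN-GTT",
]
_IR_TRNA_INTRONS = {"trnI-GAT": (815,), "trnA-TGC": (802,)}
_IR_RRNA = [("rrn16S", 1491), ("rrn23S", 2810), ("rrn4.5S", 103), ("rrn5S", 121)]

# junction-spanning genes: (name, total length, bases extending into the IR)
_SPAN_RPS19 = ("rps19", 279, 120)   # LSC/IRb
_SPAN_NDHF = ("ndhF", 2241, 12)     # IRb/SSC, minus strand
_SPAN_YCF1 = ("ycf1", 5577, 1074)   # SSC/IRa


def default_gene_plan() -> list[GenePlanEntry]:
    """The built-in 118-gene complement (junction spanners added separately)."""
    plan: list[GenePlanEntry] = []

    def protein(name: str, length: int, region: str, strand: str,
                introns: tuple[int, ...]) -> GenePlanEntry:
        k = len(introns) + 1
        base, rem = divmod(length // 3, k)
        exons = tuple(3 * (base + (1 if i < rem else 0)) for i in range(k))
        return GenePlanEntry(name, "protein_coding", region, exons, strand, introns)

    for name, length in _LSC_PROTEIN:
        plan.append(
            protein(name, length, "LSC", "-" if name in _LSC_MINUS else "+",
                    _LSC_INTRONS.get(name, ()))
        )
    for name, length in _LSC_PSEUDO:
        plan.append(GenePlanEntry(name, "pseudogene", "LSC", (length,), "+"))
    for name in _LSC_TRNA:
        introns = _LSC_TRNA_INTRONS.get(name, ())
        exons = (38, 37) if introns else (75,)
        plan.append(GenePlanEntry(name, "tRNA", "LSC", exons, "+", introns))
    for name, length in _SSC_PROTEIN:
        plan.append(
            protein(name, length, "SSC", "-" if name in _SSC_MINUS else "+",
                    _SSC_INTRONS.get(name, ()))
        )
    for name in _SSC_TRNA:
        plan.append(GenePlanEntry(name, "tRNA", "SSC", (80,), "-"))
    for name, length in _IR_PROTEIN:
        plan.append(protein(name, length, "IR", "+", _IR_INTRONS.get(name, ())))
    for name in _IR_TRNA:
        introns = _IR_TRNA_INTRONS.get(name, ())
        exons = (37, 38) if introns else (74,)
        plan.append(GenePlanEntry(name, "tRNA", "IR", exons, "+", introns))
    for name, length in _IR_RRNA:
        plan.append(GenePlanEntry(name, "rRNA", "IR", (length,), "+"))
    return plan


# ---------------------------------------------------------------------------
# sequence synthesis helpers


def _codon_probs(gc_target: float, at_only_third: bool) -> tuple[list[str], np.ndarray]:
    """Sense-codon sampling weights whose expected GC equals ``gc_target``.

    Base probabilities p(G)=p(C)=q/2 are renormalized over sense codons
    (stops excluded), which biases GC slightly; q is solved by bisection
    so the expectation comes out exact.
    """
    codons = [c for c in _SENSE if (c[2] in "AT" if at_only_third else True)]
    gc_counts = np.array([sum(b in "GC" for b in c) for c in codons], dtype=float)

    def expected_gc(q: float) -> float:
        w = np.array(
            [np.prod([(q / 2 if b in "GC" else (1 - q) / 2) for b in c]) for c in codons]
        )
        w = w / w.sum()
        return float((w * gc_counts).sum() / 3)

    if at_only_third:
        # third position contributes no GC; match the first two positions only
        target = min(gc_target * 3 / 2, 0.98)
    else:
        target = gc_target
    lo, hi = 1e-6, 1 - 1e-6
    for _ in range(60):
        mid = (lo + hi) / 2
        if expected_gc(mid) < target:
            lo = mid
        else:
            hi = mid
    q = (lo + hi) / 2
    w = np.array(
        [np.prod([(q / 2 if b in "GC" else (1 - q) / 2) for b in c]) for c in codons]
    )
    return codons, w / w.sum()


class _SeqFactory:
    def __init__(self, gc_target: float, at_only_third: bool, rng: np.random.Generator):
        self.rng = rng
        self.gc = gc_target
        p = np.array([(1 - gc_target) / 2, gc_target / 2, gc_target / 2,
                      (1 - gc_target) / 2])
        self.base_p = p
        self.at_only_third = at_only_third
        self.codons, self.codon_p = _codon_probs(gc_target, at_only_third)

    def background(self, length: int) -> str:
        return "".join(self.rng.choice(_BASES, size=length, p=self.base_p))

    def cds(self, length: int) -> str:
        """ATG + sense codons + TAA; length must be a positive multiple of 3."""
        if length % 3 or length < 9:
            raise PlastomeError(f"CDS length {length} not a multiple of 3 (>= 9)")
        k = length // 3 - 2
        body = "".join(self.rng.choice(self.codons, size=k, p=self.codon_p))
        # the A/T-third-position mode trades the canonical ATG start for an
        # A/T-ending codon so GC3 is exactly zero
        start = "ATA" if self.at_only_third else "ATG"
        return start + body + "TAA"

    def sense_codons(self, k: int) -> str:
        return "".join(self.rng.choice(self.codons, size=k, p=self.codon_p))


# ---------------------------------------------------------------------------
# reference construction


def _layout_region(
    entries: list[GenePlanEntry],
    region_len: int,
    region_name: str,
    reserved_head: int,
    reserved_tail: int,
) -> list[tuple[GenePlanEntry, int]]:
    """Assign sequential start offsets with even spacers; error on overflow."""
    total = sum(e.span for e in entries)
    free = region_len - reserved_head - reserved_tail - total
    k = len(entries)
    if free < k + 1:
        raise PlastomeError(
            f"gene plan overflows region {region_name}: "
            f"{total} gene bases + reserves exceed {region_len}"
        )
    spacer = free // (k + 1)
    placed = []
    pos = reserved_head + spacer
    for e in entries:
        placed.append((e, pos))
        pos += e.span + spacer
    return placed


def _write_gene(
    buf: np.ndarray, entry: GenePlanEntry, offset: int, factory: _SeqFactory
) -> GeneFeature:
    """Write a gene's exonic content into a region buffer and return its
    feature (region-local coordinates)."""
    exons = []
    pos = offset
    for i, exon_len in enumerate(entry.exon_lengths):
        exons.append((pos, pos + exon_len))
        pos += exon_len
        if i < len(entry.intron_lengths):
            pos += entry.intron_lengths[i]
    if entry.category in ("protein_coding",):
        cds = factory.cds(sum(entry.exon_lengths))
        genomic = revcomp(cds) if entry.strand == "-" else cds
        cursor = 0
        for s, e in exons:
            buf[s:e] = list(genomic[cursor : cursor + (e - s)])
            cursor += e - s
    # tRNA / rRNA / pseudogene content stays as background composition
    return GeneFeature(
        gene_name=entry.gene_name,
        category=entry.category,
        strand=entry.strand,
        exons=tuple(exons),
        copy_tag=0,
    )


def generate_reference(config: CohortConfig) -> Plastome:
    """Build the reference genotype: LSC + IRb + SSC + revcomp(IRb)."""
    rng = np.random.default_rng(config.seed)
    factory = _SeqFactory(config.gc_target, config.at_only_third, rng)
    plan = config.gene_plan if config.gene_plan is not None else default_gene_plan()
    lsc_len, ssc_len, ir_len = config.lsc_len, config.ssc_len, config.ir_len
    n = config.total_len

    lsc = np.array(list(factory.background(lsc_len)))
    irb = np.array(list(factory.background(ir_len)))
    ssc = np.array(list(factory.background(ssc_len)))

    features: list[GeneFeature] = []
    span_rps19 = span_ndhf = span_ycf1 = None
    if config.junction_spanners:
        span_rps19, span_ndhf, span_ycf1 = _SPAN_RPS19, _SPAN_NDHF, _SPAN_YCF1

    # reserves keep plain genes away from junction-spanner footprints
    res_lsc_tail = (span_rps19[1] - span_rps19[2] + 40) if span_rps19 else 0
    res_irb_head = (span_rps19[2] + 40) if span_rps19 else 0
    res_irb_tail = (span_ycf1[2] + 40) if span_ycf1 else 0
    res_ssc_head = (span_ndhf[1] - span_ndhf[2] + 40) if span_ndhf else 0
    res_ssc_tail = (span_ycf1[1] - span_ycf1[2] + 40) if span_ycf1 else 0

    by_region: dict[str, list[GenePlanEntry]] = {"LSC": [], "SSC": [], "IR": []}
    for e in plan:
        by_region[e.region].append(e)

    for entry, off in _layout_region(by_region["LSC"], lsc_len, "LSC", 20, res_lsc_tail):
        features.append(_write_gene(lsc, entry, off, factory))
    for entry, off in _layout_region(
        by_region["SSC"], ssc_len, "SSC", res_ssc_head, res_ssc_tail
    ):
        features.append(_write_gene(ssc, entry, off, factory).shifted(lsc_len + ir_len))
    ir_local: list[GeneFeature] = []
    for entry, off in _layout_region(
        by_region["IR"], ir_len, "IR", res_irb_head, res_irb_tail
    ):
        ir_local.append(_write_gene(irb, entry, off, factory))

    if config.junction_spanners:
        # rps19-like: plus strand across LSC/IRb, tail inside the repeat
        name, length, in_ir = span_rps19
        cds = factory.cds(length)
        lsc[lsc_len - (length - in_ir):] = list(cds[: length - in_ir])
        irb[:in_ir] = list(cds[length - in_ir:])
        features.append(
            GeneFeature(name, "protein_coding", "+",
                        ((lsc_len - (length - in_ir), lsc_len + in_ir),))
        )

        # ycf1-like: plus strand across SSC/IRa; its IRa tail is written as
        # the reverse complement into the end of IRb (the mirror image)
        name, length, in_ir = span_ycf1
        cds = factory.cds(length)
        # pin four codons so the mirrored ndhF tail below stays stop-free
        cds = cds[: length - in_ir] + "GGTGCACTTGAA" + cds[length - in_ir + 12:]
        ssc[ssc_len - (length - in_ir):] = list(cds[: length - in_ir])
        irb[ir_len - in_ir:] = list(revcomp(cds[length - in_ir:]))
        start = lsc_len + ir_len + ssc_len - (length - in_ir)
        features.append(
            GeneFeature(name, "protein_coding", "+", ((start, start + length),))
        )

        # ndhF-like: minus strand across IRb/SSC; its 12 repeat bases are
        # already dictated by the ycf1 mirror
        name, length, in_ir = span_ndhf
        head_len = length - in_ir
        head = "ATG" + factory.sense_codons(head_len // 3 - 1)
        g_ssc = revcomp(head)
        # avoid chance IR extension across the IRb/SSC junction: the first
        # SSC base must not pair with the last SSC base under the mirror
        while g_ssc[0] == revcomp(ssc[ssc_len - 1])[0]:
            head = head[:-3] + factory.sense_codons(1)
            g_ssc = revcomp(head)
        ssc[:head_len] = list(g_ssc)
        start = lsc_len + ir_len - in_ir
        features.append(
            GeneFeature(name, "protein_coding", "-", ((start, start + length),))
        )

    # IR genes: the IRb copy plus its mirrored IRa duplicate
    for f in ir_local:
        features.append(f.shifted(lsc_len))
        exons = tuple(
            sorted((ir_len - e, ir_len - s) for s, e in f.exons)
        )
        mirrored = GeneFeature(
            gene_name=f.gene_name,
            category=f.category,
            strand="-" if f.strand == "+" else "+",
            exons=tuple((s + lsc_len + ir_len + ssc_len, e + lsc_len + ir_len + ssc_len)
                        for s, e in exons),
            copy_tag=1,
        )
        features.append(mirrored)

    # forbid chance extension of the repeat pair across the origin
    if lsc[0] == revcomp(lsc[lsc_len - 1])[0]:
        choices = [b for b in "ACGT" if b != revcomp(lsc[lsc_len - 1])[0]]
        lsc[0] = choices[int(rng.integers(len(choices)))]
    if not config.junction_spanners:
        while ssc[0] == revcomp(ssc[ssc_len - 1])[0]:
            ssc[0] = str(rng.choice(_BASES))

    sequence = "".join(lsc) + "".join(irb) + "".join(ssc) + revcomp("".join(irb))
    assert len(sequence) == n
    names = config.genotype_names()
    return Plastome(
        name=names[0],
        sequence=sequence,
        annotations=AnnotationSet(sorted(features, key=lambda f: (f.start, f.key))),
        partition=RegionPartition.from_lengths(lsc_len, ir_len, ssc_len),
    )


# ---------------------------------------------------------------------------
# mutation


def left_align_indel(
    ref: str, start: int, length: int, kind: str, inserted: str = ""
) -> tuple[int, str]:
    """Left-normalize an indel; returns (anchor, allele).

    ``start`` is the first deleted reference base (del) or the reference
    position *before which* the insertion occurs (ins).  The anchor is the
    reference base immediately left of the normalized event.
    """
    if kind == "del":
        while start > 0 and ref[start - 1] == ref[start + length - 1]:
            start -= 1
        return start - 1, ref[start : start + length]
    seq = inserted
    while start > 0 and ref[start - 1] == seq[-1]:
        seq = ref[start - 1] + seq[:-1]
        start -= 1
    return start - 1, seq


def _cds_maps(reference: Plastome) -> tuple[np.ndarray, np.ndarray, list[GeneFeature]]:
    """Per-position protein-coding feature index and CDS offset (or -1)."""
    n = len(reference)
    gene_idx = np.full(n, -1, dtype=np.int32)
    cds_pos = np.full(n, -1, dtype=np.int32)
    feats = [f for f in reference.annotations if f.category == "protein_coding"]
    for gi, f in enumerate(feats):
        cursor = 0
        for s, e in f.exons:
            idx = np.arange(s, e)
            fwd = cursor + np.arange(e - s)
            gene_idx[idx] = gi
            if f.strand == "+":
                cds_pos[idx] = fwd
            else:
                cds_pos[idx] = f.exon_length - 1 - fwd
            cursor += e - s
    return gene_idx, cds_pos, feats


def _synonymous_alt(
    cds: str, cds_index: int, strand: str, ref_base: str, rng: np.random.Generator
) -> Optional[str]:
    """A genomic base giving a synonymous change at this CDS position."""
    k, o = divmod(cds_index, 3)
    codon = cds[3 * k : 3 * k + 3]
    if len(codon) < 3:
        return None
    aa = _aa(codon)
    options = []
    for b in "ACGT":
        if b == codon[o]:
            continue
        alt_codon = codon[:o] + b + codon[o + 1 :]
        if alt_codon not in _STOPS and _aa(alt_codon) == aa:
            options.append(b)
    if not options:
        return None
    cds_base = options[int(rng.integers(len(options)))]
    return cds_base if strand == "+" else revcomp(cds_base)


def plan_indel_events(
    reference: Plastome,
    plan: Sequence[tuple[str, str, int, str]],
    rng: np.random.Generator,
) -> list[IndelEvent]:
    """Draw concrete indel positions matching the requested contexts."""
    p = reference.partition
    assert p is not None
    exonic = np.zeros(len(reference), dtype=bool)
    genic = np.zeros(len(reference), dtype=bool)
    for f in reference.annotations:
        genic[f.start : f.end] = True
        for s, e in f.exons:
            exonic[s:e] = True
    regions = dict(p.items())
    taken: list[tuple[int, int]] = []
    events = []
    for region, kind, length, context in plan:
        s, e = regions[region]
        ok = np.ones(e - s, dtype=bool)
        seg_exonic = exonic[s:e]
        seg_genic = genic[s:e]
        if context == "intergenic":
            ok &= ~seg_genic
        elif context == "intronic":
            ok &= seg_genic & ~seg_exonic
        elif context == "genic":
            ok &= seg_exonic
        # keep footprints clear of the region edges and of each other
        ok[: 30] = False
        ok[-(30 + length):] = False
        candidates = np.flatnonzero(ok)
        rng.shuffle(candidates)
        placed = False
        for off in candidates[:5000]:
            a = s + int(off)
            if all(abs(a - t0) > t1 + length + 10 for t0, t1 in taken):
                events.append(IndelEvent(region, int(off), kind, length))
                taken.append((a, length))
                placed = True
                break
        if not placed:
            raise PlastomeError(
                f"could not place a {context} {kind} of {length} bases in {region}"
            )
    return events


def mutate_genotype(
    reference: Plastome, div: DivergenceConfig, name: str
) -> tuple[Plastome, TruthManifest]:
    """Apply planted SNPs and indels; IRb edits are mirrored into IRa."""
    p = reference.partition
    if p is None:
        raise PlastomeError("reference needs a partition before mutation")
    rng = np.random.default_rng(div.seed)
    ref = reference.sequence
    n = len(ref)
    regions = dict(p.items())

    events = div.indel_events
    if events is None:
        events = plan_indel_events(reference, div.indel_plan, rng)

    # expand to absolute coordinates, mirroring IRb events into IRa
    factory = _SeqFactory(0.3659, False, rng)
    indels: list[dict] = []  # {kind, start, length, seq, region, mirrored}
    for ev in events:
        if ev.region not in ("LSC", "SSC", "IRb"):
            raise PlastomeError(f"indels may be planted in LSC/SSC/IRb, not {ev.region}")
        s, e = regions[ev.region]
        start = s + ev.offset
        if ev.kind == "del" and start + ev.length > e:
            raise PlastomeError(f"deletion at {start} leaves region {ev.region}")
        if ev.kind == "ins":
            seq = factory.background(ev.length)
            # keep the planted anchor stable under left-normalization
            while seq[-1] == ref[start - 1]:
                seq = factory.background(ev.length)
        else:
            seq = ref[start : start + ev.length]
        indels.append(
            dict(kind=ev.kind, start=start, length=ev.length, seq=seq,
                 region=ev.region, mirrored=False)
        )
        if ev.region == "IRb":
            u = start - regions["IRb"][0]
            ira_s = regions["IRa"][0]
            ir_len = p.ir_len
            if ev.kind == "ins":
                m_start = ira_s + (ir_len - u)
                m_seq = revcomp(seq)
            else:
                m_start = ira_s + (ir_len - u - ev.length)
                m_seq = revcomp(seq)
            indels.append(
                dict(kind=ev.kind, start=m_start, length=ev.length, seq=m_seq,
                     region="IRa", mirrored=True)
            )
    # overlap validation (including mirrors)
    spans = sorted(
        (d["start"], d["start"] + (d["length"] if d["kind"] == "del" else 0))
        for d in indels
    )
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1 + 1:
            raise PlastomeError("planted indels overlap or touch")

    # SNP positions
    forbidden = np.zeros(n, dtype=bool)
    for d in indels:
        lo = max(0, d["start"] - 2)
        hi = min(n, d["start"] + (d["length"] if d["kind"] == "del" else 0) + 2)
        forbidden[lo:hi] = True
    for pos in (0, p.lsc[1] - 1, p.ssc[0], p.ssc[1] - 1, n - 1):
        forbidden[pos] = True  # protects exact IR boundary detection

    gene_idx, cds_pos, prot_feats = _cds_maps(reference)
    cds_cache: dict[int, str] = {}
    seq_arr = np.array(list(ref))

    snps: list[dict] = []
    occupied: set[int] = set()

    def draw_snps(rng_c: np.random.Generator, region: str, rate: float) -> None:
        s, e = regions[region]
        hits = s + np.flatnonzero(rng_c.random(e - s) < rate)
        for pos in hits:
            pos = int(pos)
            if forbidden[pos] or pos in occupied:
                continue
            ref_base = ref[pos]
            alt = None
            gi = gene_idx[pos]
            if gi >= 0 and rng_c.random() < div.syn_bias:
                if gi not in cds_cache:
                    cds_cache[gi] = splice(ref, prot_feats[gi])
                alt = _synonymous_alt(
                    cds_cache[gi], int(cds_pos[pos]), prot_feats[gi].strand,
                    ref_base, rng_c
                )
            if alt is None:
                choices = [b for b in "ACGT" if b != ref_base]
                alt = choices[int(rng_c.integers(3))]
            occupied.add(pos)
            snps.append(dict(pos=pos, ref=ref_base, alt=alt,
                             region=region, mirrored=False))
            if region == "IRb":
                u = pos - regions["IRb"][0]
                m_pos = regions["IRa"][0] + (p.ir_len - 1 - u)
                occupied.add(m_pos)
                snps.append(dict(pos=m_pos, ref=ref[m_pos], alt=revcomp(alt),
                                 region="IRa", mirrored=True))

    # shared components first (identical edits across genotypes that list
    # the same component), then the genotype's private divergence
    for rate_sc, rate_ir, comp_seed in div.shared_components:
        rng_c = np.random.default_rng(comp_seed)
        draw_snps(rng_c, "LSC", rate_sc)
        draw_snps(rng_c, "SSC", rate_sc)
        draw_snps(rng_c, "IRb", rate_ir)
    draw_snps(rng, "LSC", div.snp_rate_sc)
    draw_snps(rng, "SSC", div.snp_rate_sc)
    draw_snps(rng, "IRb", div.snp_rate_ir)

    for snp in snps:
        seq_arr[snp["pos"]] = snp["alt"]

    # apply indels right to left so stored coordinates stay valid
    out = list(seq_arr)
    for d in sorted(indels, key=lambda d: -d["start"]):
        if d["kind"] == "del":
            del out[d["start"] : d["start"] + d["length"]]
        else:
            out[d["start"] : d["start"]] = list(d["seq"])
    mutated_seq = "".join(out)

    # remap annotations through the indel shifts
    breaks = sorted(
        (d["start"], -d["length"] if d["kind"] == "del" else d["length"],
         d["length"] if d["kind"] == "del" else 0)
        for d in indels
    )

    def remap(pos: int) -> int:
        shift = 0
        for start, delta, del_len in breaks:
            if pos <= start:
                break
            if del_len and pos < start + del_len:
                return start + shift  # position inside a deleted segment
            shift += delta
        return pos + shift

    new_features = []
    for f in reference.annotations:
        exons = []
        for s, e in f.exons:
            ns, ne = remap(s), remap(e)
            if ne > ns:
                exons.append((ns, ne))
        if exons:
            new_features.append(replace(f, exons=tuple(exons)))

    def shift_in(region: str) -> int:
        s, e = regions[region]
        return sum(
            delta for start, delta, _ in breaks if s <= start < e
        )

    region_lengths = {
        "LSC": p.lsc_len + shift_in("LSC"),
        "SSC": p.ssc_len + shift_in("SSC"),
        "IR": p.ir_len + shift_in("IRb"),
    }
    new_partition = RegionPartition.from_lengths(
        region_lengths["LSC"], region_lengths["IR"], region_lengths["SSC"]
    )

    mutant = Plastome(
        name=name,
        sequence=mutated_seq,
        annotations=AnnotationSet(new_features),
        partition=new_partition,
    )

    # manifest (variant coordinates are on the reference)
    from .variants import classify_position  # local import avoids a cycle

    rows = []
    for snp in snps:
        ctx, fl, fr = classify_position(reference, snp["pos"])
        rows.append(
            dict(sample=name, type="SNP", ref_position=snp["pos"], length=1,
                 ref_allele=snp["ref"], alt_allele=snp["alt"],
                 region=snp["region"], context=ctx, flank_left=fl, flank_right=fr,
                 mirrored=snp["mirrored"], orig_start=snp["pos"])
        )
    for d in indels:
        anchor, allele = left_align_indel(
            ref, d["start"], d["length"],
            "del" if d["kind"] == "del" else "ins", d["seq"]
        )
        kind = "deletion" if d["kind"] == "del" else "insertion"
        site = d["start"] if d["kind"] == "del" else max(d["start"] - 1, 0)
        ctx, fl, fr = classify_position(reference, site)
        rows.append(
            dict(sample=name, type=kind, ref_position=anchor, length=d["length"],
                 ref_allele=allele if kind == "deletion" else "",
                 alt_allele=allele if kind == "insertion" else "",
                 region=d["region"], context=ctx, flank_left=fl, flank_right=fr,
                 mirrored=d["mirrored"], orig_start=d["start"])
        )
    columns = ["sample", "type", "ref_position", "length", "ref_allele",
               "alt_allele", "region", "context", "flank_left", "flank_right",
               "mirrored", "orig_start"]
    variants = (
        pd.DataFrame(rows, columns=columns)
        .sort_values(["ref_position", "type"], kind="stable")
        .reset_index(drop=True)
    )
    manifest = TruthManifest(
        sample=name,
        variants=variants,
        region_lengths=region_lengths,
        gene_complement=sorted({f.gene_name for f in new_features}),
    )
    return mutant, manifest


def true_alignment(
    reference: Plastome, mutant: Plastome, manifest: TruthManifest
) -> "Alignment":
    """The exact pairwise alignment implied by the planted events."""
    from .model import Alignment

    ref = reference.sequence
    events = manifest.variants
    indels = events[events["type"] != "SNP"].sort_values("orig_start")
    ref_row: list[str] = []
    alt_row: list[str] = []
    cursor = 0
    snp_alt = {
        int(r.ref_position): r.alt_allele
        for r in events[events["type"] == "SNP"].itertuples()
    }

    def emit(upto: int) -> None:
        nonlocal cursor
        for pos in range(cursor, upto):
            ref_row.append(ref[pos])
            alt_row.append(snp_alt.get(pos, ref[pos]))
        cursor = upto

    for r in indels.itertuples():
        start = int(r.orig_start)
        if r.type == "deletion":
            emit(start)
            ref_row.append(ref[start : start + int(r.length)])
            alt_row.append("-" * int(r.length))
            cursor = start + int(r.length)
        else:
            emit(start)
            # reconstruct the un-normalized inserted content from the
            # normalized allele
            shift = start - 1 - int(r.ref_position)
            allele = r.alt_allele
            seq = allele[shift:] + ref[start - shift : start] if shift else allele
            ref_row.append("-" * int(r.length))
            alt_row.append(seq)
    emit(len(ref))
    aln = Alignment(
        ids=[reference.name, mutant.name],
        seqs=["".join(ref_row), "".join(alt_row)],
    )
    assert aln.seqs[1].replace("-", "") == mutant.sequence
    return aln


# ---------------------------------------------------------------------------
# cohorts


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """Five genotypes emulating the study cohort: one reference, one very
    close genotype (15 LSC indels: 11 insertions + 4 deletions, net +46 bp)
    and three more distant relatives with 32 / 57 / 31 indels."""

    def seeds(i: int) -> int:
        return (seed * 7919 + i * 104_729 + 17) % (2**31)

    hb2_plan = (
        [("LSC", "ins", L, "intergenic") for L in (6, 6, 5, 8, 5, 7, 6, 5, 8)]
        + [("LSC", "ins", 6, "genic"), ("LSC", "ins", 9, "genic")]
        + [("LSC", "del", L, "intergenic") for L in (6, 5, 8)]
        + [("LSC", "del", 6, "genic")]
    )
    jbl_plan = (
        [("LSC", "ins", 5 + (i % 9), "intergenic") for i in range(16)]
        + [("LSC", "del", 5 + (i % 7), "intergenic") for i in range(10)]
        + [("SSC", "ins", 6, "intergenic"), ("SSC", "ins", 8, "intergenic")]
        + [("SSC", "del", 5, "intergenic")]
        + [("LSC", "ins", 7, "intronic"), ("LSC", "del", 6, "intronic")]
        + [("LSC", "ins", 6, "genic")]
    )
    erc_plan = (
        [("LSC", "ins", 5 + (i % 11), "intergenic") for i in range(26)]
        + [("LSC", "del", 5 + (i % 9), "intergenic") for i in range(18)]
        + [("SSC", "ins", 5 + (i % 6), "intergenic") for i in range(6)]
        + [("SSC", "del", 6, "intergenic"), ("SSC", "del", 9, "intergenic")]
        + [("LSC", "ins", 8, "intronic"), ("SSC", "del", 5, "intronic")]
        + [("LSC", "del", 9, "genic"), ("LSC", "ins", 6, "genic")]
        + [("IRb", "ins", 6, "intergenic")]
    )
    bet_plan = (
        [("LSC", "ins", 5 + (i % 8), "intergenic") for i in range(14)]
        + [("LSC", "del", 5 + (i % 6), "intergenic") for i in range(11)]
        + [("SSC", "ins", 7, "intergenic"), ("SSC", "ins", 5, "intergenic")]
        + [("SSC", "del", 8, "intergenic")]
        + [("LSC", "ins", 9, "intronic"), ("LSC", "del", 6, "intronic")]
        + [("LSC", "ins", 9, "genic")]
    )
    # shared components plant the internal branches of the true tree:
    # ((HB1, HB2), ((JBL, BET), ERC)) — all non-HB genotypes share one
    # component, the two eastern-pear-like genotypes share a second
    comp_others = (7e-4, 5e-5, seeds(10))
    comp_east = (6e-4, 5e-5, seeds(11))
    divergence = [
        DivergenceConfig(snp_rate_sc=1.5e-4, snp_rate_ir=2e-5,
                         indel_plan=hb2_plan, seed=seeds(1)),
        DivergenceConfig(snp_rate_sc=2.5e-4, snp_rate_ir=2e-5,
                         indel_plan=jbl_plan, seed=seeds(2),
                         shared_components=(comp_others, comp_east)),
        DivergenceConfig(snp_rate_sc=5e-4, snp_rate_ir=4e-5,
                         indel_plan=erc_plan, seed=seeds(3),
                         shared_components=(comp_others,)),
        DivergenceConfig(snp_rate_sc=2.5e-4, snp_rate_ir=2e-5,
                         indel_plan=bet_plan, seed=seeds(4),
                         shared_components=(comp_others, comp_east)),
    ]
    names = ["Phop_HB1", "Phop_HB2", "Puss_JBL", "Pcom_ERC", "Pbet_BET"]
    return CohortConfig(
        n_genotypes=5,
        names=names,
        divergence=divergence,
        gene_deletions={
            "Puss_JBL": ["atpB", "trnI-GAT"],
            "Pcom_ERC": ["atpB", "trnI-GAT"],
            "Pbet_BET": ["trnI-GAT"],
        },
        seed=seed,
    )


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[Plastome], list[TruthManifest]]:
    """One reference plus n_genotypes - 1 mutated genotypes."""
    if config.n_genotypes < 2:
        raise PlastomeError("a cohort needs at least 2 genotypes")
    names = config.genotype_names()
    reference = generate_reference(config)
    divergence = config.divergence
    if divergence is None:
        base = default_cohort_config(config.seed).divergence
        assert base is not None
        divergence = [
            replace(base[min(i, len(base) - 1)],
                    seed=(config.seed * 7919 + (i + 1) * 104_729 + 17) % (2**31))
            for i in range(config.n_genotypes - 1)
        ]
    if len(divergence) != config.n_genotypes - 1:
        raise PlastomeError("divergence list must cover every non-reference genotype")

    genomes = [reference]
    manifests: list[TruthManifest] = []
    for name, div in zip(names[1:], divergence):
        mutant, manifest = mutate_genotype(reference, div, name)
        genomes.append(mutant)
        manifests.append(manifest)

    # annotation-level gene losses (gain-loss truth)
    for i, g in enumerate(genomes):
        drop = {d.lower() for d in config.gene_deletions.get(g.name, [])}
        if drop:
            kept = [f for f in g.annotations if f.gene_name.lower() not in drop]
            genomes[i] = replace(g, annotations=AnnotationSet(kept))
    return genomes, manifests
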