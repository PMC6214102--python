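"""Core domain objects shared by every stage of the pipeline.

Coordinate conventions
----------------------
All coordinates are 0-based, half-open intervals on the forward strand of
the (possibly normalized) circle.  GFF3 I/O converts from/to 1-based
inclusive at the boundary.  After normalization the large single copy
region starts at position 0 and the region order along the sequence is
LSC, IRb, SSC, IRa.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

Interval = tuple[int, int]

CATEGORIES = ("protein_coding", "tRNA", "rRNA", "pseudogene")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    """GC fraction over non-N bases; 'N' bases carry no weight."""
    seq = seq.upper()
    n_informative = len(seq) - seq.count("N")
    if n_informative == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / n_informative


class PlastomeError(ValueError):
    """Invalid plastome, annotation or partition input."""


def splice(sequence: str, feature: "GeneFeature") -> str:
    """Spliced gene sequence on the coding sense: exons concatenated in
    genomic order, reverse-complemented for minus-strand genes."""
    s = "".join(sequence[a:b] for a, b in feature.exons)
    return revcomp(s) if feature.strand == "-" else s


@dataclass(frozen=True)
class GeneFeature:
    """A single annotated gene copy.

    ``exons`` are stored in ascending genomic order regardless of strand;
    splicing (see :func:`plastokit.codon.splice`) reverses them for minus
    strand genes.  Introns are the gaps between consecutive exons and are
    always derived, never stored.
    """

    gene_name: str
    category: str
    strand: str
    exons: tuple[Interval, ...]
    copy_tag: int = 0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise PlastomeError(f"unknown gene category {self.category!r}")
        if self.strand not in "+-":
            raise PlastomeError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise PlastomeError(f"{self.gene_name}: at least one exon required")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if e <= s or s < 0:
                raise PlastomeError(f"{self.gene_name}: bad exon interval ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise PlastomeError(f"{self.gene_name}: exons overlap or are unordered")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span_length(self) -> int:
        """Full genomic extent, introns included."""
        return self.end - self.start

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def intron_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.introns)

    @property
    def key(self) -> tuple[str, int]:
        return (self.gene_name.lower(), self.copy_tag)

    def shifted(self, offset: int) -> "GeneFeature":
        return replace(
            self, exons=tuple((s + offset, e + offset) for s, e in self.exons)
        )


@dataclass
class AnnotationSet:
    """All gene features of one genome; (gene_name, copy_tag) pairs unique."""

    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for f in self.features:
            if f.key in seen:
                raise PlastomeError(
                    f"duplicate (gene_name, copy_tag) pair {f.key} in annotation set"
                )
            seen.add(f.key)

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def by_name(self, gene_name: str) -> list[GeneFeature]:
        name = gene_name.lower()
        return [f for f in self.features if f.gene_name.lower() == name]

    def get(self, gene_name: str, copy_tag: int = 0) -> Optional[GeneFeature]:
        for f in self.features:
            if f.key == (gene_name.lower(), copy_tag):
                return f
        return None

    def of_category(self, category: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category == category]

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for f in self.features:
            counts[f.category] += 1
        return counts


@dataclass(frozen=True)
class RegionPartition:
    """Coordinates of LSC, IRb, SSC, IRa on the circle.

    Intervals are (start, end) with start < end; ``end`` may exceed the
    genome length for a region that wraps the origin of an un-normalized
    genome (all positions are understood modulo ``genome_length``).  The
    four arcs tile the circle exactly, in cyclic order LSC, IRb, SSC, IRa.
    """

    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval
    genome_length: int

    def __post_init__(self) -> None:
        n = self.genome_length
        arcs = [self.lsc, self.irb, self.ssc, self.ira]
        if sum(e - s for s, e in arcs) != n:
            raise PlastomeError("partition arcs do not tile the circle")
        if (self.irb[1] - self.irb[0]) != (self.ira[1] - self.ira[0]):
            raise PlastomeError("|IRb| != |IRa|")
        for prev, cur in zip(arcs, arcs[1:] + arcs[:1]):
            if cur[0] % n != prev[1] % n:
                raise PlastomeError("partition arcs not in cyclic LSC,IRb,SSC,IRa order")

    @classmethod
    def from_lengths(cls, lsc_len: int, ir_len: int, ssc_len: int) -> "RegionPartition":
        n = lsc_len + ssc_len + 2 * ir_len
        a = lsc_len
        b = a + ir_len
        c = b + ssc_len
        return cls(lsc=(0, a), irb=(a, b), ssc=(b, c), ira=(c, n), genome_length=n)

    @property
    def is_normalized(self) -> bool:
        return self.lsc[0] == 0 and self.ira[1] == self.genome_length

    @property
    def lsc_len(self) -> int:
        return self.lsc[1] - self.lsc[0]

    @property
    def ssc_len(self) -> int:
        return self.ssc[1] - self.ssc[0]

    @property
    def ir_len(self) -> int:
        return self.irb[1] - self.irb[0]

    def region_of(self, pos: int) -> str:
        """Name of the region containing circular position ``pos``."""
        n = self.genome_length
        pos %= n
        for name, (s, e) in self.items():
            if s <= pos < e or s <= pos + n < e:
                return name
        raise PlastomeError(f"position {pos} not covered by partition")

    def items(self) -> list[tuple[str, Interval]]:
        return [
            ("LSC", self.lsc),
            ("IRb", self.irb),
            ("SSC", self.ssc),
            ("IRa", self.ira),
        ]

    def junctions(self) -> list[tuple[str, int]]:
        """Junction names and positions in normalized coordinates."""
        return [
            ("LSC/IRb", self.lsc[1]),
            ("IRb/SSC", self.irb[1]),
            ("SSC/IRa", self.ssc[1]),
            ("IRa/LSC", self.ira[1]),
        ]


@dataclass
class Plastome:
    """A named circular plastid genome with annotations and, once computed,
    its quadripartite region partition."""

    name: str
    sequence: str
    annotations: AnnotationSet = field(default_factory=AnnotationSet)
    partition: Optional[RegionPartition] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PlastomeError(f"{self.name}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise PlastomeError(f"{self.name}: non-ACGTN characters {sorted(bad)}")
        n = len(self.sequence)
        for f in self.annotations:
            if f.end > n:
                raise PlastomeError(
                    f"{self.name}: feature {f.gene_name} exceeds sequence length "
                    f"({f.end} > {n})"
                )
        if self.partition is not None and self.partition.genome_length != n:
            raise PlastomeError(f"{self.name}: partition length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_fraction(self.sequence)

    def region_sequence(self, region: str) -> str:
        if self.partition is None:
            raise PlastomeError(f"{self.name}: no partition computed")
        interval = dict(self.partition.items())[region]
        s, e = interval
        doubled = self.sequence + self.sequence
        return doubled[s:e]


@dataclass
class Alignment:
    """A gapped sequence set (pairwise or multiple); rows share one length."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if not self.seqs:
            raise PlastomeError("alignment has no rows")
        if len(self.ids) != len(self.seqs):
            raise PlastomeError("ids/seqs length mismatch")
        self.seqs = [s.upper() for s in self.seqs]
        width = len(self.seqs[0])
        for name, s in zip(self.ids, self.seqs):
            if len(s) != width:
                raise PlastomeError(f"ragged alignment: row {name!r}")
        for col in range(width) if width * len(self.seqs) <= 2_000_000 else []:
            if all(s[col] == "-" for s in self.seqs):
                raise PlastomeError(f"all-gap column at {col}")

    @property
    def width(self) -> int:
        return len(self.seqs[0])

    def row(self, name: str) -> str:
        return self.seqs[self.ids.index(name)]

    def degapped(self, index: int) -> str:
        return self.seqs[index].replace("-", "")
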