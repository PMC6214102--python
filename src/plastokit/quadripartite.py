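"""Quadripartite structure: inverted-repeat detection, normalization and
Table-style region summaries.

Plastomes carry two identical repeats in opposite orientation (IRa/IRb)
separating a large and a small single-copy region.  Detection here is
exact-match: k-mer seeds (k = 31 by default) between the circular sequence
and its reverse complement are chained on diagonals and extended to
maximal runs; the longest pair of disjoint exact reverse-complement
copies at least ``min_ir_len`` long wins.  Exactness keeps the result
deterministic; a mismatch-tolerant mode is deliberately not offered.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

import pandas as pd

from .model import (
    AnnotationSet,
    GeneFeature,
    Plastome,
    PlastomeError,
    RegionPartition,
    gc_fraction,
    revcomp,
)


class NoIRFound(PlastomeError):
    """No exact reverse-complement repeat pair of the required length."""


class DegenerateStructure(PlastomeError):
    """Repeats cover more than 90% of the genome."""


def _maximal_rc_matches(sequence: str, k: int) -> list[tuple[int, int, int]]:
    """All maximal circular matches between the sequence and its reverse
    complement, as (start_a, start_b, length) with starts mod n.

    A match means circular interval B of the genome is the exact reverse
    complement of circular interval A.
    """
    n = len(sequence)
    s2 = sequence + sequence
    rc2 = revcomp(sequence) * 2

    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(s2) - k + 1):
        index[s2[i : i + k]].append(i)

    # collect seed hits grouped by diagonal d = i - j; j ranges over the
    # doubled reverse complement so wrap-crossing matches appear unbroken
    diagonals: dict[int, list[int]] = defaultdict(list)
    for j in range(len(rc2) - k + 1):
        for i in index.get(rc2[j : j + k], ()):
            diagonals[i - j].append(j)

    raw: set[tuple[int, int, int]] = set()
    for d, js in diagonals.items():
        js.sort()
        run_start = prev = js[0]
        for j in js[1:] + [js[-1] + 2]:
            if j == prev + 1:
                prev = j
                continue
            length = min(prev - run_start + k, n)
            i0 = run_start + d
            a = i0 % n
            b = (n - run_start - length) % n
            lo, hi = sorted([(a, length), (b, length)])
            raw.add((lo[0], hi[0], length))
            run_start = prev = j
    return sorted(raw)


def _circ_disjoint(a: int, b: int, length: int, n: int) -> bool:
    return (b - a) % n >= length and (a - b) % n >= length


def detect_inverted_repeats(
    sequence: str, min_ir_len: int = 1000, k: int = 31
) -> RegionPartition:
    """Partition a circular sequence into LSC, IRb, SSC, IRa.

    Returns the maximal-length pair of disjoint exact reverse-complement
    repeats of at least ``min_ir_len`` bases; of the two single-copy arcs
    between them the longer is LSC.  Ties on repeat length break toward
    the smallest start coordinate.  The returned partition is expressed in
    the input's own (possibly rotated) coordinates; see :func:`normalize`.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if n < 2 * min_ir_len + 2:
        raise NoIRFound(
            f"sequence of {n} bases cannot hold two repeats of {min_ir_len}"
        )
    k = min(k, min_ir_len)
    candidates = [
        (a, b, length)
        for a, b, length in _maximal_rc_matches(sequence, k)
        if length >= min_ir_len and _circ_disjoint(a, b, length, n)
    ]
    if not candidates:
        raise NoIRFound(f"no reverse-complement repeat pair >= {min_ir_len} bases")
    best_len = max(c[2] for c in candidates)
    a, b, ir_len = min(c for c in candidates if c[2] == best_len)
    if 2 * ir_len > 0.9 * n:
        raise DegenerateStructure(
            f"repeats of {ir_len} bases cover more than 90% of the {n}-base genome"
        )

    # the two single-copy arcs between the repeat copies; the longer arc is
    # LSC and the copy immediately following it (clockwise) is IRb
    gap_ab = (b - (a + ir_len)) % n  # arc from end of copy A to start of copy B
    gap_ba = (a - (b + ir_len)) % n  # arc from end of copy B to start of copy A
    if gap_ab >= gap_ba:
        lsc_start, lsc_len, ssc_len = (a + ir_len) % n, gap_ab, gap_ba
    else:
        lsc_start, lsc_len, ssc_len = (b + ir_len) % n, gap_ba, gap_ab
    return RegionPartition(
        lsc=(lsc_start, lsc_start + lsc_len),
        irb=(lsc_start + lsc_len, lsc_start + lsc_len + ir_len),
        ssc=(
            lsc_start + lsc_len + ir_len,
            lsc_start + lsc_len + ir_len + ssc_len,
        ),
        ira=(
            lsc_start + lsc_len + ir_len + ssc_len,
            lsc_start + n,
        ),
        genome_length=n,
    )


def _rotate_features(
    features: list[GeneFeature], offset: int, n: int
) -> list[GeneFeature]:
    """Shift all features left by ``offset`` on the circle, splitting any
    feature that would wrap the new origin."""
    out: list[GeneFeature] = []
    used_tags: dict[str, set[int]] = defaultdict(set)
    for f in features:
        used_tags[f.gene_name.lower()].add(f.copy_tag)
    for f in features:
        exons = [((s - offset) % n, (e - offset - 1) % n + 1) for s, e in f.exons]
        head = [(s, e) for s, e in exons if s < e]
        wrapped = [(s, e) for s, e in exons if s >= e]
        if not wrapped:
            out.append(replace(f, exons=tuple(sorted(head))))
            continue
        # split wrapping exons at the origin
        parts_low = [(0, e) for s, e in wrapped] + [p for p in head if p[0] < n // 2]
        parts_high = [(s, n) for s, e in wrapped] + [p for p in head if p[0] >= n // 2]
        out.append(replace(f, exons=tuple(sorted(parts_high))))
        tag = max(used_tags[f.gene_name.lower()]) + 1
        used_tags[f.gene_name.lower()].add(tag)
        out.append(replace(f, exons=tuple(sorted(parts_low)), copy_tag=tag))
    return out


def _flip_features(features: list[GeneFeature], n: int) -> list[GeneFeature]:
    out = []
    for f in features:
        exons = tuple(sorted((n - e, n - s) for s, e in f.exons))
        strand = "-" if f.strand == "+" else "+"
        out.append(replace(f, exons=exons, strand=strand))
    return out


def normalize(plastome: Plastome, partition: RegionPartition) -> Plastome:
    """Rotate (and possibly flip) a genome into canonical orientation.

    The circle is rotated so that LSC starts at position 0 with region
    order LSC, IRb, SSC, IRa.  Both orientations satisfy that order, so
    the lexicographically smaller of the two candidate sequences is chosen
    (forward wins ties), which makes the operation idempotent and
    invariant under rotation and reverse-complementation of the input.
    """
    n = len(plastome)
    if partition.genome_length != n:
        raise PlastomeError("partition does not match sequence length")

    # forward candidate: rotate so LSC start -> 0
    off_f = partition.lsc[0] % n
    fwd = plastome.sequence[off_f:] + plastome.sequence[:off_f]

    # flipped candidate: reverse complement maps LSC end -> LSC start
    off_r = (n - (partition.lsc[1] % n)) % n
    rc = revcomp(plastome.sequence)
    rev = rc[off_r:] + rc[:off_r]

    canonical = RegionPartition.from_lengths(
        partition.lsc_len, partition.ir_len, partition.ssc_len
    )
    if fwd <= rev:
        features = _rotate_features(list(plastome.annotations), off_f, n)
        seq = fwd
    else:
        features = _flip_features(list(plastome.annotations), n)
        features = _rotate_features(features, off_r, n)
        seq = rev
    return Plastome(
        name=plastome.name,
        sequence=seq,
        annotations=AnnotationSet(features),
        partition=canonical,
    )


def verify_partition(plastome: Plastome) -> None:
    """Assert the partition invariants on a normalized genome."""
    p = plastome.partition
    if p is None:
        raise PlastomeError(f"{plastome.name}: no partition")
    irb = plastome.region_sequence("IRb")
    ira = plastome.region_sequence("IRa")
    if ira != revcomp(irb):
        raise PlastomeError(f"{plastome.name}: IRa is not the reverse complement of IRb")


@dataclass(frozen=True)
class RegionSummary:
    """One genome's row of the cross-species comparison table."""

    name: str
    total_len: int
    lsc_len: int
    ssc_len: int
    ir_len: int
    gc_pct: float
    at_pct: float
    gene_number: int
    pseudogene_number: int
    ir_gene_number: int
    protein_coding_number: int
    rrna_number: int
    trna_number: int
    protein_coding_pct: float
    rrna_pct: float
    trna_pct: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _majority_region(feature: GeneFeature, partition: RegionPartition) -> str:
    """Region holding the majority of the feature's span (normalized
    coordinates, no wrapping)."""
    overlaps = {name: 0 for name, _ in partition.items()}
    for name, (s, e) in partition.items():
        ov = min(e, feature.end) - max(s, feature.start)
        if ov > 0:
            overlaps[name] += ov
    return max(overlaps, key=lambda r: (overlaps[r], r))


def region_summary(plastome: Plastome) -> RegionSummary:
    """Counts and percentages for the basic-characteristics table.

    Category percentages recompute as 100 * count / gene_number rounded to
    2 decimals; pseudogenes count toward the gene number.  IR-resident
    genes are assigned by majority overlap.
    """
    p = plastome.partition
    if p is None:
        raise PlastomeError(f"{plastome.name}: partition required for summary")
    counts = plastome.annotations.category_counts()
    total_genes = len(plastome.annotations)
    gc = gc_fraction(plastome.sequence) * 100
    ir_genes = sum(
        1
        for f in plastome.annotations
        if _majority_region(f, p) in ("IRb", "IRa")
    )

    def pct(x: int) -> float:
        return round(100 * x / total_genes, 2) if total_genes else 0.0

    return RegionSummary(
        name=plastome.name,
        total_len=len(plastome),
        lsc_len=p.lsc_len,
        ssc_len=p.ssc_len,
        ir_len=p.ir_len,
        gc_pct=round(gc, 2),
        at_pct=round(100 - gc, 2),
        gene_number=total_genes,
        pseudogene_number=counts["pseudogene"],
        ir_gene_number=ir_genes,
        protein_coding_number=counts["protein_coding"],
        rrna_number=counts["rRNA"],
        trna_number=counts["tRNA"],
        protein_coding_pct=pct(counts["protein_coding"]),
        rrna_pct=pct(counts["rRNA"]),
        trna_pct=pct(counts["tRNA"]),
    )


def summary_table(cohort: list[Plastome]) -> pd.DataFrame:
    """Cross-species summary, one row per genome."""
    return pd.DataFrame([region_summary(p).as_dict() for p in cohort])
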