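"""Per-gene Ka/Ks via codon-aware alignment and Nei–Gojobori (1986)
counting.

For each shared gene the two proteins are aligned globally (BLOSUM62,
affine gaps), the alignment is back-translated onto the source codons,
and synonymous/nonsynonymous sites and differences are counted per the
NG86 scheme: per-codon site fractions from the nine single-base
neighbors (mutations to stop codons are nonsynonymous), pathway
averaging for multi-difference codon pairs (pathways through stop codons
excluded unless all are), Jukes–Cantor correction
d = -(3/4)·ln(1 - 4p/3), and the Ka/Ks ratio classified as positive
(> 1), neutral (= 1 within tolerance), or purifying (< 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import isclose, log
from typing import Optional

import pandas as pd

from ._pairwise import align_protein
from .model import Plastome, PlastomeError, splice

_BASES = "TCAG"
_STOPS = {"TAA", "TAG", "TGA"}
_ALL = [a + b + c for a in _BASES for b in _BASES for c in _BASES]


def _translate(codon: str) -> str:
    from Bio.Seq import Seq

    return "*" if codon in _STOPS else str(Seq(codon).translate(table=11))


_AA = {c: _translate(c) for c in _ALL}


def syn_sites(codon: str) -> float:
    """Synonymous site count of a sense codon (NG86).

    Each position contributes (synonymous neighbors)/3; a neighbor that
    is a stop codon is nonsynonymous.
    """
    if codon in _STOPS:
        raise PlastomeError(f"stop codon {codon} has no site decomposition")
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in _STOPS and _AA[alt] == _AA[codon]:
                syn += 1
        s += syn / 3
    return s


_SYN_SITES = {c: syn_sites(c) for c in _ALL if c not in _STOPS}


def pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over minimal mutational pathways.

    Pathways passing through a stop codon are excluded; when every
    pathway does, all are included.
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in permutations(diffs):
        cur = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS and nxt != c2:
                through_stop = True
            if _AA.get(cur, "*") == _AA.get(nxt, "*") and nxt not in _STOPS and cur not in _STOPS:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, through_stop))
    valid = [(s, n) for s, n, t in paths if not t]
    if not valid:
        valid = [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 distance; undefined at or beyond saturation (p >= 3/4)."""
    if p < 0:
        raise PlastomeError("negative proportion")
    if p >= 0.75:
        return None
    return 0.0 if p == 0 else -0.75 * log(1 - 4 * p / 3)


def classify_selection(ratio: Optional[float], tol: float = 1e-9) -> str:
    """Ka/Ks > 1 positive, = 1 neutral, < 1 purifying, None undefined."""
    if ratio is None:
        return "undefined"
    if ratio < 0:
        raise PlastomeError("negative Ka/Ks ratio")
    if isclose(ratio, 1.0, abs_tol=tol):
        return "neutral"
    return "positive" if ratio > 1 else "purifying"


@dataclass(frozen=True)
class KaKsResult:
    gene_name: str
    codons_compared: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: Optional[float]
    Ka: Optional[float]
    ratio: Optional[float]
    classification: str

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def align_proteins(a: str, b: str) -> tuple[str, str]:
    """Global BLOSUM62 alignment (gap open -10, extend -1), deterministic
    tie-breaking shared with the DNA aligner."""
    if not a or not b:
        raise PlastomeError("empty protein sequence")
    aa, bb, _ = align_protein(a, b)
    return aa, bb


def codon_alignment(
    protein_alignment: tuple[str, str], cds_a: str, cds_b: str
) -> tuple[str, str]:
    """Back-translate a protein alignment onto the source codons.

    Each residue column expands to its codon; gap columns expand to three
    gaps.  Each CDS must translate to its aligned protein (terminal stop
    trimmed)."""
    pa, pb = protein_alignment
    out = []
    for prot, cds in ((pa, cds_a), (pb, cds_b)):
        degapped = prot.replace("-", "")
        trimmed = cds[: 3 * len(degapped)]
        for i, res in enumerate(degapped):
            codon = trimmed[3 * i : 3 * i + 3]
            if len(codon) < 3:
                raise PlastomeError(
                    f"CDS shorter than protein at residue {i} ({res})"
                )
            aa = _AA.get(codon, "X")
            if res not in ("X", aa) and aa != "X":
                raise PlastomeError(
                    f"translation mismatch at residue {i}: {codon} -> {aa} != {res}"
                )
        row = []
        cursor = 0
        for res in prot:
            if res == "-":
                row.append("---")
            else:
                row.append(trimmed[3 * cursor : 3 * cursor + 3])
                cursor += 1
        out.append("".join(row))
    if len(out[0]) != len(out[1]) or len(out[0]) % 3:
        raise PlastomeError("codon alignment construction failed")
    return out[0], out[1]


def ng86(codon_aln: tuple[str, str], gene_name: str = "") -> KaKsResult:
    """NG86 Ka/Ks from a codon alignment.

    Codon columns containing gaps, Ns or stop codons are skipped.  S is
    averaged over the two sequences; multi-difference codons are pathway
    averaged.  Ks = 0 (or an undefined JC correction) leaves the ratio
    undefined.
    """
    a, b = codon_aln
    if len(a) != len(b) or len(a) % 3:
        raise PlastomeError("codon alignment rows must share a length divisible by 3")
    s_a = s_b = 0.0
    sd = nd = 0.0
    ncod = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        if ca in _STOPS or cb in _STOPS:
            continue
        ncod += 1
        s_a += _SYN_SITES[ca]
        s_b += _SYN_SITES[cb]
        d_s, d_n = pathway_counts(ca, cb)
        sd += d_s
        nd += d_n
    if ncod == 0:
        raise PlastomeError(f"{gene_name}: no comparable codon pairs")
    S = (s_a + s_b) / 2
    N = 3 * ncod - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    if Ks is None or Ka is None or Ks == 0:
        ratio = None
    else:
        ratio = Ka / Ks
    return KaKsResult(
        gene_name=gene_name, codons_compared=ncod, S=S, N=N, Sd=sd, Nd=nd,
        pS=pS, pN=pN, Ks=Ks, Ka=Ka, ratio=ratio,
        classification=classify_selection(ratio),
    )


def gene_kaks(
    ref: Plastome, alt: Plastome, gene_name: str
) -> Optional[KaKsResult]:
    """NG86 for one shared gene (copy_tag 0 representatives)."""
    fa = ref.annotations.get(gene_name, 0)
    fb = alt.annotations.get(gene_name, 0)
    if fa is None or fb is None:
        return None
    cds_a = splice(ref.sequence, fa)
    cds_b = splice(alt.sequence, fb)
    pa = _protein(cds_a)
    pb = _protein(cds_b)
    if not pa or not pb:
        return None
    aln = align_proteins(pa, pb)
    codon_aln = codon_alignment(aln, cds_a, cds_b)
    return ng86(codon_aln, gene_name=gene_name)


def _protein(cds: str) -> str:
    """Translate a CDS for alignment: internal stops become X, the
    terminal stop is trimmed, trailing partial codons are dropped."""
    aa = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            aa.append("X")
        elif codon in _STOPS:
            aa.append("*")
        else:
            aa.append(_AA[codon])
    if aa and aa[-1] == "*":
        aa.pop()
    return "".join("X" if c == "*" else c for c in aa)


def kaks_scan(
    ref: Plastome, alt: Plastome, genes: Optional[list[str]] = None
) -> pd.DataFrame:
    """Ka/Ks for every shared protein-coding gene of a genome pair."""
    if genes is None:
        ref_names = {
            f.gene_name for f in ref.annotations if f.category == "protein_coding"
        }
        alt_names = {
            f.gene_name for f in alt.annotations if f.category == "protein_coding"
        }
        genes = sorted(ref_names & alt_names)
    rows = []
    for g in genes:
        res = gene_kaks(ref, alt, g)
        if res is not None:
            row = res.as_dict()
            row["sample"] = alt.name
            rows.append(row)
    cols = ["sample", "gene_name", "codons_compared", "S", "N", "Sd", "Nd",
            "pS", "pN", "Ks", "Ka", "ratio", "classification"]
    return pd.DataFrame(rows, columns=cols)
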