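"""Pairwise alignment (against an exhaustive DP oracle), variant calling
round trips, indel normalization and summaries."""

from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastokit._pairwise import AlignmentError, align_dna
from plastokit.model import Alignment, AnnotationSet, GeneFeature, Plastome
from plastokit.simulate import mutate_genotype, true_alignment
from plastokit.variants import (
    call_variants,
    classify_position,
    pairwise_align,
    variant_summary,
)
from conftest import small_config, small_divergence
from plastokit.simulate import generate_cohort, generate_reference


# --- exhaustive alignment-score oracle (tiny strings) ----------------------

MATCH, MISMATCH, GAP_OPEN, GAP_EXT = 2, -3, -5, -2


def oracle_score(a: str, b: str) -> float:
    """Best global affine score by exhaustive recursion over alignments;
    a gap of length g costs GAP_OPEN + g * GAP_EXT.  ``state`` is the move
    that PRODUCED cell (i, j), so every gap run pays its opening once."""
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == 0 and j == 0:
            return 0.0 if state == "M" else NEG
        if i < 0 or j < 0:
            return NEG
        if state == "M":
            if i == 0 or j == 0:
                return NEG
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            return max(best(i - 1, j - 1, p) for p in "MDI") + s
        if state == "D":
            if i == 0:
                return NEG
            return max(
                best(i - 1, j, "D") + GAP_EXT,
                max(best(i - 1, j, p) for p in "MI") + GAP_OPEN + GAP_EXT,
            )
        if j == 0:
            return NEG
        return max(
            best(i, j - 1, "I") + GAP_EXT,
            max(best(i, j - 1, p) for p in "MD") + GAP_OPEN + GAP_EXT,
        )

    return max(best(len(a), len(b), s) for s in "MDI")


@pytest.mark.parametrize(
    "a,b",
    [
        ("ACGTACGT", "ACGACGT"),
        ("ACGT", "ACGT"),
        ("AAAA", "AATA"),
        ("GATTACA", "GCATGCT"),
        ("ACCCGT", "AGT"),
        ("A", "TTTT"),
        ("ACGTTTACG", "ACGACG"),
    ],
)
def test_affine_aligner_matches_exhaustive_oracle_score(a, b):
    aa, bb, score = align_dna(a, b)
    assert score == oracle_score(a, b)
    # the emitted alignment must realize the claimed score
    realized, gap = 0, None
    for ca, cb in zip(aa, bb):
        if ca != "-" and cb != "-":
            realized += MATCH if ca == cb else MISMATCH
            gap = None
        else:
            which = "a" if ca == "-" else "b"
            realized += GAP_EXT if gap == which else GAP_OPEN + GAP_EXT
            gap = which
    assert realized == score


def test_aligner_matches_oracle_on_random_strings(rng):
    for _ in range(25):
        a = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 9)))
        b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 9)))
        _, _, score = align_dna(a, b)
        assert score == oracle_score(a, b)


dna = st.text(alphabet="ACGT", min_size=1, max_size=8)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(a=dna, b=dna)
def test_aligner_score_equals_oracle_property(a, b):
    _, _, score = align_dna(a, b)
    assert score == oracle_score(a, b)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    ref=st.text(alphabet="ACGT", min_size=20, max_size=60),
    start=st.integers(min_value=1, max_value=15),
    length=st.integers(min_value=1, max_value=5),
)
def test_left_normalized_deletion_is_a_faithful_rewriting(ref, start, length):
    """Re-applying a deletion at its normalized anchor reproduces the
    same mutated sequence (normalization changes coordinates, never the
    edit's effect)."""
    from plastokit.simulate import left_align_indel

    if start + length > len(ref):
        return
    anchor, allele = left_align_indel(ref, start, length, "del")
    s2 = anchor + 1
    assert ref[s2:s2 + length] == allele
    assert ref[:start] + ref[start + length:] == ref[:s2] + ref[s2 + length:]


def test_single_base_deletion_is_anchored_at_reference_position_three():
    aln = pairwise_align("ACGTACGT", "ACGACGT")
    plastome = Plastome(name="r", sequence="ACGTACGT")
    table = call_variants(aln, 0, plastome, min_indel_len=1)
    assert len(table.variants) == 1
    row = table.variants.iloc[0]
    assert row["type"] == "deletion"
    assert row["length"] == 1
    # left-aligned anchor: base before the deleted run
    assert row["ref_position"] == 2


def test_identical_sequences_align_gapless_and_call_nothing():
    aln = pairwise_align("ACGT" * 50, "ACGT" * 50)
    assert "-" not in aln.seqs[0] + aln.seqs[1]
    p = Plastome(name="r", sequence="ACGT" * 50)
    assert call_variants(aln, 0, p).variants.empty


def test_band_precondition_rejects_very_different_lengths():
    with pytest.raises(AlignmentError):
        pairwise_align("ACGT" * 10, "ACGT" * 1000, band=100)


def test_left_alignment_in_homopolymer_is_position_invariant():
    """Deleting any 5-base window of a homopolymer run normalizes to the
    same anchor."""
    ref = "ACGT" + "A" * 12 + "CCGGTT"
    positions = set()
    for cut in range(4, 4 + 8):
        alt = ref[:cut] + ref[cut + 5:]
        aln = Alignment(ids=["r", "s"],
                        seqs=[ref, ref[:cut] + "-" * 5 + ref[cut + 5:]])
        p = Plastome(name="r", sequence=ref)
        t = call_variants(aln, 0, p, min_indel_len=5)
        assert len(t.variants) == 1
        positions.add(int(t.variants.iloc[0]["ref_position"]))
    assert len(positions) == 1
    assert positions.pop() == 3  # base before the homopolymer run


def test_insertion_deletion_symmetry_under_role_swap():
    ref = "ACGTTTGCAACGGT"
    alt = "ACGTTTGCTTAGCAACGGT"[:len(ref) + 3]
    alt = "ACGTTTGC" + "TAG" + "AACGGT"
    aln_fwd = pairwise_align(ref, alt)
    p_ref = Plastome(name="r", sequence=ref)
    ins = call_variants(aln_fwd, 0, p_ref, min_indel_len=1).variants
    aln_rev = pairwise_align(alt, ref)
    p_alt = Plastome(name="a", sequence=alt)
    dele = call_variants(aln_rev, 0, p_alt, min_indel_len=1).variants
    assert list(ins["type"]) == ["insertion"]
    assert list(dele["type"]) == ["deletion"]
    assert ins.iloc[0]["length"] == dele.iloc[0]["length"] == 3


def test_short_indels_screened_but_counted():
    ref = "ACGTTACC" + "GCTAGCTA" * 4 + "TTGCAAGG"
    alt = ref[:10] + ref[14:]  # 4-base deletion
    aln = pairwise_align(ref, alt)
    p = Plastome(name="r", sequence=ref)
    t = call_variants(aln, 0, p, min_indel_len=5)
    assert t.variants.empty
    assert t.small_indel_count == 1
    assert t.small_indels.iloc[0]["length"] == 4


def test_round_trip_with_true_alignment_matches_manifest(small_pair):
    cohort, manifests = small_pair
    aln = true_alignment(cohort[0], cohort[1], manifests[0])
    called = call_variants(aln, 0, cohort[0], min_indel_len=5).variants
    truth = manifests[0].variants
    truth_keep = truth[(truth["type"] == "SNP") | (truth["length"] >= 5)]
    cols = ["type", "ref_position", "length", "region", "context"]
    a = called[cols].sort_values(cols).reset_index(drop=True)
    b = truth_keep[cols].sort_values(cols).reset_index(drop=True)
    assert a.equals(b)


def test_round_trip_with_internal_aligner_matches_manifest(small_pair):
    cohort, manifests = small_pair
    aln = pairwise_align(cohort[0].sequence, cohort[1].sequence)
    aln.ids = [cohort[0].name, cohort[1].name]
    called = call_variants(aln, 0, cohort[0], min_indel_len=5).variants
    truth = manifests[0].variants
    truth_keep = truth[(truth["type"] == "SNP") | (truth["length"] >= 5)]
    cols = ["type", "ref_position", "length"]
    a = called[cols].sort_values(cols).reset_index(drop=True)
    b = truth_keep[cols].sort_values(cols).reset_index(drop=True)
    assert a.equals(b)


def test_intronic_and_genic_context_classification():
    feats = [GeneFeature("g1", "protein_coding", "+", ((100, 200), (300, 400)))]
    p = Plastome(name="x", sequence="A" * 1000,
                 annotations=AnnotationSet(feats))
    assert classify_position(p, 150)[0] == "genic"
    assert classify_position(p, 250)[0] == "intronic"
    ctx, fl, fr = classify_position(p, 500)
    assert ctx == "intergenic"
    assert fl == "g1"


def test_planted_intronic_indel_is_classified_intronic():
    cfg = small_config(seed=21)
    ref = generate_reference(cfg)
    div = small_divergence(
        31, snp_rate_sc=0, snp_rate_ir=0,
        indel_plan=[("LSC", "del", 6, "intronic")],
    )
    mut, manifest = mutate_genotype(ref, div, "m")
    assert list(manifest.variants["context"]) == ["intronic"]
    aln = true_alignment(ref, mut, manifest)
    called = call_variants(aln, 0, ref).variants
    assert list(called["context"]) == ["intronic"]


def test_variant_summary_marginals():
    cohort, manifests = generate_cohort(
        small_config(seed=23, divergence=[small_divergence(41)])
    )
    aln = true_alignment(cohort[0], cohort[1], manifests[0])
    table = call_variants(aln, 0, cohort[0])
    s = variant_summary(table)
    assert s["by_type"]["count"].sum() == len(table.variants)
    ins = int(s["by_type"]["count"].get("insertion", 0))
    assert ins == (table.variants["type"] == "insertion").sum()


def test_empty_table_gives_all_zero_summary():
    p = Plastome(name="r", sequence="ACGT" * 10)
    aln = Alignment(ids=["r", "s"], seqs=["ACGT" * 10, "ACGT" * 10])
    s = variant_summary(call_variants(aln, 0, p))
    assert all(df.empty for df in s.values())
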