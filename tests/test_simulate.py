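"""Generator contracts: geometry, determinism, planted-truth bookkeeping."""

import numpy as np
import pytest

from plastokit.model import PlastomeError, gc_fraction, revcomp
from plastokit.simulate import (
    CohortConfig,
    DivergenceConfig,
    default_cohort_config,
    generate_cohort,
    generate_reference,
    mutate_genotype,
    true_alignment,
)
from conftest import small_config, small_divergence


def test_reference_geometry_matches_config(reference):
    # 87,962 + 19,201 + 2 x 26,386 = 159,935
    assert len(reference) == 159_935
    p = reference.partition
    assert (p.lsc_len, p.ir_len, p.ssc_len) == (87_962, 26_386, 19_201)


def test_ira_is_exact_reverse_complement_of_irb(reference):
    assert reference.region_sequence("IRa") == revcomp(
        reference.region_sequence("IRb")
    )


def test_same_seed_is_byte_identical():
    a = generate_reference(small_config(seed=9))
    b = generate_reference(small_config(seed=9))
    assert a.sequence == b.sequence
    assert [f.exons for f in a.annotations] == [f.exons for f in b.annotations]


def test_different_seed_changes_sequence():
    a = generate_reference(small_config(seed=9))
    b = generate_reference(small_config(seed=10))
    assert a.sequence != b.sequence


def test_gc_content_hits_target_within_binomial_bound(reference):
    # binomial concentration at n ~ 1.6e5: 3 sd ~ 0.0036
    assert abs(reference.gc - 0.3659) <= 0.003


def test_at_only_third_positions_gives_gc3_zero():
    from plastokit.codon import genome_usage

    cfg = small_config(seed=5)
    cfg.at_only_third = True
    ref = generate_reference(cfg)
    usage = genome_usage(ref, min_len=300)
    assert usage.gc3 == 0.0


def test_zero_rates_and_no_indels_reproduce_reference():
    cfg = small_config(seed=4)
    ref = generate_reference(cfg)
    div = DivergenceConfig(snp_rate_sc=0, snp_rate_ir=0, indel_events=[], seed=1)
    mut, manifest = mutate_genotype(ref, div, "clone")
    assert mut.sequence == ref.sequence
    assert manifest.variants.empty


def test_planted_indel_manifest_bookkeeping():
    """11 insertions + 4 deletions (>= 5 bp, all LSC) give 15 manifest
    events, all in the LSC region."""
    cfg = small_config(seed=6)
    ref = generate_reference(cfg)
    plan = [("LSC", "ins", 5 + i % 4, "intergenic") for i in range(11)]
    plan += [("LSC", "del", 5 + i, "intergenic") for i in range(4)]
    div = DivergenceConfig(snp_rate_sc=0, snp_rate_ir=0, indel_plan=plan, seed=2)
    mut, manifest = mutate_genotype(ref, div, "m")
    v = manifest.variants
    assert len(v) == 15
    assert set(v["region"]) == {"LSC"}
    assert (v["type"] == "insertion").sum() == 11
    assert (v["type"] == "deletion").sum() == 4
    assert (v["length"] >= 5).all()
    net = (v.loc[v["type"] == "insertion", "length"].sum()
           - v.loc[v["type"] == "deletion", "length"].sum())
    assert len(mut) == len(ref) + net


def test_ir_edits_are_mirrored_and_preserve_repeat_identity():
    cfg = small_config(seed=7)
    ref = generate_reference(cfg)
    div = DivergenceConfig(
        snp_rate_sc=0, snp_rate_ir=2e-3,
        indel_plan=[("IRb", "ins", 6, "intergenic")], seed=3,
    )
    mut, manifest = mutate_genotype(ref, div, "m")
    v = manifest.variants
    assert (v["mirrored"].sum()) == (~v["mirrored"]).sum()  # one mirror each
    assert set(v["region"]) <= {"IRb", "IRa"}
    p = mut.partition
    n = len(mut)
    irb = mut.sequence[p.irb[0]:p.irb[1]]
    ira = mut.sequence[p.ira[0]:p.ira[1]]
    assert ira == revcomp(irb)


def test_sc_variants_exceed_ir_variants_at_ordered_rates():
    cfg = small_config(seed=8)
    ref = generate_reference(cfg)
    div = DivergenceConfig(snp_rate_sc=1e-3, snp_rate_ir=1e-4,
                           indel_events=[], seed=4)
    _, manifest = mutate_genotype(ref, div, "m")
    v = manifest.variants
    sc = v["region"].isin(["LSC", "SSC"]).sum()
    ir = v["region"].isin(["IRa", "IRb"]).sum()
    assert sc > ir


def test_cohort_rejects_fewer_than_two_genotypes():
    cfg = small_config(seed=1, n_genotypes=1)
    with pytest.raises(PlastomeError):
        generate_cohort(cfg)


def test_cohort_names_are_distinct_and_mutants_carry_manifests():
    cohort, manifests = generate_cohort(
        small_config(seed=2, n_genotypes=3,
                     divergence=[small_divergence(5), small_divergence(6)])
    )
    names = [g.name for g in cohort]
    assert len(set(names)) == 3
    assert len(manifests) == 2


def test_gene_deletions_remove_annotation_only():
    cfg = small_config(seed=2, n_genotypes=2, divergence=[small_divergence(5)])
    cfg.gene_deletions = {cfg.genotype_names()[1]: ["geneC"]}
    cohort, _ = generate_cohort(cfg)
    assert cohort[0].annotations.by_name("geneC")
    assert not cohort[1].annotations.by_name("geneC")


def test_true_alignment_degaps_to_both_sequences(small_pair):
    cohort, manifests = small_pair
    aln = true_alignment(cohort[0], cohort[1], manifests[0])
    assert aln.seqs[0].replace("-", "") == cohort[0].sequence
    assert aln.seqs[1].replace("-", "") == cohort[1].sequence


def test_default_cohort_emulates_study_shape(default_cohort):
    cohort, manifests = default_cohort
    assert [g.name for g in cohort] == [
        "Phop_HB1", "Phop_HB2", "Puss_JBL", "Pcom_ERC", "Pbet_BET"
    ]
    hb2 = manifests[0].variants
    ind = hb2[hb2["type"] != "SNP"]
    assert len(ind) == 15
    assert (ind["type"] == "insertion").sum() == 11
    assert (ind["type"] == "deletion").sum() == 4
    assert set(ind["region"]) == {"LSC"}
    assert len(cohort[1]) - len(cohort[0]) == 46  # HB-2 is 46 bp longer


def test_overlapping_planted_indels_are_rejected():
    cfg = small_config(seed=6)
    ref = generate_reference(cfg)
    from plastokit.simulate import IndelEvent

    div = DivergenceConfig(
        snp_rate_sc=0, snp_rate_ir=0,
        indel_events=[IndelEvent("LSC", 500, "del", 10),
                      IndelEvent("LSC", 505, "del", 10)],
        seed=1,
    )
    with pytest.raises(PlastomeError):
        mutate_genotype(ref, div, "m")


def test_gene_plan_overflow_is_rejected_naming_region():
    cfg = small_config(seed=1)
    cfg.ssc_len = 400  # geneE + geneF cannot fit
    with pytest.raises(PlastomeError, match="SSC"):
        generate_reference(cfg)
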