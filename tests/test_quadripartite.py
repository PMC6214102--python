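"""IR detection against a brute-force oracle, normalization invariances,
and summary arithmetic."""

import numpy as np
import pytest

from plastokit.model import Plastome, RegionPartition, revcomp
from plastokit.quadripartite import (
    DegenerateStructure,
    NoIRFound,
    detect_inverted_repeats,
    normalize,
    region_summary,
    verify_partition,
)
from conftest import small_config
from plastokit.simulate import generate_reference


def brute_force_ir(sequence: str, min_len: int):
    """Oracle: maximal disjoint exact reverse-complement repeat pair on the
    circle, by exhaustive run-length dynamic programming over all
    substring pairs of the doubled sequence versus its doubled reverse
    complement.  Independent of the k-mer seeding the implementation uses.
    """
    n = len(sequence)
    s2 = np.frombuffer((sequence * 2).encode(), dtype="S1")
    rc2 = np.frombuffer((revcomp(sequence) * 2).encode(), dtype="S1")
    m = len(rc2)
    candidates = []

    def record(i_end: int, j_end: int, run: int) -> None:
        L = min(run, n)
        i = i_end - run + 1  # run start in s2
        j = j_end - run + 1  # run start in rc2
        # a circular match may be truncated in the doubled coordinates;
        # keep only full-length representations
        a = i % n
        b = (n - j - L) % n
        if (b - a) % n >= L and (a - b) % n >= L:
            candidates.append((L, *sorted((a, b))))

    prev = np.zeros(m, dtype=np.int32)
    for i in range(len(s2)):
        eq = s2[i] == rc2
        cur = np.zeros(m, dtype=np.int32)
        cur[0] = 1 if eq[0] else 0
        cur[1:] = np.where(eq[1:], prev[:-1] + 1, 0)
        # runs ending at row i-1 that do not continue into row i
        cont = np.zeros(m, dtype=bool)
        cont[:-1] = eq[1:]
        for j in np.flatnonzero((prev >= min_len) & ~cont):
            record(i - 1, int(j), int(prev[j]))
        prev = cur
    for j in np.flatnonzero(prev >= min_len):
        record(len(s2) - 1, int(j), int(prev[j]))
    if not candidates:
        return None
    L = max(c[0] for c in candidates)
    return min(c for c in candidates if c[0] == L)


def _planted(rng, lsc=10_000, ir=1500, ssc=2000):
    def rand(k):
        return "".join(rng.choice(list("ACGT"), size=k))

    # pin the single-copy termini so the planted repeat cannot extend by a
    # chance complementary base and is the true maximal pair
    L = "A" + rand(lsc - 2) + "A"
    S = "A" + rand(ssc - 2) + "A"
    R = rand(ir)
    return L + R + S + revcomp(R), lsc, ir, ssc


def test_detection_matches_brute_force_oracle_on_planted_structure(rng):
    seq, lsc, ir, ssc = _planted(rng, lsc=3000, ir=450, ssc=900)
    part = detect_inverted_repeats(seq, min_ir_len=200)
    oracle = brute_force_ir(seq, 200)
    assert oracle is not None
    assert part.ir_len == oracle[0] == ir
    assert (part.lsc_len, part.ssc_len) == (lsc, ssc)
    assert {part.irb[0] % len(seq), part.ira[0] % len(seq)} == {oracle[1], oracle[2]}


def test_detection_matches_oracle_under_random_rotations(rng):
    seq, _, ir, _ = _planted(rng, lsc=2000, ir=300, ssc=700)
    n = len(seq)
    for rot in rng.integers(0, n, size=4):
        rotated = seq[rot:] + seq[:rot]
        part = detect_inverted_repeats(rotated, min_ir_len=200)
        oracle = brute_force_ir(rotated, 200)
        assert part.ir_len == oracle[0] == ir
        assert {part.irb[0] % n, part.ira[0] % n} == {oracle[1], oracle[2]}


def test_spec_scale_planted_structure_is_recovered_exactly(rng):
    # 10 kb LSC + 1.5 kb repeat + 2 kb SSC + reverse complement repeat
    seq, lsc, ir, ssc = _planted(rng, lsc=10_000, ir=1500, ssc=2000)
    part = detect_inverted_repeats(seq, min_ir_len=500)
    assert (part.lsc_len, part.ir_len, part.ssc_len) == (lsc, ir, ssc)


def test_random_sequence_without_repeat_raises_noir(rng):
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    with pytest.raises(NoIRFound):
        detect_inverted_repeats(seq, min_ir_len=1000)


def test_degenerate_structure_is_rejected(rng):
    R = "".join(rng.choice(list("ACGT"), size=4800))
    seq = "AC" + R + "GT" + revcomp(R)
    with pytest.raises(DegenerateStructure):
        detect_inverted_repeats(seq, min_ir_len=1000)


def test_generator_round_trip_recovers_configured_lengths():
    cfg = small_config(seed=13)
    ref = generate_reference(cfg)
    part = detect_inverted_repeats(ref.sequence, min_ir_len=1000)
    assert (part.lsc_len, part.ir_len, part.ssc_len) == (
        cfg.lsc_len, cfg.ir_len, cfg.ssc_len
    )
    verify_partition(ref)


def test_partition_invariants_asserted_on_accepted_input(rng):
    seq, *_ = _planted(rng)
    part = detect_inverted_repeats(seq, min_ir_len=500)
    n = len(seq)
    arcs = [part.lsc, part.irb, part.ssc, part.ira]
    assert sum(e - s for s, e in arcs) == n
    doubled = seq + seq
    irb = doubled[part.irb[0]:part.irb[1]]
    ira = doubled[part.ira[0]:part.ira[1]]
    assert ira == revcomp(irb)


def test_normalize_is_idempotent_and_rotation_and_flip_invariant():
    cfg = small_config(seed=14)
    ref = generate_reference(cfg)
    n = len(ref)
    part = detect_inverted_repeats(ref.sequence, min_ir_len=1000)
    canonical = normalize(ref, part)

    again = normalize(
        canonical, detect_inverted_repeats(canonical.sequence, min_ir_len=1000)
    )
    assert again.sequence == canonical.sequence  # idempotent

    for rot in (12_345, 3, n - 7):
        rotated = Plastome(name="r", sequence=ref.sequence[rot:] + ref.sequence[:rot])
        p2 = detect_inverted_repeats(rotated.sequence, min_ir_len=1000)
        assert normalize(rotated, p2).sequence == canonical.sequence

    flipped = Plastome(name="f", sequence=revcomp(ref.sequence))
    p3 = detect_inverted_repeats(flipped.sequence, min_ir_len=1000)
    assert normalize(flipped, p3).sequence == canonical.sequence


def test_normalize_remaps_annotations_consistently():
    from plastokit.model import splice

    cfg = small_config(seed=15)
    ref = generate_reference(cfg)
    rot = 4321
    rotated = Plastome(
        name="r",
        sequence=ref.sequence[rot:] + ref.sequence[:rot],
        annotations=ref.annotations,  # deliberately stale coordinates
    )
    # instead: shift features along with the rotation
    from plastokit.quadripartite import _rotate_features
    from plastokit.model import AnnotationSet

    rotated.annotations = AnnotationSet(
        _rotate_features(list(ref.annotations), rot, len(ref))
    )
    part = detect_inverted_repeats(rotated.sequence, min_ir_len=1000)
    norm = normalize(rotated, part)
    want = {
        (f.key, splice(ref.sequence, f)) for f in ref.annotations
    }
    got = {
        (f.key, splice(norm.sequence, f)) for f in norm.annotations
    }
    if norm.sequence == ref.sequence:
        assert want == got


def test_region_summary_matches_table_arithmetic(reference):
    s = region_summary(reference)
    assert s.total_len == 159_935
    assert s.gene_number == 118
    assert s.protein_coding_number == 77
    assert s.trna_number == 31
    assert s.rrna_number == 8
    assert s.pseudogene_number == 2
    assert s.ir_gene_number == 32
    # percentages recompute from counts (2-dp rounding)
    assert s.protein_coding_pct == round(100 * 77 / 118, 2)
    assert s.rrna_pct == round(100 * 8 / 118, 2)
    assert s.trna_pct == round(100 * 31 / 118, 2)
    assert abs(s.gc_pct + s.at_pct - 100) < 0.011


def test_rrna_percentage_example():
    # a 114-gene complement with 8 rRNAs reads 7.02%
    assert round(100 * 8 / 114, 2) == 7.02


def test_gc_of_at_only_sequence_is_zero():
    p = Plastome(
        name="at", sequence="AT" * 3000,
        partition=RegionPartition.from_lengths(2000, 1500, 1000),
    )
    s = region_summary(p)
    assert s.gc_pct == 0.0
    assert s.at_pct == 100.0
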