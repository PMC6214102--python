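"""Supermatrix construction, distances, NJ (additive-matrix oracle and a
library cross-check), bootstrap, Newick round trips."""

import numpy as np
import pytest

from plastokit.model import PlastomeError
from plastokit.phylo import (
    DistanceMatrix,
    SuperMatrix,
    bootstrap,
    build_supermatrix,
    distance_matrix,
    nj_tree,
    root_with_outgroup,
    shared_genes,
    write_newick,
)


# --- random additive-tree oracle -------------------------------------------

def random_additive_tree(rng, n_taxa):
    """A random binary tree with positive branch lengths, returned as the
    exact leaf-to-leaf distance matrix plus the set of bipartitions."""
    nodes = [{"leaves": frozenset([f"t{i}"])} for i in range(n_taxa)]
    dist = {(f"t{i}", f"t{i}"): 0.0 for i in range(n_taxa)}
    leaf_depth = {f"t{i}": 0.0 for i in range(n_taxa)}
    # track distances by simulating joins with explicit path lengths
    import itertools

    # simpler: build tree structure then compute path lengths
    parent = {}
    lengths = {}
    idx = list(range(n_taxa))
    next_id = n_taxa
    children = {}
    while len(idx) > 1:
        i, j = sorted(rng.choice(len(idx), size=2, replace=False))
        a, b = idx[i], idx[j]
        la = float(rng.integers(1, 20))
        lb = float(rng.integers(1, 20))
        children[next_id] = [(a, la), (b, lb)]
        idx = [x for x in idx if x not in (a, b)] + [next_id]
        next_id += 1
    root = idx[0]

    leaves_of = {}

    def collect(node):
        if node < n_taxa:
            leaves_of[node] = {f"t{node}": 0.0}
            return leaves_of[node]
        out = {}
        for child, ln in children[node]:
            for leaf, d in collect(child).items():
                out[leaf] = d + ln
        leaves_of[node] = out
        return out

    collect(root)
    taxa = sorted(f"t{i}" for i in range(n_taxa))
    D = np.zeros((n_taxa, n_taxa))
    for node, below in leaves_of.items():
        if node < n_taxa:
            continue
        kids = children[node]
        for (c1, l1), (c2, l2) in [(kids[0], kids[1])]:
            for leaf_a, da in leaves_of[c1].items():
                for leaf_b, db in leaves_of[c2].items():
                    ia, ib = taxa.index(leaf_a), taxa.index(leaf_b)
                    D[ia, ib] = D[ib, ia] = da + l1 + db + l2
    # true bipartitions (non-trivial splits)
    all_taxa = frozenset(taxa)
    bips = set()
    for node, below in leaves_of.items():
        side = frozenset(below)
        if 1 < len(side) < n_taxa - 1:
            other = all_taxa - side
            bips.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return taxa, D, bips


def test_nj_is_exact_on_the_spec_four_taxon_matrix():
    taxa = ("A", "B", "C", "D")
    D = np.array(
        [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 0, 0]], dtype=float
    )
    D[2, 3] = D[3, 2] = 9
    D[3, 3] = 0
    tree = nj_tree(DistanceMatrix(ids=taxa, values=D))
    lengths = {l.name: l.length for l in tree.root.leaves()}
    assert lengths == {"A": 2.0, "B": 3.0, "C": 4.0, "D": 5.0}
    bips = {frozenset(k) for k in tree.bipartitions()}
    assert bips == {frozenset({"A", "B"})}
    internal = next(iter(tree.bipartitions().values()))
    assert internal.length == pytest.approx(1.0)


def test_nj_recovers_random_additive_trees_exactly(rng):
    """NJ is exact on additive matrices: topology and leaf path lengths."""
    for _ in range(100):
        n = int(rng.integers(5, 13))
        taxa, D, true_bips = random_additive_tree(rng, n)
        tree = nj_tree(DistanceMatrix(ids=tuple(taxa), values=D))
        got = {frozenset(k) for k in tree.bipartitions()}
        assert got == true_bips
        # recomputed leaf-to-leaf path lengths reproduce the input matrix
        reco = _tree_distances(tree, taxa)
        assert np.allclose(reco, D)


def _tree_distances(tree, taxa):
    import dendropy

    t = dendropy.Tree.get(data=tree.newick(), schema="newick")
    pdm = t.phylogenetic_distance_matrix()
    n = len(taxa)
    out = np.zeros((n, n))
    tax = {x.label: x for x in t.taxon_namespace}
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = pdm.distance(tax[taxa[i]], tax[taxa[j]])
    return out


def test_nj_agrees_with_scikit_bio_on_random_matrices(rng):
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj

    for _ in range(5):
        taxa, D, true_bips = random_additive_tree(rng, 7)
        ours = nj_tree(DistanceMatrix(ids=tuple(taxa), values=D))
        theirs = sk_nj(SkDM(D, ids=taxa))
        their_bips = set()
        all_taxa = frozenset(taxa)
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(taxa) - 1:
                other = all_taxa - side
                their_bips.add(min(side, other,
                                   key=lambda s: (len(s), sorted(s))))
        assert {frozenset(k) for k in ours.bipartitions()} == their_bips


def test_two_taxa_single_edge():
    tree = nj_tree(DistanceMatrix(ids=("A", "B"),
                                  values=np.array([[0.0, 3.0], [3.0, 0.0]])))
    lengths = sorted(l.length for l in tree.root.leaves())
    assert sum(lengths) == pytest.approx(3.0)


def test_distance_models_and_saturation():
    m = SuperMatrix(taxa=["a", "b"], rows=["AAAAAAAAAA", "AACAAAAAAC"],
                    partitions={})
    p = distance_matrix(m, model="p")
    assert p.values[0, 1] == pytest.approx(0.2)
    po = distance_matrix(m, model="poisson")
    assert po.values[0, 1] == pytest.approx(-np.log(0.8))
    assert po.values[0, 1] >= p.values[0, 1]
    sat = SuperMatrix(taxa=["a", "b"], rows=["AAAA", "CCCC"], partitions={})
    with pytest.raises(PlastomeError, match="saturated"):
        distance_matrix(sat, model="poisson")


def test_pairwise_deletion_ignores_gap_columns():
    m = SuperMatrix(taxa=["a", "b"], rows=["AA--AAAAAA", "AACC-AAAAC"],
                    partitions={})
    d = distance_matrix(m, model="p")
    # 7 comparable columns, 1 mismatch
    assert d.values[0, 1] == pytest.approx(1 / 7)


def test_shared_genes_excludes_planted_deletion(default_cohort):
    cohort, _ = default_cohort
    genes = shared_genes(cohort)
    assert "atpB" not in genes      # deleted in two genotypes
    assert "rbcL" in genes
    assert genes == sorted(genes)


def test_supermatrix_width_is_sum_of_partitions(default_cohort):
    cohort, _ = default_cohort
    genes = shared_genes(cohort)[:10]
    sm = build_supermatrix(cohort, genes)
    assert sm.width == sum(e - s for s, e in sm.partitions.values())
    assert len(sm.rows) == len(cohort)
    assert len({len(r) for r in sm.rows}) == 1


def test_identical_genomes_give_gapless_supermatrix(default_cohort):
    cohort, _ = default_cohort
    sm = build_supermatrix([cohort[0], cohort[0]], ["rbcL", "psbA"])
    assert "-" not in sm.rows[0] + sm.rows[1]
    assert sm.rows[0] == sm.rows[1]


def test_close_pair_are_sisters_with_high_support(default_cohort):
    cohort, _ = default_cohort
    sm = build_supermatrix(cohort, shared_genes(cohort))
    tree = bootstrap(sm, reps=100, seed=5)
    bips = {frozenset(k): node.support for k, node in tree.bipartitions().items()}
    assert bips[frozenset({"Phop_HB1", "Phop_HB2"})] >= 95


def test_single_rep_supports_are_zero_or_hundred(default_cohort):
    cohort, _ = default_cohort
    sm = build_supermatrix(cohort, shared_genes(cohort)[:15])
    tree = bootstrap(sm, reps=1, seed=3)
    supports = {n.support for n in tree.bipartitions().values()}
    assert supports <= {0, 100}


def test_bootstrap_is_seed_deterministic(default_cohort):
    cohort, _ = default_cohort
    sm = build_supermatrix(cohort, shared_genes(cohort)[:15])
    t1 = bootstrap(sm, reps=25, seed=11)
    t2 = bootstrap(sm, reps=25, seed=11)
    assert t1.newick() == t2.newick()


def test_newick_round_trip_and_outgroup_rooting(tmp_path, rng):
    import dendropy

    taxa, D, _ = random_additive_tree(rng, 6)
    tree = nj_tree(DistanceMatrix(ids=tuple(taxa), values=D))
    write_newick(tree, tmp_path / "t.nwk")
    parsed = dendropy.Tree.get(path=str(tmp_path / "t.nwk"), schema="newick")
    assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == taxa
    reco = _tree_distances(tree, taxa)
    assert np.allclose(reco, D)

    rooted = root_with_outgroup(tree, taxa[0])
    reparsed = dendropy.Tree.get(data=rooted, schema="newick")
    top = reparsed.seed_node.child_nodes()
    sides = [sorted(l.taxon.label for l in c.leaf_iter()) for c in top]
    assert [taxa[0]] in sides
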