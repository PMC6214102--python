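"""Shared-gene supermatrix, distances, neighbor-joining and bootstrap.

Protein sequences of genes present in every genome are aligned per gene
(pairwise for two taxa, star alignment onto the first taxon otherwise —
adequate for high-identity cohorts; external alignments can be supplied
instead), concatenated into a supermatrix, converted to pairwise
distances (p-distance or Poisson-corrected, with pairwise deletion of
gap columns) and clustered with the Saitou–Nei neighbor-joining
algorithm.  Supports come from column-resampling bootstrap replicates.
NJ is exact on additive matrices; ties on the Q criterion break toward
the lowest taxon-index pair and negative branch lengths are clamped to
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from typing import Optional

import numpy as np
import pandas as pd

from .kaks import _protein, align_proteins
from .model import Plastome, PlastomeError, splice


def shared_genes(cohort: list[Plastome]) -> list[str]:
    """Protein-coding genes present (copy >= 1) in every genome, sorted."""
    if len(cohort) < 2:
        raise PlastomeError("shared_genes needs at least two genomes")
    sets = []
    display: dict[str, str] = {}
    for g in cohort:
        names = set()
        for f in g.annotations:
            if f.category == "protein_coding":
                names.add(f.gene_name.lower())
                display.setdefault(f.gene_name.lower(), f.gene_name)
        sets.append(names)
    common = set.intersection(*sets)
    return sorted(display[n] for n in common)


@dataclass
class SuperMatrix:
    taxa: list[str]
    rows: list[str]
    partitions: dict[str, tuple[int, int]]  # gene -> (start, end) columns

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def _star_align(proteins: list[str]) -> list[str]:
    """Star alignment onto the first sequence.

    Each sequence is pairwise-aligned to the first; insertions relative
    to the anchor are merged per anchor position (left-justified,
    padded to the longest insertion)."""
    ref = proteins[0]
    pairs = [align_proteins(ref, p) for p in proteins[1:]]
    L = len(ref)
    ins_len = [0] * (L + 1)  # insertion slot before anchor position i
    parsed = []
    for ra, pa in pairs:
        cols: list[str] = [""] * (L + 1)   # insertions per slot
        residues: list[str] = [""] * L     # residue aligned to each anchor pos
        ri = 0
        for cr, cp in zip(ra, pa):
            if cr == "-":
                cols[ri] += cp
            else:
                residues[ri] = cp
                ri += 1
        for i in range(L + 1):
            ins_len[i] = max(ins_len[i], len(cols[i]))
        parsed.append((cols, residues))
    out = []
    # anchor row
    row = []
    for i in range(L):
        row.append("-" * ins_len[i])
        row.append(ref[i])
    row.append("-" * ins_len[L])
    out.append("".join(row))
    for cols, residues in parsed:
        row = []
        for i in range(L):
            row.append(cols[i].ljust(ins_len[i], "-"))
            row.append(residues[i] if residues[i] else "-")
        row.append(cols[L].ljust(ins_len[L], "-"))
        out.append("".join(row))
    return out


def build_supermatrix(
    cohort: list[Plastome], genes: Optional[list[str]] = None
) -> SuperMatrix:
    """Concatenated per-gene protein alignments in sorted gene order."""
    if genes is None:
        genes = shared_genes(cohort)
    taxa = [g.name for g in cohort]
    parts: dict[str, tuple[int, int]] = {}
    chunks: list[list[str]] = [[] for _ in cohort]
    offset = 0
    for gene in sorted(genes):
        prots = []
        for g in cohort:
            f = g.annotations.get(gene, 0)
            if f is None:
                raise PlastomeError(f"genome {g.name} lacks shared gene {gene}")
            prots.append(_protein(splice(g.sequence, f)))
        if any(not p for p in prots):
            raise PlastomeError(f"empty protein for gene {gene}")
        if len(set(prots)) == 1:
            aligned = list(prots)
        elif len(prots) == 2:
            a, b = align_proteins(prots[0], prots[1])
            aligned = [a, b]
        else:
            aligned = _star_align(prots)
        width = len(aligned[0])
        parts[gene] = (offset, offset + width)
        offset += width
        for i, row in enumerate(aligned):
            chunks[i].append(row)
    return SuperMatrix(
        taxa=taxa, rows=["".join(c) for c in chunks], partitions=parts
    )


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise PlastomeError("distance matrix shape mismatch")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise PlastomeError("distance matrix must be symmetric with zero diagonal")
        if (v < 0).any():
            raise PlastomeError("negative distances")
        object.__setattr__(self, "values", v)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def distance_matrix(matrix: SuperMatrix, model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gap columns.

    p = mismatches / compared columns; poisson d = -ln(1 - p).  A fully
    saturated pair (p = 1) is rejected."""
    if model not in ("p", "poisson"):
        raise PlastomeError(f"unknown distance model {model!r}")
    if len(matrix.rows) < 2:
        raise PlastomeError("need at least two rows")
    arr = np.frombuffer(
        "".join(matrix.rows).encode(), dtype="S1"
    ).reshape(len(matrix.rows), -1)
    gap = arr == b"-"
    k = len(matrix.taxa)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ok = ~gap[i] & ~gap[j]
            compared = int(ok.sum())
            if compared == 0:
                raise PlastomeError(
                    f"no comparable columns between {matrix.taxa[i]} and "
                    f"{matrix.taxa[j]}"
                )
            p = float((arr[i, ok] != arr[j, ok]).sum()) / compared
            if model == "p":
                dist = p
            else:
                if p >= 1:
                    raise PlastomeError(
                        f"saturated pair {matrix.taxa[i]}/{matrix.taxa[j]} (p = 1)"
                    )
                dist = -log(1 - p)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(ids=tuple(matrix.taxa), values=d)


@dataclass
class TreeNode:
    name: str = ""
    length: float = 0.0
    support: Optional[int] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())


@dataclass
class Tree:
    """Unrooted tree stored as a rooted multifurcation at the last join."""

    root: TreeNode
    taxa: tuple[str, ...]

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else str(node.support)
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Internal-edge bipartitions, keyed by the canonical side."""
        all_taxa = frozenset(self.taxa)
        out: dict[frozenset[str], TreeNode] = {}

        def walk(node: TreeNode) -> None:
            for c in node.children:
                if not c.is_leaf:
                    side = c.leaf_names()
                    out[_canonical_side(side, all_taxa)] = c
                walk(c)

        walk(self.root)
        return out


def _canonical_side(side: frozenset[str], all_taxa: frozenset[str]) -> frozenset[str]:
    other = all_taxa - side
    a, b = sorted([side, other], key=lambda s: (len(s), sorted(s)))
    return a


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining with the standard Q criterion.

    Ties on minimal Q break toward the lowest (i, j) index pair; negative
    branch lengths are clamped to zero; the final three-node star is
    resolved exactly.  Two taxa yield a single edge of the full distance,
    split across the two pendant branches.
    """
    k = len(dm.ids)
    if k < 2:
        raise PlastomeError("need at least two taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.ids]
    if k == 2:
        d = dm.values[0, 1]
        nodes[0].length = d / 2
        nodes[1].length = d / 2
        return Tree(root=TreeNode(children=nodes), taxa=dm.ids)

    D = dm.values.copy()
    active = list(range(k))
    node_of = {i: nodes[i] for i in active}
    while len(active) > 3:
        r = len(active)
        sums = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                if best is None or q < best[0]:
                    best = (q, i, j)
        _, i, j = best
        li = D[i, j] / 2 + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        node_of[i].length = max(li, 0.0)
        node_of[j].length = max(lj, 0.0)
        parent = TreeNode(children=[node_of[i], node_of[j]])
        # distances to the new node
        new_idx = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for m in active:
            if m in (i, j):
                continue
            D[new_idx, m] = D[m, new_idx] = (D[i, m] + D[j, m] - D[i, j]) / 2
        active = [m for m in active if m not in (i, j)] + [new_idx]
        node_of[new_idx] = parent
    # resolve the final star exactly
    if len(active) == 3:
        i, j, m = active
        node_of[i].length = max((D[i, j] + D[i, m] - D[j, m]) / 2, 0.0)
        node_of[j].length = max((D[i, j] + D[j, m] - D[i, m]) / 2, 0.0)
        node_of[m].length = max((D[i, m] + D[j, m] - D[i, j]) / 2, 0.0)
        root = TreeNode(children=[node_of[i], node_of[j], node_of[m]])
    else:  # two clusters left
        i, j = active
        d = D[i, j]
        node_of[i].length = d / 2
        node_of[j].length = d / 2
        root = TreeNode(children=[node_of[i], node_of[j]])
    return Tree(root=root, taxa=dm.ids)


def bootstrap(
    matrix: SuperMatrix,
    reps: int = 100,
    seed: int = 0,
    model: str = "poisson",
) -> Tree:
    """NJ tree with bootstrap supports on internal edges.

    Supermatrix columns are resampled with replacement ``reps`` times;
    support = percentage of replicates containing the bipartition.
    """
    if reps < 1:
        raise PlastomeError("reps must be >= 1")
    main = nj_tree(distance_matrix(matrix, model=model))
    all_taxa = frozenset(matrix.taxa)
    counts: dict[frozenset[str], int] = {
        key: 0 for key in main.bipartitions()
    }
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(
        "".join(matrix.rows).encode(), dtype="S1"
    ).reshape(len(matrix.rows), -1)
    width = arr.shape[1]
    for _ in range(reps):
        idx = rng.integers(0, width, size=width)
        rows = ["".join(x) for x in arr[:, idx].astype(str)]
        rep_matrix = SuperMatrix(taxa=matrix.taxa, rows=rows, partitions={})
        try:
            rep_tree = nj_tree(distance_matrix(rep_matrix, model=model))
        except PlastomeError:
            continue
        for key in rep_tree.bipartitions():
            if key in counts:
                counts[key] += 1
    for key, node in main.bipartitions().items():
        node.support = round(100 * counts[key] / reps)
    return main


def write_newick(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


def root_with_outgroup(tree: Tree, outgroup: str) -> str:
    """Display-rooted Newick with the outgroup sister to everything else.

    Computation stays unrooted; this is presentation only (dendropy does
    the rerooting)."""
    import dendropy

    t = dendropy.Tree.get(data=tree.newick(), schema="newick")
    node = t.find_node_with_taxon_label(outgroup)
    if node is None:
        raise PlastomeError(f"outgroup {outgroup!r} not in tree")
    t.to_outgroup_position(node, update_bipartitions=True)
    return t.as_string(schema="newick").strip()
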