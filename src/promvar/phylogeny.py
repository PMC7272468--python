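"""Pairwise distances and neighbor-joining trees for promoter panels.

Distances are computed with pairwise deletion: alignment positions with a gap
or N in either sequence of a pair are excluded, and p is the fraction of
mismatches among the remaining positions.  The optional Jukes-Cantor
correction is d = -(3/4) ln(1 - 4p/3).  The tree is built with the
Saitou-Nei neighbor-joining algorithm, implemented here directly: at each
step the pair minimizing

    Q(i, j) = (r - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

is joined, with ties broken by the lexicographically smallest label pair
(internal nodes inherit their smallest leaf label as sort key).  Negative
branch lengths are clamped to zero and the clamped deficit is recorded on the
returned tree.  Branch lengths are in substitutions per nucleotide position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from .alignment import PromoterAlignment


class DistanceError(ValueError):
    """Raised for invalid distance matrices or incomparable sequence pairs."""


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise DistanceError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if len(set(self.labels)) != n:
            raise DistanceError("duplicate labels")
        if not np.all(np.isfinite(self.d)):
            raise DistanceError("non-finite distances")
        if np.any(self.d < 0):
            raise DistanceError("negative distances")
        if not np.allclose(self.d, self.d.T):
            raise DistanceError("asymmetric matrix")
        if np.any(np.diag(self.d) != 0):
            raise DistanceError("nonzero diagonal")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.d):
                fh.write(label + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            labels = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [line.rstrip("\n").split("\t")[1:] for line in fh]
        return cls(labels, np.array(rows, dtype=float))


@dataclass
class PhyloTree:
    """Unrooted tree with branch lengths, backed by a dendropy tree."""

    tree: dendropy.Tree
    clamped_deficit: float = 0.0

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(t.label for t in self.tree.taxon_namespace)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=text, schema="newick")
        return cls(tree)


def _pair_distance(seq_a: str, seq_b: str, model: str) -> float:
    compared = mismatches = 0
    for x, y in zip(seq_a, seq_b):
        if x in "-N" or y in "-N":
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        raise DistanceError("sequence pair with zero comparable sites")
    p = mismatches / compared
    if model == "p_distance":
        return p
    if model == "jc69":
        if p >= 0.75:
            raise DistanceError(f"jc69 undefined for p = {p:.4f} >= 0.75")
        return -0.75 * math.log1p(-4.0 * p / 3.0)
    raise ValueError(f"unknown model {model!r}")


def distance_from_sequences(
    labels: list[str], sequences: list[str], model: str = "p_distance"
) -> DistanceMatrix:
    """Pairwise-deletion distance matrix over aligned sequences."""
    if len(labels) < 2:
        raise DistanceError("need at least two sequences")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pair_distance(sequences[i], sequences[j], model)
    return DistanceMatrix(list(labels), d)


def pairwise_distance(aln: PromoterAlignment, model: str = "p_distance") -> DistanceMatrix:
    return distance_from_sequences(
        aln.accession_ids, [r.sequence for r in aln.records], model
    )


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; deterministic, from the distance matrix."""
    n = len(dm.labels)
    if n < 2:
        raise DistanceError("need at least two taxa")

    taxa = dendropy.TaxonNamespace(dm.labels)
    nodes: list[dendropy.Node] = []
    for label in dm.labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        nodes.append(node)
    keys = list(dm.labels)  # sort key: smallest leaf label in each subtree
    d = dm.d.astype(float).copy()
    active = list(range(n))
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        iu, ju = np.triu_indices(m, k=1)
        qu = q[iu, ju]
        qmin = qu.min()
        best = None
        for a, b in zip(iu[qu == qmin], ju[qu == qmin]):
            pair_key = tuple(sorted((keys[active[a]], keys[active[b]])))
            if best is None or pair_key < best[0]:
                best = (pair_key, int(a), int(b))
        _, a, b = best
        i, j = active[a], active[b]
        li = 0.5 * sub[a, b] + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = sub[a, b] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = clamp(li)
        nodes[j].edge.length = clamp(lj)
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d = np.vstack([d, new_row])
        d = np.hstack([d, np.append(new_row, 0.0)[:, None]])
        np.maximum(d, 0.0, out=d)
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    root = dendropy.Node()
    if len(active) == 1:
        root = nodes[active[0]]
    elif len(active) == 2:
        i, j = active
        root.add_child(nodes[i])
        root.add_child(nodes[j])
        half = d[i, j] / 2.0
        nodes[i].edge.length = half
        nodes[j].edge.length = half
    else:
        i, j, k = active
        root.add_child(nodes[i])
        root.add_child(nodes[j])
        root.add_child(nodes[k])
        nodes[i].edge.length = clamp(0.5 * (d[i, j] + d[i, k] - d[j, k]))
        nodes[j].edge.length = clamp(0.5 * (d[i, j] + d[j, k] - d[i, k]))
        nodes[k].edge.length = clamp(0.5 * (d[i, k] + d[j, k] - d[i, j]))

    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return PhyloTree(tree, clamped_deficit=deficit)


def write_newick(tree: PhyloTree, path) -> None:
    """Serialize with branch lengths; problem labels are quoted by the writer."""
    for taxon in tree.tree.taxon_namespace:
        if not taxon.label:
            raise ValueError("empty leaf label cannot be serialized")
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


def robinson_foulds(a: PhyloTree, b: PhyloTree) -> int:
    """Unrooted symmetric (bipartition) distance between two trees."""
    taxa = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=a.newick(), schema="newick", taxon_namespace=taxa)
    tb = dendropy.Tree.get(data=b.newick(), schema="newick", taxon_namespace=taxa)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(treecompare.symmetric_difference(ta, tb))


def tree_has_split(tree: PhyloTree, side: set[str]) -> bool:
    """True iff some edge of the (unrooted) tree induces the given leaf split."""
    t = dendropy.Tree.get(data=tree.newick(), schema="newick")
    all_labels = {leaf.taxon.label for leaf in t.leaf_node_iter()}
    if not side <= all_labels:
        raise ValueError("split side contains unknown labels")
    target = frozenset(side)
    complement = frozenset(all_labels - side)
    for node in t.preorder_node_iter():
        clade = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if clade == target or clade == complement:
            return True
    return False
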