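"""Distances, neighbor joining, and Newick serialization."""

import itertools
import math

import numpy as np
import pytest

from promvar.alignment import AlignmentRecord, PromoterAlignment
from promvar.phylogeny import (
    DistanceError,
    DistanceMatrix,
    PhyloTree,
    distance_from_sequences,
    neighbor_joining,
    pairwise_distance,
    read_newick,
    robinson_foulds,
    tree_has_split,
    write_newick,
)
from promvar.synthetic import simulate_additive_distances


def canonical_split(side: frozenset, all_labels: frozenset) -> frozenset:
    other = frozenset(all_labels - side)
    return min(side, other, key=lambda s: (len(s), sorted(s)))


def nj_least_squares_oracle(dm: DistanceMatrix) -> set[frozenset]:
    """Best topology for 5 taxa by least squares over all 15 topologies.

    Returns the non-trivial bipartitions of the winning topology.  Each
    unrooted 5-taxon tree has two internal edges; topologies are enumerated
    as unordered pairs of cherries.
    """
    labels = dm.labels
    assert len(labels) == 5
    best = None
    for pair1 in itertools.combinations(range(5), 2):
        rest = [i for i in range(5) if i not in pair1]
        for pair2 in itertools.combinations(rest, 2):
            # topology: cherry pair1 - inner - cherry pair2, fifth taxon on inner
            splits = [frozenset(pair1), frozenset(pair2)]
            # build path matrix over edges: 5 pendant + 2 internal
            edges = 7
            paths = []
            dvec = []
            middle = [i for i in range(5) if i not in pair1 and i not in pair2][0]

            def edge_vector(i, j):
                v = [0.0] * edges
                v[i] += 1
                v[j] += 1
                # internal edge 5 separates pair1 from the rest,
                # internal edge 6 separates pair2 from the rest
                in1 = (i in pair1) + (j in pair1)
                in2 = (i in pair2) + (j in pair2)
                if in1 == 1:
                    v[5] = 1
                if in2 == 1:
                    v[6] = 1
                return v

            for i, j in itertools.combinations(range(5), 2):
                paths.append(edge_vector(i, j))
                dvec.append(dm.d[i, j])
            lengths, residual, *_ = np.linalg.lstsq(
                np.array(paths), np.array(dvec), rcond=None
            )
            fitted = np.array(paths) @ lengths
            sse = float(np.sum((fitted - np.array(dvec)) ** 2))
            if best is None or sse < best[0]:
                all_labels = frozenset(labels)
                best = (
                    sse,
                    {
                        canonical_split(frozenset(labels[i] for i in s), all_labels)
                        for s in splits
                    },
                    middle,
                )
    return best[1]


def tree_bipartitions(tree: PhyloTree) -> set[frozenset]:
    import dendropy

    t = dendropy.Tree.get(data=tree.newick(), schema="newick")
    labels = frozenset(leaf.taxon.label for leaf in t.leaf_node_iter())
    out = set()
    for node in t.preorder_node_iter():
        clade = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if 1 < len(clade) < len(labels) - 1:
            out.add(canonical_split(clade, labels))
    return out


class TestDistances:
    def test_identical_sequences_zero(self):
        dm = distance_from_sequences(["a", "b"], ["ACGT", "ACGT"])
        assert dm.d[0, 1] == 0.0

    def test_p_distance_counts_mismatches(self):
        dm = distance_from_sequences(["a", "b"], ["ACGTACGTAC", "ACGTACGTAG"])
        assert dm.d[0, 1] == pytest.approx(0.1)

    def test_pairwise_deletion_excludes_gaps_and_n(self):
        dm = distance_from_sequences(["a", "b"], ["AC-TN", "AGGTC"])
        # comparable: positions 0, 1, 3 -> one mismatch
        assert dm.d[0, 1] == pytest.approx(1.0 / 3.0)

    def test_zero_comparable_sites_rejected(self):
        with pytest.raises(DistanceError):
            distance_from_sequences(["a", "b"], ["--AA", "GG--"])

    def test_jc69_closed_form(self):
        dm = distance_from_sequences(
            ["a", "b"], ["ACGTACGTAC", "ACGTACGTAG"], model="jc69"
        )
        assert dm.d[0, 1] == pytest.approx(-0.75 * math.log(1 - 0.4 / 3), abs=1e-10)
        assert dm.d[0, 1] == pytest.approx(0.10732, abs=1e-5)

    def test_jc69_saturated_rejected(self):
        with pytest.raises(DistanceError):
            distance_from_sequences(["a", "b"], ["AAAA", "CCCC"], model="jc69")

    def test_jc69_dominates_p_distance(self):
        rng = np.random.default_rng(5)
        ancestor = rng.choice(list("ACGT"), 200)
        seqs = []
        for _ in range(4):
            seq = ancestor.copy()
            mutate = rng.random(200) < 0.1
            seq[mutate] = rng.choice(list("ACGT"), int(mutate.sum()))
            seqs.append("".join(seq))
        labels = list("abcd")
        p = distance_from_sequences(labels, seqs, "p_distance")
        j = distance_from_sequences(labels, seqs, "jc69")
        assert np.all(j.d >= p.d - 1e-12)
        assert np.allclose(p.d, p.d.T) and np.allclose(j.d, j.d.T)
        assert np.all(np.diag(p.d) == 0)

    def test_matrix_validation(self):
        with pytest.raises(DistanceError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(DistanceError):
            DistanceMatrix(["a", "b"], np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0.0, 2.0], [2.0, 0.0]]))
        tree = neighbor_joining(dm)
        total = sum(
            e.length for e in tree.tree.preorder_edge_iter() if e.length is not None
        )
        assert total == pytest.approx(2.0)
        assert sorted(tree.leaf_labels) == ["A", "B"]

    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        lengths = {
            leaf.taxon.label: leaf.edge.length
            for leaf in tree.tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx(1.0, abs=1e-12)
        assert lengths["B"] == pytest.approx(1.0, abs=1e-12)
        assert lengths["C"] == pytest.approx(3.0, abs=1e-12)

    def test_five_taxon_matches_least_squares_oracle(self):
        for seed in range(10):
            dm, _ = simulate_additive_distances(5, seed=seed)
            tree = neighbor_joining(dm)
            assert tree_bipartitions(tree) == nj_least_squares_oracle(dm)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_recovers_generating_topology_and_lengths(self, n_taxa):
        for seed in range(5):
            dm, newick = simulate_additive_distances(n_taxa, seed=seed)
            tree = neighbor_joining(dm)
            truth = PhyloTree.from_newick(newick)
            assert robinson_foulds(tree, truth) == 0
            assert tree.clamped_deficit == 0.0
            # additivity: leaf-to-leaf path lengths reproduce the input matrix
            import dendropy

            t = dendropy.Tree.get(data=tree.newick(), schema="newick")
            pdm = t.phylogenetic_distance_matrix()
            for i, a in enumerate(dm.labels):
                for j, b in enumerate(dm.labels):
                    if i < j:
                        ta = t.taxon_namespace.get_taxon(a)
                        tb = t.taxon_namespace.get_taxon(b)
                        assert pdm.distance(ta, tb) == pytest.approx(
                            dm.d[i, j], abs=1e-8
                        )

    def test_matches_independent_library_nj(self):
        """Cross-check topology against scikit-bio's NJ implementation."""
        skbio = pytest.importorskip("skbio")
        for seed in (1, 2, 3):
            dm, _ = simulate_additive_distances(6, seed=seed)
            ours = neighbor_joining(dm)
            theirs = skbio.tree.nj(skbio.DistanceMatrix(dm.d, ids=dm.labels))
            other = PhyloTree.from_newick(str(theirs))
            assert robinson_foulds(ours, other) == 0


class TestNewick:
    def test_round_trip(self, tmp_path):
        dm, _ = simulate_additive_distances(6, seed=9)
        tree = neighbor_joining(dm)
        path = tmp_path / "tree.nwk"
        write_newick(tree, path)
        again = read_newick(path)
        assert robinson_foulds(tree, again) == 0
        assert sorted(again.leaf_labels) == sorted(tree.leaf_labels)

    def test_metacharacter_labels_quoted(self, tmp_path):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        tree = neighbor_joining(DistanceMatrix(["A (x)", "B:1"], d))
        path = tmp_path / "tree.nwk"
        write_newick(tree, path)
        assert sorted(read_newick(path).leaf_labels) == ["A (x)", "B:1"]

    def test_empty_label_rejected(self, tmp_path):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        tree = neighbor_joining(DistanceMatrix(["A", "B"], d))
        tree.tree.taxon_namespace[1].label = ""
        with pytest.raises(ValueError):
            write_newick(tree, tmp_path / "bad.nwk")


def test_panel_tree_groups_subspecies_with_their_progenitors(default_panel):
    """Indica-like haplotypes group with the nivara-like outgroup and
    japonica-like with the rufipogon-like one."""
    panel = default_panel
    aln = panel.alignment
    truth = panel.truth
    reps = [members[0] for members in truth.haplotype_members]
    wild = [a for accs in truth.wild_accessions.values() for a in accs]
    sub = aln.subset(reps + wild)
    tree = neighbor_joining(pairwise_distance(sub))
    indica_side = {
        m[0] for m in truth.haplotype_members if m[0] in set(truth.indica_like_accessions)
    } | set(truth.wild_accessions["wild_nivara"])
    assert tree_has_split(tree, indica_side)
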