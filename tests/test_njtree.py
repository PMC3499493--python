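"""Neighbor joining, bootstrap supports, and cohesion checks."""

import numpy as np
import pytest

from barcodegap.distances import DistanceMatrix, distance_matrix
from barcodegap.njtree import BarcodeTree, TreeNode, bootstrap_supports, is_cohesive, nj
from barcodegap.seqio import AlignedSet, BarcodeRecord
from barcodegap.synthetic_data import SimConfig, simulate_dataset


def dm(labels, d):
    d = np.asarray(d, float)
    return DistanceMatrix(labels=list(labels), d=d, n_sites=np.full(d.shape, 500))


def tree_pairwise(tree: BarcodeTree):
    """Leaf-to-leaf path distances of a reconstructed tree."""
    out = {}

    def walk(node):
        if node.is_leaf:
            return {node.label: node.length}
        depth_sets = [walk(c) for c in node.children]
        for i in range(len(depth_sets)):
            for j in range(i + 1, len(depth_sets)):
                for a, da in depth_sets[i].items():
                    for b, db in depth_sets[j].items():
                        out[frozenset((a, b))] = da + db
        merged = {}
        for ds in depth_sets:
            for leaf, depth in ds.items():
                merged[leaf] = depth + node.length
        return merged

    walk(tree.root)
    return out


class TestNJ:
    def test_three_taxa_equidistant_star(self):
        t = nj(dm("ABC", [[0, 2, 2], [2, 0, 2], [2, 2, 0]]))
        assert sorted(t.leaves) == ["A", "B", "C"]
        assert all(c.length == pytest.approx(1.0) for c in t.root.children)

    def test_four_taxon_additive_example(self):
        d = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        t = nj(dm("ABCD", d))
        splits = {frozenset(k) for k in t.bipartitions()}
        assert splits == {frozenset("CD")}
        lengths = {}
        def collect(node):
            for c in node.children:
                if c.is_leaf:
                    lengths[c.label] = c.length
                collect(c)
        collect(t.root)
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})
        pw = tree_pairwise(t)
        assert pw[frozenset("AB")] == pytest.approx(3.0)
        assert pw[frozenset("AD")] == pytest.approx(6.0)

    def test_label_order_invariance(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(1, 2, size=(6, 6))
        D = (base + base.T) / 2
        np.fill_diagonal(D, 0)
        labels = [f"T{i}" for i in range(6)]
        t1 = nj(dm(labels, D))
        perm = rng.permutation(6)
        t2 = nj(dm([labels[i] for i in perm], D[np.ix_(perm, perm)]))
        assert set(map(frozenset, t1.bipartitions())) == set(
            map(frozenset, t2.bipartitions())
        )
        pw1, pw2 = tree_pairwise(t1), tree_pairwise(t2)
        for key in pw1:
            assert pw1[key] == pytest.approx(pw2[key], abs=1e-9)

    @pytest.mark.parametrize("n_leaves", [4, 6, 8, 10])
    def test_recovers_random_additive_trees_exactly(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        for _ in range(5):
            # random binary tree via sequential joins
            nodes = [({f"L{i}": 0.0}) for i in range(n_leaves)]
            splits = set()
            pw = {}
            while len(nodes) > 1:
                i, j = sorted(
                    rng.choice(len(nodes), size=2, replace=False)
                )
                di, dj = nodes[i], nodes[j]
                bi, bj = rng.uniform(0.2, 1.0, size=2)
                for a, da in di.items():
                    for b, db in dj.items():
                        pw[frozenset((a, b))] = da + bi + db + bj
                merged = {k: v + bi for k, v in di.items()}
                merged.update({k: v + bj for k, v in dj.items()})
                nodes = [
                    nodes[k] for k in range(len(nodes)) if k not in (i, j)
                ] + [merged]
                if 1 < len(merged) < n_leaves - 1:
                    splits.add(frozenset(merged))
            labels = [f"L{i}" for i in range(n_leaves)]
            D = np.zeros((n_leaves, n_leaves))
            for a in range(n_leaves):
                for b in range(a + 1, n_leaves):
                    D[a, b] = D[b, a] = pw[
                        frozenset((labels[a], labels[b]))
                    ]
            tree = nj(dm(labels, D))
            # canonicalize generating splits the same way as the tree's
            all_leaves = frozenset(labels)
            ref = min(all_leaves)
            want = {
                s if ref not in s else all_leaves - s
                for s in splits
                if 1 < len(s) < n_leaves - 1
            }
            got = set(tree.bipartitions())
            assert got == want
            recon = tree_pairwise(tree)
            for key, value in pw.items():
                assert recon[key] == pytest.approx(value, abs=1e-9)

    def test_matches_scikit_bio_on_additive_input(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        d = np.array(
            [[0, 3, 5, 6, 7],
             [3, 0, 6, 7, 8],
             [5, 6, 0, 7, 8],
             [6, 7, 7, 0, 5],
             [7, 8, 8, 5, 0]], float)
        labels = list("ABCDE")
        mine = nj(dm(labels, d))
        ref = skbio_nj(SkbioDM(d, labels))
        ref_splits = set()
        for node in ref.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(labels) - 1:
                side = side if "A" not in side else frozenset(labels) - side
                ref_splits.add(side)
        assert set(mine.bipartitions()) == ref_splits

    def test_too_few_taxa_raise(self):
        with pytest.raises(ValueError):
            nj(dm("AB", [[0, 1], [1, 0]]))

    def test_undefined_pairs_raise(self):
        m = dm("ABC", [[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        m.undefined_pairs.add(frozenset(("A", "B")))
        with pytest.raises(ValueError, match="undefined"):
            nj(m)


@pytest.fixture(scope="module")
def two_clusters():
    aligned, _ = simulate_dataset(
        SimConfig(n_genera=2, species_per_genus=1,
                  individuals_per_species=5,
                  inter_divergence_range=(0.3, 0.4), seed=7)
    )
    return aligned


class TestBootstrap:
    def test_separating_edge_fully_supported(self, two_clusters):
        tree = bootstrap_supports(two_clusters, replicates=1000, seed=1)
        cluster = frozenset(r.accession for r in two_clusters
                            if r.species == "Genus02 sp01")
        all_leaves = frozenset(tree.leaves)
        key = cluster if min(all_leaves) not in cluster else all_leaves - cluster
        assert tree.bipartitions()[key].support == 100.0

    def test_zero_replicates_returns_unannotated_tree(self, two_clusters):
        tree = bootstrap_supports(two_clusters, replicates=0, seed=1)
        assert all(n.support is None for n in tree.bipartitions().values())

    def test_same_seed_same_supports(self, two_clusters):
        t1 = bootstrap_supports(two_clusters, replicates=100, seed=42)
        t2 = bootstrap_supports(two_clusters, replicates=100, seed=42)
        s1 = {k: n.support for k, n in t1.bipartitions().items()}
        s2 = {k: n.support for k, n in t2.bipartitions().items()}
        assert s1 == s2

    def test_zero_variation_alignment_is_stable(self):
        records = [
            BarcodeRecord(f"R{i}", f"Genus sp{i}", "ACGT" * 50)
            for i in range(5)
        ]
        tree = bootstrap_supports(
            AlignedSet.from_records(records), replicates=50, seed=0
        )
        assert all(
            n.support == 100.0 for n in tree.bipartitions().values()
        )


class TestCohesion:
    @pytest.fixture()
    def interleaved(self):
        # additive tree AB|CD, but A and C share a species label
        d = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        tree = nj(dm("ABCD", d))
        records = {
            "A": BarcodeRecord("A", "Genus sp1", "ACGT"),
            "B": BarcodeRecord("B", "Genus sp2", "ACGT"),
            "C": BarcodeRecord("C", "Genus sp1", "ACGT"),
            "D": BarcodeRecord("D", "Genus sp3", "ACGT"),
        }
        return tree, records

    def test_clade_side_of_an_edge_is_cohesive(self):
        d = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        tree = nj(dm("ABCD", d))
        records = {
            acc: BarcodeRecord(acc, sp, "ACGT")
            for acc, sp in [("A", "Genus sp1"), ("B", "Genus sp1"),
                            ("C", "Genus sp2"), ("D", "Genus sp2")]
        }
        assert is_cohesive(tree, "Genus sp1", records)
        assert is_cohesive(tree, "Genus sp2", records)

    def test_interleaved_species_is_not_cohesive(self, interleaved):
        tree, records = interleaved
        assert not is_cohesive(tree, "Genus sp1", records)

    def test_singleton_is_cohesive_by_convention(self, interleaved):
        tree, records = interleaved
        assert is_cohesive(tree, "Genus sp2", records)

    def test_absent_species_raises(self, interleaved):
        tree, records = interleaved
        with pytest.raises(ValueError, match="no leaf"):
            is_cohesive(tree, "Genus sp9", records)


def test_newick_round_trips_through_dendropy():
    dendropy = pytest.importorskip("dendropy")
    aligned, _ = simulate_dataset(SimConfig(seed=1, n_genera=2))
    m = distance_matrix(aligned)
    tree = nj(m)
    newick = tree.to_newick({r.accession: r for r in aligned})
    parsed = dendropy.Tree.get(data=newick, schema="newick")
    assert len(parsed.leaf_nodes()) == len(aligned)
    assert {t.label.split("|")[0] for t in parsed.taxon_namespace} == set(
        m.labels
    )
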