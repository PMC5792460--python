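import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from barcodekit import (
    AlignedLocus,
    SpecimenRecord,
    bootstrap_support,
    build_species_tree,
    label_clusters,
    neighbor_joining,
    prune_undefined,
)
from barcodekit.distance import DistanceMatrix
from barcodekit.errors import IncompleteMatrixError, InsufficientTaxaError

from conftest import exact_path_matrix

ADDITIVE_4 = DistanceMatrix(
    ["A", "B", "C", "D"],
    "p",
    np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
    ),
)


def leaf_edge_lengths(tree):
    return {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}


class TestNeighborJoining:
    def test_additive_four_taxon_topology_and_lengths(self):
        tree = neighbor_joining(ADDITIVE_4)
        # AB|CD with leaf edges A:1 B:2 C:3 D:4 and internal edge 1
        assert leaf_edge_lengths(tree) == pytest.approx(
            {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        )
        internal = [
            e.length
            for e in tree.preorder_internal_edge_iter(exclude_seed_edge=True)
        ]
        assert internal == pytest.approx([1.0])

    def test_additive_matrix_reproduced_exactly(self):
        tree = neighbor_joining(ADDITIVE_4)
        pdm = tree.phylogenetic_distance_matrix()
        tx = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(ADDITIVE_4.ids):
            for j in range(i + 1, 4):
                b = ADDITIVE_4.ids[j]
                assert pdm.patristic_distance(tx[a], tx[b]) == pytest.approx(
                    ADDITIVE_4.values[i, j], abs=1e-9
                )

    def test_three_taxa_closed_form(self):
        m = DistanceMatrix(
            ["x", "y", "z"],
            "p",
            np.array([[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]]),
        )
        tree = neighbor_joining(m)
        assert leaf_edge_lengths(tree) == pytest.approx(
            {"x": 0.2, "y": 0.1, "z": 0.3}
        )

    def test_edge_count_and_leaf_set(self):
        tree = neighbor_joining(exact_path_matrix(build_species_tree(8, 0.1, 3)))
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        assert sorted(leaves) == [f"species_{i:02d}" for i in range(1, 9)]
        n_edges = sum(
            1 for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node
        )
        assert n_edges == 2 * 8 - 3

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_random_topologies_from_path_lengths(self, seed):
        n = 6 + seed % 7
        true = build_species_tree(n, 0.2, seed)
        est = neighbor_joining(exact_path_matrix(true), taxon_namespace=true.taxon_namespace)
        est.encode_bipartitions()
        true.encode_bipartitions()
        assert treecompare.symmetric_difference(true, est) == 0

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_independent_nj_implementation(self, seed):
        """Cross-check topology against scikit-bio's neighbor joining."""
        import skbio

        n = 8
        true = build_species_tree(n, 0.3, seed + 100)
        m = exact_path_matrix(true)
        ours = neighbor_joining(m)
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(m.values, ids=m.ids))
        theirs = dendropy.Tree.get(
            data=str(sk_tree).replace("root", ""),
            schema="newick",
            taxon_namespace=ours.taxon_namespace,
        )
        theirs.is_rooted = False
        ours.encode_bipartitions()
        theirs.encode_bipartitions()
        assert treecompare.symmetric_difference(ours, theirs) == 0

    def test_incomplete_matrix_rejected(self):
        vals = ADDITIVE_4.values.copy()
        vals[0, 1] = vals[1, 0] = np.nan
        with pytest.raises(IncompleteMatrixError):
            neighbor_joining(DistanceMatrix(ADDITIVE_4.ids, "p", vals))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(InsufficientTaxaError):
            neighbor_joining(
                DistanceMatrix(["a", "b"], "p", np.array([[0, 1.0], [1.0, 0]]))
            )


def test_prune_undefined_drops_worst_specimen_first():
    vals = np.array(
        [
            [0, np.nan, np.nan, 0.1],
            [np.nan, 0, 0.2, 0.3],
            [np.nan, 0.2, 0, 0.4],
            [0.1, 0.3, 0.4, 0],
        ]
    )
    pruned, removed = prune_undefined(DistanceMatrix(list("abcd"), "p", vals))
    assert removed == ["a"]
    assert pruned.ids == list("bcd")
    assert not np.isnan(pruned.values).any()


class TestBootstrap:
    def two_cluster_locus(self):
        # two 4-specimen species separated by 50 fixed differences over 200 columns
        a = "A" * 200
        b = "A" * 150 + "T" * 50
        rows = [(f"a{i}", a) for i in range(4)] + [(f"b{i}", b) for i in range(4)]
        return AlignedLocus("L", rows)

    def specimens(self):
        return [SpecimenRecord(f"a{i}", "alpha") for i in range(4)] + [
            SpecimenRecord(f"b{i}", "beta") for i in range(4)
        ]

    def test_strong_split_gets_high_support(self):
        tree = bootstrap_support(self.two_cluster_locus(), "p", n_reps=100, seed=5)
        disc = label_clusters(tree, self.specimens(), "species")
        assert disc.verdicts["alpha"].support >= 95
        assert disc.verdicts["beta"].support >= 95

    def test_identical_sequences_have_no_supported_resolution(self):
        rows = [(f"s{i}", "ACGT" * 50) for i in range(6)]
        specs = [SpecimenRecord(f"s{i}", f"sp{i % 2}") for i in range(6)]
        tree = bootstrap_support(AlignedLocus("L", rows), "p", n_reps=20, seed=1)
        supports = [
            e.head_node.support
            for e in tree.preorder_internal_edge_iter(exclude_seed_edge=True)
        ]
        assert all(s == 0.0 for s in supports)

    def test_seed_determinism(self):
        locus = self.two_cluster_locus()
        t1 = bootstrap_support(locus, "p", n_reps=30, seed=9)
        t2 = bootstrap_support(locus, "p", n_reps=30, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_invalid_rep_count_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(self.two_cluster_locus(), "p", n_reps=0, seed=1)


def tree_from_newick(newick, specimens):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestLabelClusters:
    def make_specimens(self, species, vouchered=None):
        vouchered = vouchered or {k: True for k in species}
        return [
            SpecimenRecord(k, v, vouchered=vouchered[k]) for k, v in species.items()
        ]

    def test_clean_split_discriminates_both(self):
        tree = tree_from_newick("((A1:1,A2:1):1,(B1:1,B2:1):1);", None)
        specs = self.make_specimens({"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
        disc = label_clusters(tree, specs, "species")
        assert disc.overall_rate == 100.0
        assert all(v.discriminated for v in disc.verdicts.values())

    def test_interleaved_split_discriminates_neither(self):
        tree = tree_from_newick("((A1:1,B1:1):1,(A2:1,B2:1):1);", None)
        specs = self.make_specimens({"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
        disc = label_clusters(tree, specs, "species")
        assert disc.overall_rate == 0.0
        assert not any(v.is_exclusive_cluster for v in disc.verdicts.values())

    def test_voucher_clause_blocks_discrimination(self):
        tree = tree_from_newick("((A1:1,A2:1):1,(B1:1,B2:1):1);", None)
        specs = self.make_specimens(
            {"A1": "A", "A2": "A", "B1": "B", "B2": "B"},
            vouchered={"A1": False, "A2": False, "B1": True, "B2": True},
        )
        disc = label_clusters(tree, specs, "species")
        assert disc.verdicts["A"].is_exclusive_cluster
        assert not disc.verdicts["A"].discriminated
        assert disc.verdicts["B"].discriminated
        assert disc.overall_rate == 50.0

    def test_unlabeled_leaf_rejected(self):
        tree = tree_from_newick("((A1:1,A2:1):1,(B1:1,GHOST:1):1);", None)
        specs = self.make_specimens({"A1": "A", "A2": "A", "B1": "B"})
        with pytest.raises(KeyError):
            label_clusters(tree, specs, "species")

    def _oracle_exclusive(self, tree, members):
        """Independent monophyly check: reroot at an outside leaf, then
        compare the MRCA's leaf set (dendropy's own machinery)."""
        clone = tree.clone(depth=1)
        out_leaf = next(
            lf for lf in clone.leaf_node_iter() if lf.taxon.label not in members
        )
        clone.reroot_at_edge(out_leaf.edge)
        taxa = [t for t in clone.taxon_namespace if t.label in members]
        mrca = clone.mrca(taxa=taxa)
        return {lf.taxon.label for lf in mrca.leaf_iter()} == members

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_mrca_oracle_on_random_labeled_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        tree = build_species_tree(n, 1.0, seed)
        labels = [f"g{rng.integers(0, 3)}" for _ in range(n)]
        while len(set(labels)) < 2:
            labels = [f"g{rng.integers(0, 3)}" for _ in range(n)]
        leaf_names = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        specs = [SpecimenRecord(l, g) for l, g in zip(leaf_names, labels)]
        disc = label_clusters(tree, specs, "species")
        groups = {}
        for l, g in zip(leaf_names, labels):
            groups.setdefault(g, set()).add(l)
        for g, members in groups.items():
            if len(members) == n:
                continue
            assert disc.verdicts[g].is_exclusive_cluster == self._oracle_exclusive(
                tree, members
            ), (g, members)

    def test_invariant_to_rerooting(self):
        tree = tree_from_newick("((A1:1,A2:1):1,((B1:1,B2:1):1,(C1:1,C2:1):1):1);", None)
        specs = self.make_specimens(
            {"A1": "A", "A2": "A", "B1": "B", "B2": "B", "C1": "C", "C2": "C"}
        )
        base = label_clusters(tree, specs, "species")
        clone = tree.clone(depth=1)
        leaf = next(lf for lf in clone.leaf_node_iter() if lf.taxon.label == "B1")
        clone.reroot_at_edge(leaf.edge)
        rerooted = label_clusters(clone, specs, "species")
        assert {k: v.is_exclusive_cluster for k, v in base.verdicts.items()} == {
            k: v.is_exclusive_cluster for k, v in rerooted.verdicts.items()
        }
        assert base.overall_rate == rerooted.overall_rate
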