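import numpy as np
import pytest

from barcodekit import (
    LocusConfig,
    SimulationConfig,
    build_species_tree,
    default_config,
    distance_matrix,
    profile_locus,
    simulate_library,
    simulate_locus,
    summarize_pairwise,
)
from barcodekit.simulate import make_metadata


def newick(tree):
    return tree.as_string(schema="newick")


class TestBuildSpeciesTree:
    def test_two_species_single_path_of_requested_depth(self):
        tree = build_species_tree(2, 0.05, 1)
        leaves = tree.leaf_nodes()
        assert len(leaves) == 2
        total = sum(lf.edge.length for lf in leaves)
        assert total == pytest.approx(0.05)

    def test_binary_tree_edge_count(self):
        tree = build_species_tree(6, 0.05, 7)
        assert len(tree.leaf_nodes()) == 6
        n_edges = sum(
            1 for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node
        )
        assert n_edges == 2 * 6 - 3

    def test_seed_determinism(self):
        assert newick(build_species_tree(6, 0.05, 7)) == newick(
            build_species_tree(6, 0.05, 7)
        )

    def test_mean_path_scaled_to_depth(self):
        tree = build_species_tree(5, 0.08, 11)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = list(tree.taxon_namespace)
        paths = [
            pdm.patristic_distance(taxa[i], taxa[j])
            for i in range(len(taxa))
            for j in range(i + 1, len(taxa))
        ]
        assert np.mean(paths) == pytest.approx(0.08)

    def test_fewer_than_two_species_rejected(self):
        with pytest.raises(ValueError):
            build_species_tree(1, 0.05, 1)


class TestSimulateLocus:
    def test_zero_intra_depth_gives_identical_conspecifics(self):
        meta = make_metadata(3, [3, 3, 3])
        cfg = LocusConfig("L", length=120, inter_depth=0.05, intra_depth=0.0)
        tree = build_species_tree(3, 0.05, 2)
        locus = simulate_locus(tree, cfg, meta, seed=4)
        by_species = {}
        species_of = {r.specimen_id: r.species for r in meta}
        for sid, seq in locus.rows:
            by_species.setdefault(species_of[sid], set()).add(seq)
        assert all(len(seqs) == 1 for seqs in by_species.values())

    def test_exact_dropout_count(self):
        meta = make_metadata(4, [10, 10, 10, 10])
        cfg = LocusConfig("L", length=100, inter_depth=0.05, intra_depth=0.001,
                          recovery_rate=0.5)
        locus = simulate_locus(build_species_tree(4, 0.05, 3), cfg, meta, seed=8)
        assert len(locus.rows) == 20

    def test_unknown_species_rejected(self):
        from barcodekit import SpecimenRecord

        meta = make_metadata(2, [2, 2]) + [SpecimenRecord("x1", "unknown_species")]
        cfg = LocusConfig("L", length=100, inter_depth=0.05, intra_depth=0.01)
        with pytest.raises(KeyError):
            simulate_locus(build_species_tree(2, 0.05, 1), cfg, meta, seed=0)

    def test_divergence_recovery_at_long_length(self):
        """Observed mean intra/inter K2P distances converge to the
        configured depths (length 5000, five seeds pooled, within 10%)."""
        cfg = LocusConfig("L", length=5000, inter_depth=0.05, intra_depth=0.003)
        meta = make_metadata(6, [4] * 6)
        intra, inter = [], []
        for seed in range(5):
            tree = build_species_tree(6, cfg.inter_depth - cfg.intra_depth, seed + 20)
            locus = simulate_locus(tree, cfg, meta, seed + 60)
            s = summarize_pairwise(distance_matrix(locus, "K2P"), meta)
            intra.append(s.intra_stats["mean"])
            inter.append(s.inter_stats["mean"])
        assert np.mean(intra) == pytest.approx(0.003, rel=0.10)
        assert np.mean(inter) == pytest.approx(0.05, rel=0.10)

    def test_species_indel_blocks_are_fixed_within_species(self):
        cfg = LocusConfig("L", length=150, inter_depth=0.05, intra_depth=0.0,
                          indel_rate=1.0, indel_length=6)
        meta = make_metadata(3, [3, 3, 3])
        locus = simulate_locus(build_species_tree(3, 0.05, 5), cfg, meta, seed=6)
        species_of = {r.specimen_id: r.species for r in meta}
        gaps_by_species = {}
        for sid, seq in locus.rows:
            cols = frozenset(i for i, c in enumerate(seq) if c == "-")
            gaps_by_species.setdefault(species_of[sid], set()).add(cols)
        for sp, patterns in gaps_by_species.items():
            assert len(patterns) == 1
            assert len(next(iter(patterns))) == 6


class TestSimulateLibrary:
    def test_study_scale_library_shape(self):
        lib = simulate_library(default_config(seed=3))
        assert len(lib.specimens) == 39
        assert len(lib.loci) == 4
        assert {l.name: l.length for l in lib.loci} == {
            "ITS2": 234, "matK": 239, "ndhF-rpl32": 173, "rbcL": 350,
        }

    def test_recovery_counts_are_exact(self):
        lib = simulate_library(default_config(seed=3))
        expected = {"ITS2": 26, "matK": 32, "ndhF-rpl32": 35, "rbcL": 27}
        assert {l.name: len(l.rows) for l in lib.loci} == expected
        p = profile_locus(lib.locus("ndhF-rpl32"), lib.specimens)
        assert p.recovery_rate == pytest.approx(89.74, abs=0.01)

    def test_seed_determinism_bytes(self, tmp_path):
        from barcodekit import write_library

        cfg = default_config(seed=5)
        p1 = write_library(simulate_library(cfg), tmp_path / "a")
        p2 = write_library(simulate_library(cfg), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_mean_inter_exceeds_mean_intra_everywhere(self):
        cfg = SimulationConfig(
            n_species=4,
            samples_per_species=(3, 3, 3, 3),
            loci=tuple(
                LocusConfig(f"L{i}", length=2000, inter_depth=0.05, intra_depth=0.005)
                for i in range(2)
            ),
            seed=0,
        )
        for seed in range(5):
            lib = simulate_library(
                SimulationConfig(**{**cfg.__dict__, "seed": seed})
            )
            for locus in lib.loci:
                s = summarize_pairwise(distance_matrix(locus, "K2P"), lib.specimens)
                assert s.inter_stats["mean"] > s.intra_stats["mean"]

    def test_linked_loci_share_topology(self):
        from dendropy.calculate import treecompare
        import dendropy

        cfg = SimulationConfig(
            n_species=5,
            samples_per_species=(2,) * 5,
            loci=(
                LocusConfig("p1", length=100, inter_depth=0.05, intra_depth=0.001),
                LocusConfig("p2", length=100, inter_depth=0.09, intra_depth=0.001),
            ),
            seed=4,
            linked_loci=("p1", "p2"),
        )
        from barcodekit.simulate import _derived_seed, scale_tree

        t1 = build_species_tree(5, 0.049, _derived_seed(4, 0))
        t2 = scale_tree(
            build_species_tree(5, 0.049, _derived_seed(4, 0)).clone(depth=1), 0.089
        )
        tns = dendropy.TaxonNamespace()
        a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick",
                              taxon_namespace=tns)
        b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick",
                              taxon_namespace=tns)
        a.encode_bipartitions(); b.encode_bipartitions()
        assert treecompare.symmetric_difference(a, b) == 0
        # and the library builds without error under linkage
        lib = simulate_library(cfg)
        assert len(lib.loci) == 2

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = default_config(seed=9)
        path = tmp_path / "sim.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            LocusConfig("L", length=10, inter_depth=0.05, intra_depth=0.01)
        with pytest.raises(ValueError):
            LocusConfig("L", length=100, inter_depth=0.01, intra_depth=0.02)
        with pytest.raises(ValueError):
            SimulationConfig(1, (3,), (), seed=0)
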