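import dendropy
import numpy as np
import pytest

from barcodekit import (
    AlignedLocus,
    BarcodeLibrary,
    SpecimenRecord,
    default_config,
    simulate_library,
)
from barcodekit.distance import DistanceMatrix


@pytest.fixture
def two_species_library():
    """2 species x 2 specimens, 40 bp, clearly separated clusters:
    within-species distance ~0.025, between ~0.25."""
    base = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"
    other = "TGCATGCATGCA" + base[12:]
    specimens = [
        SpecimenRecord("a1", "alpha"),
        SpecimenRecord("a2", "alpha"),
        SpecimenRecord("b1", "beta"),
        SpecimenRecord("b2", "beta"),
    ]
    locus = AlignedLocus(
        "L1",
        [
            ("a1", base),
            ("a2", base[:-1] + "C"),
            ("b1", other),
            ("b2", other[:-1] + "G"),
        ],
    )
    return BarcodeLibrary(specimens, [locus])


@pytest.fixture(scope="session")
def demo_library():
    """The default six-species, four-locus study-scale simulation."""
    return simulate_library(default_config(seed=7))


def exact_path_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Patristic (path-length) distances between all leaves of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix([t.label for t in taxa], "p", vals)


def random_distance_matrix(rng: np.random.Generator, n: int) -> DistanceMatrix:
    """Random symmetric matrix with zero diagonal (not necessarily additive)."""
    vals = rng.uniform(0.0, 0.2, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix([f"s{i:02d}" for i in range(n)], "p", vals)
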