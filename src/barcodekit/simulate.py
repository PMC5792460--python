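"""Synthetic multi-locus barcode libraries with controlled divergence,
recovery, and diagnostic indels.

The generator produces the statistical structure a barcode-library
evaluation assumes: a random bifurcating species genealogy per locus,
sequences evolved under the Kimura two-parameter (K80) substitution model —
the same model family the downstream distance estimator inverts, so
parameter-recovery tests are meaningful — specimen-level divergence within
each species, species-fixed diagnostic indel blocks, and per-locus
missing-sequence (dropout) rates.

Calibration: the species tree's mean leaf-to-leaf path length is scaled to
``inter_depth - intra_depth`` and every specimen hangs from its species
leaf on a pendant branch of ``intra_depth / 2``. Two conspecific specimens
therefore diverge by ``intra_depth`` in expectation, and two heterospecific
ones by ``inter_depth`` on average, so observed mean K2P distances recover
the configured depths as sequence length grows.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import yaml

from .library import (
    AlignedLocus,
    BarcodeLibrary,
    SpecimenRecord,
    TISSUES,
    write_library,
)

_BASES = "ACGT"


@dataclass(frozen=True)
class LocusConfig:
    """Generation parameters for one barcode region.

    ``kappa`` is the transition/transversion rate ratio; ``inter_depth`` and
    ``intra_depth`` are expected substitutions/site between and within
    species; ``indel_rate`` is the per-species probability of one
    species-fixed gap block of ``indel_length`` columns; ``recovery_rate``
    is the fraction of specimens yielding a sequence.
    """

    name: str
    length: int
    inter_depth: float
    intra_depth: float
    kappa: float = 2.0
    indel_rate: float = 0.0
    indel_length: int = 6
    recovery_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.length < 50:
            raise ValueError(f"{self.name}: length must be >= 50, got {self.length}")
        if not (0 <= self.intra_depth < self.inter_depth):
            raise ValueError(
                f"{self.name}: need 0 <= intra_depth < inter_depth, "
                f"got {self.intra_depth} / {self.inter_depth}"
            )
        if not (0 < self.recovery_rate <= 1):
            raise ValueError(f"{self.name}: recovery_rate must be in (0, 1]")
        if not (0 <= self.indel_rate <= 1):
            raise ValueError(f"{self.name}: indel_rate must be in [0, 1]")
        if self.kappa <= 0:
            raise ValueError(f"{self.name}: kappa must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Full library recipe: species, sampling depths, loci, seed.

    ``linked_loci`` names loci that share one genealogy shape (plastid-like
    linkage); all other loci draw independent genealogies.
    """

    n_species: int
    samples_per_species: tuple[int, ...]
    loci: tuple[LocusConfig, ...]
    seed: int = 0
    linked_loci: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if len(self.samples_per_species) != self.n_species:
            raise ValueError(
                f"samples_per_species has {len(self.samples_per_species)} entries "
                f"for {self.n_species} species"
            )
        if any(s < 1 for s in self.samples_per_species):
            raise ValueError("every samples_per_species must be >= 1")
        known = {l.name for l in self.loci}
        stray = set(self.linked_loci) - known
        if stray:
            raise ValueError(f"linked_loci not in loci: {sorted(stray)}")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["samples_per_species"] = list(self.samples_per_species)
        data["linked_loci"] = list(self.linked_loci)
        data["loci"] = [asdict(l) for l in self.loci]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["loci"] = tuple(LocusConfig(**l) for l in data["loci"])
        data["samples_per_species"] = tuple(data["samples_per_species"])
        data["linked_loci"] = tuple(data.get("linked_loci", ()))
        return cls(**data)


def species_label(index: int) -> str:
    return f"species_{index + 1:02d}"


def _derived_seed(base: int, stream: int) -> int:
    # keep derived seeds in int32 range for portability
    return (base * 100_003 + 7_919 * stream + 1) % (2**31)


def _mean_leaf_path(tree: dendropy.Tree) -> float:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    total = npairs = 0
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            total += pdm.patristic_distance(taxa[i], taxa[j])
            npairs += 1
    return total / npairs if npairs else 0.0


def scale_tree(tree: dendropy.Tree, target_mean_path: float) -> dendropy.Tree:
    """Scale all branch lengths so the mean leaf-to-leaf path equals the
    target (no-op when the tree has no path length)."""
    mean = _mean_leaf_path(tree)
    if mean > 0 and target_mean_path >= 0:
        factor = target_mean_path / mean
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
    return tree


def build_species_tree(
    n_species: int, inter_depth: float, seed: int
) -> dendropy.Tree:
    """Random bifurcating unrooted species tree with ``n_species`` leaves,
    scaled so the mean leaf-to-leaf path length equals ``inter_depth``.

    Topology is built by repeated random joins; branch lengths are drawn
    exponential(1) then rescaled. Deterministic for a fixed seed.
    """
    if n_species < 2:
        raise ValueError(f"n_species must be >= 2, got {n_species}")
    rng = np.random.default_rng(seed)
    labels = [species_label(i) for i in range(n_species)]
    tns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(l)) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = float(rng.exponential(1.0))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    center = dendropy.Node()
    for child in nodes:
        center.add_child(child)
        child.edge.length = float(rng.exponential(1.0))
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return scale_tree(tree, inter_depth)


def _evolve(
    codes: np.ndarray, t: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """One K80 step: evolve an encoded sequence along a branch of expected
    length ``t`` substitutions/site."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    u = rng.random(codes.shape[0])
    out = codes.copy()
    out[(u >= p_same) & (u < p_same + p_ts)] ^= 2          # transition partner
    tv1 = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
    tv2 = u >= p_same + p_ts + p_tv
    out[tv1] ^= 1
    out[tv2] ^= 3
    return out


def simulate_locus(
    tree: dendropy.Tree,
    cfg: LocusConfig,
    metadata: Sequence[SpecimenRecord],
    seed: int,
) -> AlignedLocus:
    """Simulate one aligned locus over a species tree.

    Species-level sequences evolve along the tree from a uniform-random root
    sequence; each specimen then evolves from its species sequence on a
    pendant branch of ``intra_depth / 2``. Each species independently
    receives one fixed gap block of ``indel_length`` columns with
    probability ``indel_rate``. A fraction ``1 - recovery_rate`` of
    specimens (exact rounded count, chosen at random) get no sequence.
    Raises ``KeyError`` when a metadata species has no tree leaf.
    """
    rng = np.random.default_rng(seed)
    leaf_of = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    for rec in metadata:
        if rec.species not in leaf_of:
            raise KeyError(
                f"species {rec.species!r} not on the species tree "
                f"(leaves: {sorted(leaf_of)})"
            )
    # species-level sequences: preorder traversal from the seed node
    seqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    seqs[id(root)] = rng.integers(0, 4, size=cfg.length, dtype=np.int8)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        seqs[id(node)] = _evolve(
            seqs[id(node.parent_node)], node.edge.length or 0.0, cfg.kappa, rng
        )
    # specimen sequences on pendant branches
    specimen_codes: list[tuple[str, np.ndarray]] = []
    for rec in metadata:
        base = seqs[id(leaf_of[rec.species])]
        specimen_codes.append(
            (rec.specimen_id, _evolve(base, cfg.intra_depth / 2.0, cfg.kappa, rng))
        )
    # species-fixed diagnostic indel blocks
    gap_blocks: dict[str, tuple[int, int]] = {}
    for sp in sorted({rec.species for rec in metadata}):
        if rng.random() < cfg.indel_rate:
            start = int(rng.integers(0, cfg.length - cfg.indel_length + 1))
            gap_blocks[sp] = (start, start + cfg.indel_length)
    species_of = {rec.specimen_id: rec.species for rec in metadata}
    # dropout: exact rounded count of recovered specimens
    n = len(specimen_codes)
    n_keep = int(round(cfg.recovery_rate * n))
    keep = set(rng.choice(n, size=n_keep, replace=False).tolist())
    rows: list[tuple[str, str]] = []
    for idx, (sid, codes) in enumerate(specimen_codes):
        if idx not in keep:
            continue
        chars = [_BASES[c] for c in codes]
        block = gap_blocks.get(species_of[sid])
        if block:
            for col in range(*block):
                chars[col] = "-"
        rows.append((sid, "".join(chars)))
    return AlignedLocus(cfg.name, rows)


def make_metadata(
    n_species: int,
    samples_per_species: Sequence[int],
    regions: Optional[Sequence[str]] = None,
) -> list[SpecimenRecord]:
    """Specimen table for a simulated library: ids ``<species>_<k>``, all
    vouchered, tissues cycling through the four specimen types, species
    split between two broad geographic regions unless given explicitly."""
    if regions is None:
        half = (n_species + 1) // 2
        regions = ["Asia" if i < half else "Africa" for i in range(n_species)]
    records = []
    t = 0
    for i in range(n_species):
        sp = species_label(i)
        for k in range(samples_per_species[i]):
            records.append(
                SpecimenRecord(
                    specimen_id=f"{sp}_{k + 1:02d}",
                    species=sp,
                    vouchered=True,
                    region=regions[i],
                    tissue=TISSUES[t % len(TISSUES)],
                )
            )
            t += 1
    return records


def simulate_library(cfg: SimulationConfig) -> BarcodeLibrary:
    """Generate a full multi-locus library from a configuration.

    Each locus draws an independent genealogy (loci named in
    ``linked_loci`` share one shape, rescaled to each locus's depth). Fixed
    seed implies byte-identical output.
    """
    metadata = make_metadata(cfg.n_species, cfg.samples_per_species)
    loci: list[AlignedLocus] = []
    linked_tree: Optional[dendropy.Tree] = None
    for idx, lcfg in enumerate(cfg.loci):
        depth = lcfg.inter_depth - lcfg.intra_depth
        if lcfg.name in cfg.linked_loci:
            if linked_tree is None:
                linked_tree = build_species_tree(
                    cfg.n_species, depth, _derived_seed(cfg.seed, 0)
                )
            tree = scale_tree(linked_tree.clone(depth=1), depth)
        else:
            tree = build_species_tree(
                cfg.n_species, depth, _derived_seed(cfg.seed, idx + 1)
            )
        loci.append(
            simulate_locus(
                tree, lcfg, metadata, _derived_seed(cfg.seed, 100 + idx)
            )
        )
    return BarcodeLibrary(metadata, loci)


def default_config(seed: int = 0) -> SimulationConfig:
    """Library recipe emulating a six-species tropical-hardwood barcode
    study: 39 specimens sampled 4–11 per species, four loci with the
    aligned lengths, recovery rates, and mean intra/interspecific K2P
    depths characteristic of ITS2, matK, ndhF-rpl32 and rbcL, and
    species-fixed indel blocks on the two non-coding regions."""
    loci = (
        LocusConfig(
            name="ITS2", length=234, inter_depth=0.080, intra_depth=0.020,
            kappa=2.0, indel_rate=0.5, indel_length=6, recovery_rate=0.67,
        ),
        LocusConfig(
            name="matK", length=239, inter_depth=0.0099, intra_depth=0.0026,
            kappa=2.0, indel_rate=0.0, recovery_rate=0.82,
        ),
        LocusConfig(
            name="ndhF-rpl32", length=173, inter_depth=0.0091, intra_depth=0.0045,
            kappa=2.0, indel_rate=0.2, indel_length=6, recovery_rate=0.90,
        ),
        LocusConfig(
            name="rbcL", length=350, inter_depth=0.0073, intra_depth=0.0063,
            kappa=2.0, indel_rate=0.0, recovery_rate=0.70,
        ),
    )
    return SimulationConfig(
        n_species=6,
        samples_per_species=(4, 5, 6, 6, 7, 11),
        loci=loci,
        seed=seed,
    )


def simulate_to_dir(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate and write the library (FASTA + TSV), the per-locus true
    trees (Newick), and the config (YAML) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    library = simulate_library(cfg)
    paths = write_library(library, outdir)
    for idx, lcfg in enumerate(cfg.loci):
        depth = lcfg.inter_depth - lcfg.intra_depth
        stream = 0 if lcfg.name in cfg.linked_loci else idx + 1
        tree = build_species_tree(cfg.n_species, depth, _derived_seed(cfg.seed, stream))
        tree = scale_tree(tree, depth)
        tree_path = outdir / f"{lcfg.name}.true.nwk"
        tree_path.write_text(
            tree.as_string(schema="newick", suppress_rooting=True)
        )
        paths[f"{lcfg.name}.true_tree"] = tree_path
    cfg_path = outdir / "simulation.yaml"
    cfg.to_yaml(cfg_path)
    paths["config"] = cfg_path
    return paths
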