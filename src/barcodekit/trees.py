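"""Unrooted neighbor-joining trees, bootstrap support, and cluster scoring.

The discrimination criterion scored here is the tree-based one used in
barcode-library evaluation: a species (or any metadata label) is
*discriminated* when all its specimens form an exclusive cluster on the
unrooted NJ tree — i.e. some edge bipartitions the leaves into exactly that
label's specimens versus all others — and at least one specimen in the
cluster comes from a vouchered collection.

Neighbor joining is implemented here with the Studier–Keppler update and a
deterministic lowest-(row, column) tie break so results are identical across
platforms; trees are returned as :class:`dendropy.Tree` objects (unrooted,
seed node of degree 3) for Newick IO and bipartition work.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .distance import (
    DEFAULT_MIN_OVERLAP,
    DistanceMatrix,
    Model,
    distance_matrix,
    encode_sequences,
    matrix_from_codes,
)
from .errors import IncompleteMatrixError, InsufficientTaxaError
from .library import AlignedLocus, SpecimenRecord

logger = logging.getLogger(__name__)


def neighbor_joining(
    matrix: DistanceMatrix,
    taxon_namespace: Optional[dendropy.TaxonNamespace] = None,
) -> dendropy.Tree:
    """Build an unrooted NJ tree from a complete distance matrix.

    Standard agglomeration on the Q criterion with Studier–Keppler distance
    updates; ties broken by the lowest (row, column) index pair. Negative
    branch lengths are retained as computed. Raises
    :class:`IncompleteMatrixError` on NaN entries and
    :class:`InsufficientTaxaError` below three taxa.
    """
    if np.isnan(matrix.values).any():
        raise IncompleteMatrixError(
            f"{matrix.n_undefined_pairs} undefined entries; prune or impute first"
        )
    if matrix.n < 3:
        raise InsufficientTaxaError(f"need >= 3 taxa, have {matrix.n}")
    tns = taxon_namespace or dendropy.TaxonNamespace(matrix.ids)
    nodes = [
        dendropy.Node(taxon=tns.require_taxon(label=i)) for i in matrix.ids
    ]
    cur = matrix.values.astype(float).copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = cur.sum(axis=1)
        Q = (m - 2) * cur - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # row-major argmin = lexicographically smallest (i, j) among ties
        i, j = divmod(int(np.argmin(Q)), m)
        if i > j:
            i, j = j, i
        dij = cur[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = vi
        parent.add_child(nodes[j])
        nodes[j].edge.length = vj
        dnew = 0.5 * (cur[i, :] + cur[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        nxt = np.empty((m - 1, m - 1))
        nxt[:-1, :-1] = cur[np.ix_(keep, keep)]
        nxt[-1, :-1] = nxt[:-1, -1] = dnew[keep]
        nxt[-1, -1] = 0.0
        cur = nxt
        nodes = [nodes[k] for k in keep] + [parent]
    # closed-form resolution of the last three lineages around a center node
    d01, d02, d12 = cur[0, 1], cur[0, 2], cur[1, 2]
    center = dendropy.Node()
    for node, length in zip(
        nodes,
        (
            0.5 * (d01 + d02 - d12),
            0.5 * (d01 + d12 - d02),
            0.5 * (d02 + d12 - d01),
        ),
    ):
        center.add_child(node)
        node.edge.length = length
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def prune_undefined(matrix: DistanceMatrix) -> tuple[DistanceMatrix, list[str]]:
    """Iteratively drop the specimen with the most undefined entries (ties:
    first in id order) until the matrix is complete. Returns the pruned
    matrix and the removed ids."""
    removed: list[str] = []
    cur = matrix
    while np.isnan(cur.values).any():
        nan_counts = np.isnan(cur.values).sum(axis=1)
        worst = cur.ids[int(np.argmax(nan_counts))]
        removed.append(worst)
        cur = cur.drop([worst])
    if removed:
        logger.info("pruned %d specimens with undefined distances: %s", len(removed), removed)
    return cur, removed


def tree_edge_clusters(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Map each edge of the unrooted tree to the leaf-label set on its head
    side. Every edge induces one bipartition; the complement is implicit."""
    clusters: dict[frozenset, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        leafset = frozenset(lf.taxon.label for lf in node.leaf_iter())
        clusters[leafset] = node
    return clusters


def _node_support(node: dendropy.Node) -> Optional[float]:
    sup = getattr(node, "support", None)
    if sup is not None:
        return float(sup)
    if node.is_internal() and node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            return None
    return None


def bootstrap_support(
    locus: AlignedLocus,
    model: Model = "p",
    n_reps: int = 100,
    seed: int = 0,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> dendropy.Tree:
    """NJ tree for the locus with per-edge bootstrap support percentages.

    Columns are resampled with replacement (same aligned length); each
    replicate matrix is rebuilt and NJ rerun; support for an internal edge
    is the percentage of replicate trees containing the same bipartition.
    Replicates with undefined distances are skipped and logged. Supports are
    stored on internal nodes (``node.support`` and the node label); edges of
    zero length carry no phylogenetic signal and get support 0.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    full = distance_matrix(locus, model, min_overlap)
    pruned, _ = prune_undefined(full)
    if pruned.n < 3:
        raise InsufficientTaxaError("fewer than 3 specimens with defined distances")
    tree = neighbor_joining(pruned)
    tns = tree.taxon_namespace
    keep = set(pruned.ids)
    ids = [i for i in locus.ids if i in keep]
    codes = encode_sequences([s for i, s in locus.rows if i in keep])
    rng = np.random.default_rng(seed)
    L = codes.shape[1]
    split_counts: Counter = Counter()
    n_used = 0
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep_matrix = matrix_from_codes(ids, codes[:, cols], model, min_overlap)
        if np.isnan(rep_matrix.values).any():
            logger.info("bootstrap replicate skipped: undefined distances")
            continue
        rep_tree = neighbor_joining(rep_matrix, taxon_namespace=tns)
        rep_tree.encode_bipartitions()
        for edge in rep_tree.preorder_internal_edge_iter(exclude_seed_edge=True):
            split_counts[edge.bipartition.split_bitmask] += 1
        n_used += 1
    tree.encode_bipartitions()
    for edge in tree.preorder_internal_edge_iter(exclude_seed_edge=True):
        if n_used == 0 or (edge.length is not None and edge.length <= 1e-12):
            support = 0.0
        else:
            support = 100.0 * split_counts[edge.bipartition.split_bitmask] / n_used
        edge.head_node.support = support
        edge.head_node.label = f"{support:.1f}"
    return tree


@dataclass(frozen=True)
class LabelVerdict:
    """Per-label clustering verdict on one tree."""

    label: str
    n_specimens: int
    is_exclusive_cluster: bool
    has_voucher: bool
    support: Optional[float]
    discriminated: bool


@dataclass
class DiscriminationResult:
    """Cluster verdicts for every label plus the overall discrimination rate.

    The rate counts only labels with >= 2 specimens on the tree: a singleton
    leaf is trivially its own cluster and says nothing about cohesion.
    """

    label_field: str
    verdicts: dict[str, LabelVerdict]
    overall_rate: float

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": v.label,
                    "n_specimens": v.n_specimens,
                    "exclusive_cluster": v.is_exclusive_cluster,
                    "has_voucher": v.has_voucher,
                    "support": math.nan if v.support is None else v.support,
                    "discriminated": v.discriminated,
                }
                for v in self.verdicts.values()
            ]
        )


def label_clusters(
    tree: dendropy.Tree,
    specimens: Sequence[SpecimenRecord],
    label_field: str = "species",
    min_support: float = 0.0,
) -> DiscriminationResult:
    """Score each label for exclusive clustering on the unrooted tree.

    A label is an exclusive cluster iff some edge separates exactly its
    leaves from all others; it is *discriminated* when additionally at least
    one of its specimens is vouchered and, when supports are present on the
    tree, the separating edge's support is >= ``min_support``.
    """
    meta = {s.specimen_id: s for s in specimens}
    leaf_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    unknown = [l for l in leaf_labels if l not in meta]
    if unknown:
        raise KeyError(f"leaves without metadata: {unknown}")
    group_of = {l: getattr(meta[l], label_field) for l in leaf_labels}
    all_leaves = frozenset(leaf_labels)
    clusters = tree_edge_clusters(tree)
    groups: dict[str, set] = {}
    for leaf, grp in group_of.items():
        groups.setdefault(grp, set()).add(leaf)
    verdicts: dict[str, LabelVerdict] = {}
    n_discriminated = n_eligible = 0
    for grp in sorted(groups):
        members = frozenset(groups[grp])
        node = clusters.get(members)
        if node is None:
            # the same bipartition may be stored from the complement side
            node = clusters.get(all_leaves - members)
        exclusive = node is not None
        support = _node_support(node) if exclusive else None
        has_voucher = any(meta[l].vouchered for l in members)
        discriminated = (
            exclusive
            and has_voucher
            and (support is None or support >= min_support)
        )
        verdicts[grp] = LabelVerdict(
            grp, len(members), exclusive, has_voucher, support, discriminated
        )
        if len(members) >= 2:
            n_eligible += 1
            n_discriminated += bool(discriminated)
    rate = 100.0 * n_discriminated / n_eligible if n_eligible else math.nan
    return DiscriminationResult(label_field, verdicts, rate)


def write_newick(
    tree: dendropy.Tree, path: str | Path, clamp_negative: bool = False
) -> None:
    """Write Newick with 6-decimal branch lengths; optionally clamp negative
    lengths to zero for viewers that reject them."""
    out = tree.clone(depth=1) if clamp_negative else tree
    if clamp_negative:
        for edge in out.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                edge.length = 0.0
    text = out.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
    )
    Path(path).write_text(text)
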