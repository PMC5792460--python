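"""Multi-locus barcode combinations: concatenation and exhaustive
evaluation of all non-empty locus subsets with both identification methods.

Concatenation is complete-case by default: a specimen enters a combination
only if it has a sequence at every locus in the subset (distance methods
are sensitive to large missing blocks). An 'N'-padding mode keeps every
specimen seen at any subset locus, filling absences with missing data that
pairwise deletion then skips.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .distance import (
    DEFAULT_MIN_OVERLAP,
    GapReport,
    PairwiseSummary,
    barcoding_gap,
    distance_matrix,
    summarize_pairwise,
)
from .errors import BarcodekitError, InsufficientDataError
from .library import AlignedLocus, BarcodeLibrary
from .matching import (
    MatchParameters,
    best_close_match,
    best_match,
    intraspecific_threshold,
    success_rate,
)
from .trees import label_clusters, neighbor_joining, prune_undefined

logger = logging.getLogger(__name__)


def concatenate_loci(
    library: BarcodeLibrary,
    subset: Sequence[str],
    pad_missing: bool = False,
) -> AlignedLocus:
    """Join the subset's alignments into one supermatrix locus.

    Specimens present at all subset loci are retained (complete-case);
    with ``pad_missing`` every specimen present at any subset locus is kept
    and absent loci are filled with 'N'. Sequences are joined in the listed
    locus order; rows follow the library's specimen order.
    """
    if not subset:
        raise ValueError("empty locus subset")
    loci = [library.locus(name) for name in subset]
    if pad_missing:
        kept = [
            s.specimen_id
            for s in library.specimens
            if any(s.specimen_id in set(l.ids) for l in loci)
        ]
    else:
        present = set(loci[0].ids)
        for l in loci[1:]:
            present &= set(l.ids)
        kept = [s.specimen_id for s in library.specimens if s.specimen_id in present]
    if not kept:
        raise InsufficientDataError(
            f"no specimen has sequences at all of {list(subset)}"
        )
    rows = []
    seq_maps = [dict(l.rows) for l in loci]
    for sid in kept:
        parts = [
            m.get(sid, "N" * l.length) for m, l in zip(seq_maps, loci)
        ]
        rows.append((sid, "".join(parts)))
    return AlignedLocus("+".join(subset), rows)


@dataclass
class CombinationResult:
    """Evaluation of one locus subset with both methods."""

    loci: tuple[str, ...]
    n_specimens: int
    summary: Optional[PairwiseSummary] = None
    gap: Optional[GapReport] = None
    threshold: float = math.nan
    best_match_success: float = math.nan
    best_close_match_success: float = math.nan
    tree_discrimination: float = math.nan
    n_pruned_for_tree: int = 0
    error: str = ""

    @property
    def label(self) -> str:
        return "+".join(self.loci)

    def to_row(self) -> dict:
        row: dict = {"loci": self.label, "n_specimens": self.n_specimens}
        s = self.summary.to_row() if self.summary else {}
        row.update({
            "best_match_pct": self.best_match_success,
            "best_close_match_pct": self.best_close_match_success,
            "tree_discrimination_pct": self.tree_discrimination,
            "bcm_threshold": self.threshold,
            "intra_min": s.get("intra_min", math.nan),
            "intra_max": s.get("intra_max", math.nan),
            "intra_mean": s.get("intra_mean", math.nan),
            "inter_min": s.get("inter_min", math.nan),
            "inter_max": s.get("inter_max", math.nan),
            "inter_mean": s.get("inter_mean", math.nan),
            "frac_inter_above_cutoff": self.gap.frac_inter_above if self.gap else math.nan,
            "frac_intra_below_cutoff": self.gap.frac_intra_below if self.gap else math.nan,
            "gap_overlap": self.gap.overlap if self.gap else None,
            "error": self.error,
        })
        return row


def evaluate_combination(
    library: BarcodeLibrary,
    subset: Sequence[str],
    cutoff: float = 0.05,
    percentile: float = 95.0,
    match_model: str = "K2P",
    tree_model: str = "p",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_support: float = 0.0,
    pad_missing: bool = False,
) -> CombinationResult:
    """Run the full single-combination pipeline: K2P summary + gap, best
    match, best close match (threshold from this combination's intraspecific
    distances), and NJ (p-distance) species discrimination."""
    concat = concatenate_loci(library, subset, pad_missing)
    result = CombinationResult(tuple(subset), len(concat.rows))
    matrix = distance_matrix(concat, match_model, min_overlap)  # type: ignore[arg-type]
    summary = summarize_pairwise(matrix, library.specimens)
    result.summary = summary
    try:
        result.gap = barcoding_gap(summary, cutoff)
    except InsufficientDataError as exc:
        logger.warning("combination %s: no gap report: %s", result.label, exc)
    bm = best_match(matrix, library.specimens)
    result.best_match_success = success_rate(bm).success
    try:
        result.threshold = intraspecific_threshold(summary, percentile)
    except InsufficientDataError:
        result.threshold = math.inf
    bcm = best_close_match(
        matrix, library.specimens, MatchParameters(threshold=result.threshold)
    )
    result.best_close_match_success = success_rate(bcm).success
    tree_matrix = distance_matrix(concat, tree_model, min_overlap)  # type: ignore[arg-type]
    pruned, removed = prune_undefined(tree_matrix)
    result.n_pruned_for_tree = len(removed)
    if pruned.n >= 3:
        tree = neighbor_joining(pruned)
        disc = label_clusters(tree, library.specimens, "species", min_support)
        result.tree_discrimination = disc.overall_rate
    return result


def evaluate_combinations(
    library: BarcodeLibrary,
    cutoff: float = 0.05,
    percentile: float = 95.0,
    match_model: str = "K2P",
    tree_model: str = "p",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_support: float = 0.0,
    pad_missing: bool = False,
) -> list[CombinationResult]:
    """Evaluate all 2^k - 1 non-empty locus subsets, ranked by best-close-
    match success (ties: best match, then tree discrimination, then label).

    Per-combination failures are recorded on the result, not raised.
    """
    names = [l.name for l in library.loci]
    if not names:
        raise InsufficientDataError("library has no loci")
    results = []
    for k in range(1, len(names) + 1):
        for subset in itertools.combinations(names, k):
            try:
                results.append(
                    evaluate_combination(
                        library, subset, cutoff, percentile, match_model,
                        tree_model, min_overlap, min_support, pad_missing,
                    )
                )
            except BarcodekitError as exc:
                logger.warning("combination %s failed: %s", "+".join(subset), exc)
                results.append(
                    CombinationResult(tuple(subset), 0, error=str(exc))
                )
    def sort_key(r: CombinationResult):
        return (
            -(r.best_close_match_success if not math.isnan(r.best_close_match_success) else -1.0),
            -(r.best_match_success if not math.isnan(r.best_match_success) else -1.0),
            -(r.tree_discrimination if not math.isnan(r.tree_discrimination) else -1.0),
            r.label,
        )
    return sorted(results, key=sort_key)


def combinations_table(results: Sequence[CombinationResult]) -> pd.DataFrame:
    """Ranked results as one row per combination (TSV-ready)."""
    return pd.DataFrame([r.to_row() for r in results])
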