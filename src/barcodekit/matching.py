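"""Nearest-neighbor species identification (best match / best close match).

Every sequence in the library is treated in turn as a query against all
others. *Best match* assigns the query to the species of its nearest
neighbor(s): if all minimal-distance neighbors (within ``tie_tolerance``)
are conspecific the identification is *correct*; mixed species is
*ambiguous*; all heterospecific is *incorrect*. *Best close match*
additionally rejects queries whose nearest neighbor lies above a distance
threshold — conventionally the 95th percentile of all intraspecific
pairwise distances — as *no_match*. Species represented by a single
sequence can never be matched correctly and are reported as *singleton*,
excluded from the success-rate denominator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .distance import DistanceMatrix, PairwiseSummary
from .errors import InsufficientDataError
from .library import SpecimenRecord

logger = logging.getLogger(__name__)

CATEGORIES = ("correct", "ambiguous", "incorrect", "no_match", "singleton")


@dataclass(frozen=True)
class MatchOutcome:
    """Identification verdict for one query sequence."""

    query_id: str
    category: str
    nearest_ids: tuple[str, ...]
    nearest_distance: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class MatchParameters:
    """Tuning knobs for best-close-match identification."""

    threshold: float = math.inf
    percentile: float = 95.0
    tie_tolerance: float = 0.0

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if not (0 < self.percentile <= 100):
            raise ValueError("percentile must be in (0, 100]")


def _match(
    matrix: DistanceMatrix,
    specimens: Sequence[SpecimenRecord],
    threshold: float,
    tie_tolerance: float,
) -> list[MatchOutcome]:
    species_of = {s.specimen_id: s.species for s in specimens}
    species_counts: dict[str, int] = {}
    for sid in matrix.ids:
        sp = species_of[sid]
        species_counts[sp] = species_counts.get(sp, 0) + 1
    outcomes: list[MatchOutcome] = []
    for i, qid in enumerate(matrix.ids):
        q_species = species_of[qid]
        if species_counts[q_species] < 2:
            outcomes.append(MatchOutcome(qid, "singleton", (), math.nan))
            continue
        row = matrix.values[i].copy()
        row[i] = math.nan
        if np.all(np.isnan(row)):
            logger.warning("query %s: all distances undefined; excluded", qid)
            continue
        dmin = float(np.nanmin(row))
        neighbor_idx = np.where(~np.isnan(row) & (row <= dmin + tie_tolerance))[0]
        neighbors = tuple(matrix.ids[j] for j in neighbor_idx)
        if dmin > threshold:
            category = "no_match"
        else:
            neighbor_species = {species_of[n] for n in neighbors}
            if neighbor_species == {q_species}:
                category = "correct"
            elif q_species in neighbor_species:
                category = "ambiguous"
            else:
                category = "incorrect"
        outcomes.append(MatchOutcome(qid, category, neighbors, dmin))
    return outcomes


def best_match(
    matrix: DistanceMatrix,
    specimens: Sequence[SpecimenRecord],
    tie_tolerance: float = 0.0,
) -> list[MatchOutcome]:
    """Classify every query by the species of its nearest neighbor(s).

    Queries whose distances are all undefined are excluded with a warning.
    """
    return _match(matrix, specimens, math.inf, tie_tolerance)


def intraspecific_threshold(
    summary: PairwiseSummary, percentile: float = 95.0
) -> float:
    """Distance threshold for best close match: a percentile (linear
    interpolation) of all intraspecific pairwise distances."""
    intra = summary.intra_distances
    if not intra:
        raise InsufficientDataError("no intraspecific distances to take a percentile of")
    return float(np.percentile(intra, percentile))


def best_close_match(
    matrix: DistanceMatrix,
    specimens: Sequence[SpecimenRecord],
    params: MatchParameters,
) -> list[MatchOutcome]:
    """Best match with rejection: nearest distance above the threshold
    becomes *no_match*."""
    return _match(matrix, specimens, params.threshold, params.tie_tolerance)


@dataclass(frozen=True)
class SuccessRates:
    """Category breakdown and overall success percentage.

    ``success`` counts only *correct* in the numerator; the denominator is
    all non-singleton queries. Singletons are reported separately.
    """

    success: float
    counts: dict[str, int]
    n_scored: int
    n_singletons: int

    @property
    def percentages(self) -> dict[str, float]:
        return {
            cat: 100.0 * self.counts.get(cat, 0) / self.n_scored
            for cat in ("correct", "ambiguous", "incorrect", "no_match")
        }


def success_rate(outcomes: Sequence[MatchOutcome]) -> SuccessRates:
    """Aggregate outcomes into a success percentage and category breakdown."""
    counts = {cat: 0 for cat in CATEGORIES}
    for o in outcomes:
        counts[o.category] += 1
    n_singletons = counts.pop("singleton")
    n_scored = sum(counts.values())
    if n_scored == 0:
        raise InsufficientDataError("all queries are singletons; no success rate")
    return SuccessRates(
        success=100.0 * counts["correct"] / n_scored,
        counts=counts,
        n_scored=n_scored,
        n_singletons=n_singletons,
    )


def outcomes_table(outcomes: Sequence[MatchOutcome]) -> pd.DataFrame:
    """Per-query outcomes as a tidy table (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "query_id": o.query_id,
                "category": o.category,
                "nearest_ids": ",".join(o.nearest_ids),
                "nearest_distance": o.nearest_distance,
            }
            for o in outcomes
        ]
    )
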