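"""Pairwise genetic distances under pairwise deletion, and barcoding-gap
assessment.

Two models are supported, matching the standard pairing in distance-based
barcoding studies:

* **K2P** (Kimura two-parameter): ``d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))``
  where ``P`` and ``Q`` are the proportions of transition (A<->G, C<->T) and
  transversion differences among compared sites. The correction diverges when
  ``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0`` (saturation); such pairs are
  *undefined* and excluded from summaries.
* **p** (uncorrected): proportion of differing compared sites.

Pairwise deletion: for each sequence pair, only columns where *both*
sequences carry an unambiguous base (A/C/G/T) are compared; gaps, 'N', '?'
and IUPAC ambiguity codes are dropped site-wise. Pairs with fewer than
``min_overlap`` compared sites are undefined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, InsufficientDataError, UndefinedDistanceError
from .library import AlignedLocus, SpecimenRecord

logger = logging.getLogger(__name__)

Model = Literal["K2P", "p"]

#: Minimum compared sites for a defined distance (guards short mini-barcodes
#: with heavy missing data against near-empty overlaps).
DEFAULT_MIN_OVERLAP = 20

# Base encoding: A=0, C=1, G=2, T=3; anything else (gap/missing/ambiguous) = -1.
# With this ordering a mismatch is a transition iff both codes share parity.
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


@dataclass(frozen=True)
class SitePatternCounts:
    """Compared-site classification for one sequence pair."""

    n_compared: int
    n_transition: int
    n_transversion: int

    def __post_init__(self) -> None:
        if self.n_transition + self.n_transversion > self.n_compared:
            raise ValueError("mismatches exceed compared sites")

    @property
    def p_transition(self) -> float:
        return self.n_transition / self.n_compared if self.n_compared else math.nan

    @property
    def p_transversion(self) -> float:
        return self.n_transversion / self.n_compared if self.n_compared else math.nan


def encode_sequences(sequences: Sequence[str]) -> np.ndarray:
    """Encode sequences as an (n, L) int8 array; non-ACGT characters are -1."""
    if not sequences:
        return np.empty((0, 0), dtype=np.int8)
    arr = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    return _ENCODE[arr].reshape(len(sequences), -1)


def _counts_from_codes(a: np.ndarray, b: np.ndarray) -> SitePatternCounts:
    ok = (a >= 0) & (b >= 0)
    ac, bc = a[ok], b[ok]
    diff = ac != bc
    transitions = int(np.count_nonzero(diff & ((ac & 1) == (bc & 1))))
    transversions = int(np.count_nonzero(diff)) - transitions
    return SitePatternCounts(int(ok.sum()), transitions, transversions)


def site_pattern_counts(a: str, b: str) -> SitePatternCounts:
    """Classify compared sites of two aligned sequences under pairwise deletion.

    Columns where either sequence has a gap, 'N', '?' or an ambiguity code
    are skipped; the rest are counted as identical, transition or
    transversion. Raises :class:`AlignmentError` on unequal lengths.
    """
    if len(a) != len(b):
        raise AlignmentError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    codes = encode_sequences([a.upper(), b.upper()])
    return _counts_from_codes(codes[0], codes[1])


def pairwise_distance(
    counts: SitePatternCounts,
    model: Model = "K2P",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> float:
    """Distance (substitutions/site) from site-pattern counts.

    Raises :class:`UndefinedDistanceError` when fewer than ``min_overlap``
    sites were compared, or (K2P only) when the log argument leaves its
    domain — the saturation boundary ``1-2P-Q <= 0`` or ``1-2Q <= 0``.
    """
    if counts.n_compared < min_overlap:
        raise UndefinedDistanceError(
            f"only {counts.n_compared} compared sites (< {min_overlap})"
        )
    if model == "p":
        return (counts.n_transition + counts.n_transversion) / counts.n_compared
    if model == "K2P":
        P, Q = counts.p_transition, counts.p_transversion
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        if w1 <= 0.0 or w2 <= 0.0:
            raise UndefinedDistanceError(
                f"K2P saturated: 1-2P-Q={w1:.4g}, 1-2Q={w2:.4g}"
            )
        return -0.5 * math.log(w1 * math.sqrt(w2))
    raise ValueError(f"unknown model {model!r}")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix; undefined entries are NaN."""

    ids: list[str]
    model: str
    values: np.ndarray  # (n, n) float, diagonal 0, NaN where undefined

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(self.n, k=1)
        return int(np.isnan(self.values[iu]).sum())

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def drop(self, remove: Sequence[str]) -> "DistanceMatrix":
        keep = [k for k, i in enumerate(self.ids) if i not in set(remove)]
        return DistanceMatrix(
            [self.ids[k] for k in keep],
            self.model,
            self.values[np.ix_(keep, keep)].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6f")

    def write_phylip(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            fh.write(f"{self.n}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{name:<12s}{row}\n")


def matrix_from_codes(
    ids: Sequence[str],
    codes: np.ndarray,
    model: Model = "K2P",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> DistanceMatrix:
    """Pairwise distance matrix from pre-encoded sequences (see
    :func:`encode_sequences`); undefined pairs stored as NaN."""
    n = len(ids)
    values = np.zeros((n, n), dtype=float)
    n_undef = 0
    for i in range(n):
        for j in range(i + 1, n):
            counts = _counts_from_codes(codes[i], codes[j])
            try:
                d = pairwise_distance(counts, model, min_overlap)
            except UndefinedDistanceError:
                d = math.nan
                n_undef += 1
            values[i, j] = values[j, i] = d
    if n_undef:
        logger.info("%d undefined %s pairs stored as NaN", n_undef, model)
    return DistanceMatrix(list(ids), model, values)


def distance_matrix(
    locus: AlignedLocus,
    model: Model = "K2P",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> DistanceMatrix:
    """All pairwise distances for a locus; undefined pairs stored as NaN."""
    if len(locus.rows) < 2:
        raise InsufficientDataError(
            f"locus {locus.name!r}: need >= 2 sequences, have {len(locus.rows)}"
        )
    return matrix_from_codes(
        locus.ids, encode_sequences(locus.sequences), model, min_overlap
    )


@dataclass
class PairwiseSummary:
    """Defined pairwise distances split into intra- and interspecific classes."""

    intra: list[tuple[str, str, float]]
    inter: list[tuple[str, str, float]]
    n_undefined: int = 0

    def _stats(self, pairs: list[tuple[str, str, float]]) -> dict[str, float]:
        ds = [d for _, _, d in pairs]
        if not ds:
            return {"n": 0, "min": math.nan, "max": math.nan, "mean": math.nan}
        return {"n": len(ds), "min": min(ds), "max": max(ds), "mean": float(np.mean(ds))}

    @property
    def intra_stats(self) -> dict[str, float]:
        return self._stats(self.intra)

    @property
    def inter_stats(self) -> dict[str, float]:
        return self._stats(self.inter)

    @property
    def intra_distances(self) -> list[float]:
        return [d for _, _, d in self.intra]

    @property
    def inter_distances(self) -> list[float]:
        return [d for _, _, d in self.inter]

    def to_row(self) -> dict[str, float]:
        """One summary row in the conventional min/max/mean layout."""
        a, e = self.intra_stats, self.inter_stats
        return {
            "intra_min": a["min"], "intra_max": a["max"], "intra_mean": a["mean"],
            "inter_min": e["min"], "inter_max": e["max"], "inter_mean": e["mean"],
            "n_intra_pairs": a["n"], "n_inter_pairs": e["n"],
            "n_undefined_pairs": self.n_undefined,
        }


def summarize_pairwise(
    matrix: DistanceMatrix, specimens: Sequence[SpecimenRecord]
) -> PairwiseSummary:
    """Route every defined pair to the intra- or interspecific class.

    Raises ``KeyError`` if a matrix id lacks a species label. Species whose
    pairs are all undefined contribute nothing (a warning is logged).
    """
    species_of = {s.specimen_id: s.species for s in specimens}
    for sid in matrix.ids:
        if sid not in species_of:
            raise KeyError(f"specimen {sid!r} has no metadata record")
    intra, inter = [], []
    n_undef = 0
    for i in range(matrix.n):
        for j in range(i + 1, matrix.n):
            d = matrix.values[i, j]
            a, b = matrix.ids[i], matrix.ids[j]
            if math.isnan(d):
                n_undef += 1
                continue
            (intra if species_of[a] == species_of[b] else inter).append((a, b, float(d)))
    if n_undef:
        logger.warning("%d undefined pairs excluded from pairwise summary", n_undef)
    return PairwiseSummary(intra, inter, n_undef)


@dataclass
class GapReport:
    """Barcoding-gap assessment at a distance cutoff (default 0.05)."""

    cutoff: float
    frac_inter_above: float  # % of interspecific distances strictly > cutoff
    frac_intra_below: float  # % of intraspecific distances strictly < cutoff
    overlap: bool            # max intra >= min inter
    histogram: pd.DataFrame = field(repr=False)  # columns: bin_low, bin_high, intra, inter


def barcoding_gap(
    summary: PairwiseSummary, cutoff: float = 0.05, bin_width: float = 0.01
) -> GapReport:
    """Assess the barcoding gap: distribution overlap and cutoff fractions.

    Fractions use strict inequalities ("greater than" / "lower than" the
    cutoff). Raises :class:`InsufficientDataError` if either class is empty.
    """
    intra, inter = summary.intra_distances, summary.inter_distances
    if not intra or not inter:
        raise InsufficientDataError(
            f"barcoding gap needs both classes (intra={len(intra)}, inter={len(inter)})"
        )
    frac_above = 100.0 * sum(d > cutoff for d in inter) / len(inter)
    frac_below = 100.0 * sum(d < cutoff for d in intra) / len(intra)
    overlap = max(intra) >= min(inter)
    top = max(max(intra), max(inter), cutoff)
    edges = np.arange(0.0, top + bin_width, bin_width)
    if edges[-1] <= top:
        edges = np.append(edges, edges[-1] + bin_width)
    hist = pd.DataFrame({
        "bin_low": edges[:-1],
        "bin_high": edges[1:],
        "intra": np.histogram(intra, bins=edges)[0],
        "inter": np.histogram(inter, bins=edges)[0],
    })
    return GapReport(cutoff, frac_above, frac_below, overlap, hist)
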