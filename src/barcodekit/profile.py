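"""Per-locus alignment characteristics: recovery rate, length, GC content,
variable and parsimony-informative sites, indel columns."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import InsufficientDataError
from .library import AlignedLocus, SpecimenRecord

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class LocusProfile:
    """Summary characteristics of one barcode region's alignment.

    ``indel_columns`` counts alignment columns containing at least one gap
    character, the simplest reproducible reading of an alignment's total
    "indel length" in bp.
    """

    name: str
    n_sequences: int
    recovery_rate: float          # % of specimens with a sequence
    ungapped_length_min: int
    ungapped_length_max: int
    aligned_length: int
    gc_ratio: float               # % G+C over all unambiguous ungapped characters
    n_variable: int
    pct_variable: float
    n_informative: int
    pct_informative: float
    indel_columns: int

    def to_row(self) -> dict:
        return {
            "locus": self.name,
            "recovery_rate_pct": round(self.recovery_rate, 2),
            "n_sequences": self.n_sequences,
            "ungapped_length_bp": f"{self.ungapped_length_min}-{self.ungapped_length_max}",
            "aligned_length_bp": self.aligned_length,
            "gc_ratio_pct": round(self.gc_ratio, 2),
            "n_variable_sites": self.n_variable,
            "pct_variable_sites": round(self.pct_variable, 2),
            "n_informative_sites": self.n_informative,
            "pct_informative_sites": round(self.pct_informative, 2),
            "indel_columns_bp": self.indel_columns,
        }


def profile_locus(
    locus: AlignedLocus, specimens: Sequence[SpecimenRecord]
) -> LocusProfile:
    """Compute alignment characteristics for one locus.

    A *variable* site is a column with >= 2 distinct unambiguous nucleotide
    states (gaps and missing/ambiguity codes excluded from state counting);
    a *parsimony-informative* site additionally has >= 2 states each carried
    by >= 2 sequences. GC ratio pools all unambiguous ungapped characters
    across sequences.
    """
    if len(locus.rows) < 2:
        raise InsufficientDataError(
            f"locus {locus.name!r}: need >= 2 sequences to profile"
        )
    seqs = locus.sequences
    L = locus.length
    n_variable = n_informative = indel_columns = 0
    for col in range(L):
        column = [s[col] for s in seqs]
        if "-" in column:
            indel_columns += 1
        states = Counter(c for c in column if c in _BASES)
        if len(states) >= 2:
            n_variable += 1
            if sum(1 for cnt in states.values() if cnt >= 2) >= 2:
                n_informative += 1
    gc = total = 0
    for s in seqs:
        for c in s:
            if c in _BASES:
                total += 1
                if c in "GC":
                    gc += 1
    ungapped = [sum(1 for c in s if c != "-") for s in seqs]
    return LocusProfile(
        name=locus.name,
        n_sequences=len(seqs),
        recovery_rate=100.0 * len(seqs) / len(specimens) if specimens else 0.0,
        ungapped_length_min=min(ungapped),
        ungapped_length_max=max(ungapped),
        aligned_length=L,
        gc_ratio=100.0 * gc / total if total else 0.0,
        n_variable=n_variable,
        pct_variable=100.0 * n_variable / L if L else 0.0,
        n_informative=n_informative,
        pct_informative=100.0 * n_informative / L if L else 0.0,
        indel_columns=indel_columns,
    )


def profiles_table(
    loci: Sequence[AlignedLocus], specimens: Sequence[SpecimenRecord]
) -> pd.DataFrame:
    """One row per locus, mirroring the conventional locus-characteristics table."""
    return pd.DataFrame([profile_locus(l, specimens).to_row() for l in loci])
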