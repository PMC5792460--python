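"""Character-based diagnostics between a species pair: fixed diagnostic
sites and contiguous diagnostic blocks (substitution or indel).

A column is diagnostic for species A vs B when every member of A shares one
state, every member of B shares one (different) state, and — because
diagnostic mini-barcodes are often anchored on insertions/deletions — the
gap character counts as a fifth state. Missing symbols ('N', '?') and IUPAC
ambiguity codes disqualify a column unless ``allow_missing`` relaxes this by
ignoring those sequences column-wise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import InsufficientDataError
from .library import AlignedLocus, SpecimenRecord

_STATES = frozenset("ACGT-")


@dataclass(frozen=True)
class DiagnosticSite:
    """One alignment column fixed for different states in two species."""

    column: int  # 1-based alignment column
    state_a: str
    state_b: str


@dataclass(frozen=True)
class DiagnosticBlock:
    """A maximal run of consecutive diagnostic columns.

    Coordinates are 1-based inclusive alignment columns; ``kind`` is
    ``indel`` when one species' state string is entirely gaps across the
    block, else ``substitution``.
    """

    locus: str
    species_pair: tuple[str, str]
    start: int
    end: int
    state_a: str
    state_b: str
    kind: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_bed(self) -> tuple[str, int, int]:
        """Half-open 0-based record (locus, start-1, end)."""
        return (self.locus, self.start - 1, self.end)


def _fixed_state(column_chars: list[str], allow_missing: bool) -> str | None:
    """The single shared state of a species at one column, or None."""
    if allow_missing:
        column_chars = [c for c in column_chars if c in _STATES]
        if not column_chars:
            return None
    states = set(column_chars)
    if len(states) == 1:
        state = states.pop()
        return state if state in _STATES else None
    return None


def diagnostic_sites(
    locus: AlignedLocus,
    specimens: Sequence[SpecimenRecord],
    species_a: str,
    species_b: str,
    allow_missing: bool = False,
) -> list[DiagnosticSite]:
    """All columns where species A and B are fixed for different states."""
    species_of = {s.specimen_id: s.species for s in specimens}
    seqs_a = [s for i, s in locus.rows if species_of.get(i) == species_a]
    seqs_b = [s for i, s in locus.rows if species_of.get(i) == species_b]
    if not seqs_a or not seqs_b:
        missing = [sp for sp, seqs in ((species_a, seqs_a), (species_b, seqs_b)) if not seqs]
        raise InsufficientDataError(
            f"locus {locus.name!r}: no sequences for species {missing}"
        )
    sites = []
    for col in range(locus.length):
        state_a = _fixed_state([s[col] for s in seqs_a], allow_missing)
        state_b = _fixed_state([s[col] for s in seqs_b], allow_missing)
        if state_a is not None and state_b is not None and state_a != state_b:
            sites.append(DiagnosticSite(col + 1, state_a, state_b))
    return sites


def diagnostic_blocks(
    sites: Sequence[DiagnosticSite],
    locus: str = "",
    species_pair: tuple[str, str] = ("", ""),
) -> list[DiagnosticBlock]:
    """Merge sorted diagnostic sites into maximal contiguous blocks."""
    blocks: list[DiagnosticBlock] = []
    run: list[DiagnosticSite] = []

    def flush() -> None:
        if not run:
            return
        state_a = "".join(s.state_a for s in run)
        state_b = "".join(s.state_b for s in run)
        kind = (
            "indel"
            if set(state_a) == {"-"} or set(state_b) == {"-"}
            else "substitution"
        )
        blocks.append(
            DiagnosticBlock(
                locus, species_pair, run[0].column, run[-1].column,
                state_a, state_b, kind,
            )
        )

    for site in sites:
        if run and site.column != run[-1].column + 1:
            flush()
            run = []
        run.append(site)
    flush()
    return blocks


def find_diagnostic_blocks(
    locus: AlignedLocus,
    specimens: Sequence[SpecimenRecord],
    species_a: str,
    species_b: str,
    allow_missing: bool = False,
) -> list[DiagnosticBlock]:
    """Diagnostic sites plus block merging in one call."""
    sites = diagnostic_sites(locus, specimens, species_a, species_b, allow_missing)
    return diagnostic_blocks(sites, locus.name, (species_a, species_b))


def ungapped_position(locus: AlignedLocus, specimen_id: str, column: int) -> int:
    """Map a 1-based alignment column to the 1-based ungapped coordinate of
    one specimen's sequence (position of the last base at or before the
    column; 0 if none)."""
    seq = dict(locus.rows)[specimen_id]
    return sum(1 for c in seq[:column] if c != "-")


def blocks_table(blocks: Sequence[DiagnosticBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus": b.locus,
                "species_a": b.species_pair[0],
                "species_b": b.species_pair[1],
                "start": b.start,
                "end": b.end,
                "length": b.length,
                "kind": b.kind,
                "state_a": b.state_a,
                "state_b": b.state_b,
            }
            for b in blocks
        ]
    )
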