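"""Specimen metadata, per-locus alignments, and multi-locus barcode libraries.

A barcode reference library couples one specimen table (species assignment,
voucher status, tissue, geographic region) with one pre-aligned FASTA per
barcode region. This module defines the in-memory containers and their
TSV/FASTA round trip, and validates cross-references between the two.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, FormatError, ValidationError

#: Characters legal in an aligned nucleotide sequence: the four bases,
#: IUPAC ambiguity codes, the gap character and '?' for missing data.
ALPHABET = frozenset("ACGTRYSWKMBDHVN-?")

TISSUES = ("heartwood", "sapwood", "twig", "leaf")

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}

METADATA_COLUMNS = ("specimen_id", "species", "vouchered", "region", "tissue")


@dataclass(frozen=True)
class SpecimenRecord:
    """Metadata for one specimen in the reference library."""

    specimen_id: str
    species: str
    vouchered: bool = True
    region: str = ""
    tissue: str = "leaf"

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise ValidationError("specimen_id must be non-empty")
        if not self.species:
            raise ValidationError(f"specimen {self.specimen_id!r}: species must be non-empty")


@dataclass
class AlignedLocus:
    """One barcode region's alignment: ordered (specimen_id, sequence) rows.

    All sequences share one aligned length; uppercase; gaps are '-',
    missing data 'N'/'?'.
    """

    name: str
    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise AlignmentError(
                f"locus {self.name!r}: unequal sequence lengths {sorted(lengths)}"
            )
        ids = [i for i, _ in self.rows]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"locus {self.name!r}: duplicate specimen ids {dupes}")

    @property
    def length(self) -> int:
        """Aligned length in sites (0 for an empty locus)."""
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    @property
    def sequences(self) -> list[str]:
        return [s for _, s in self.rows]

    def subset(self, ids: Iterable[str]) -> "AlignedLocus":
        """Restrict to the given specimen ids, preserving row order."""
        keep = set(ids)
        return AlignedLocus(self.name, [(i, s) for i, s in self.rows if i in keep])


@dataclass
class BarcodeLibrary:
    """A specimen table plus one alignment per barcode region."""

    specimens: list[SpecimenRecord]
    loci: list[AlignedLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.specimen_id for s in self.specimens]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate specimen ids in metadata: {dupes}")
        names = [l.name for l in self.loci]
        if len(names) != len(set(names)):
            raise ValidationError(f"duplicate locus names: {names}")
        known = set(ids)
        for locus in self.loci:
            orphans = [i for i in locus.ids if i not in known]
            if orphans:
                raise ValidationError(
                    f"locus {locus.name!r}: rows reference unknown specimens {orphans}"
                )

    @property
    def species_of(self) -> dict[str, str]:
        return {s.specimen_id: s.species for s in self.specimens}

    def locus(self, name: str) -> AlignedLocus:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(f"no locus named {name!r}; have {[l.name for l in self.loci]}")


def read_alignment(path: str | Path | io.TextIOBase, name: str) -> AlignedLocus:
    """Read an aligned FASTA file into an :class:`AlignedLocus`.

    The first whitespace-delimited header token is the specimen id; the
    remainder of the header is ignored. Sequences are uppercased. Unequal
    lengths raise :class:`AlignmentError`; an empty file or an illegal
    character raises :class:`FormatError` naming the offending record.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise FormatError(f"locus {name!r}: no FASTA records in {path}")
    rows: list[tuple[str, str]] = []
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - ALPHABET
        if bad:
            raise FormatError(
                f"locus {name!r}, record {rec.id!r}: illegal characters {sorted(bad)}"
            )
        rows.append((rec.id, seq))
    return AlignedLocus(name, rows)


def write_alignment(locus: AlignedLocus, path: str | Path) -> None:
    """Write a locus as aligned FASTA (UTF-8, Unix line endings)."""
    records = [
        SeqRecord(Seq(seq), id=spec_id, description="") for spec_id, seq in locus.rows
    ]
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta")


def _parse_bool(token: object, context: str) -> bool:
    text = str(token).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise FormatError(f"{context}: cannot parse boolean from {token!r}")


def read_metadata(path: str | Path | io.TextIOBase) -> list[SpecimenRecord]:
    """Read the specimen table (TSV with header) into records.

    Required columns: specimen_id, species, vouchered, region, tissue.
    Booleans accept true/false, 1/0, yes/no in any case.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"metadata file {path} is empty") from exc
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata file {path}: missing columns {missing}")
    records = [
        SpecimenRecord(
            specimen_id=row.specimen_id,
            species=row.species,
            vouchered=_parse_bool(row.vouchered, f"specimen {row.specimen_id!r}"),
            region=row.region,
            tissue=row.tissue,
        )
        for row in df.itertuples(index=False)
    ]
    ids = [r.specimen_id for r in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"metadata file {path}: duplicate specimen ids {dupes}")
    return records


def write_metadata(specimens: Sequence[SpecimenRecord], path: str | Path) -> None:
    """Write the specimen table as TSV (UTF-8, Unix line endings)."""
    df = pd.DataFrame(
        [
            (s.specimen_id, s.species, str(s.vouchered).lower(), s.region, s.tissue)
            for s in specimens
        ],
        columns=list(METADATA_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_library(library: BarcodeLibrary, outdir: str | Path) -> dict[str, Path]:
    """Write metadata TSV plus one FASTA per locus into ``outdir``.

    Returns a mapping from artifact name to path ('metadata' plus each
    locus name).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    meta_path = outdir / "specimens.tsv"
    write_metadata(library.specimens, meta_path)
    paths["metadata"] = meta_path
    for locus in library.loci:
        p = outdir / f"{locus.name}.fasta"
        write_alignment(locus, p)
        paths[locus.name] = p
    return paths


def read_library(metadata_path: str | Path, locus_paths: dict[str, str | Path]) -> BarcodeLibrary:
    """Assemble a validated library from a metadata TSV and per-locus FASTAs."""
    specimens = read_metadata(metadata_path)
    loci = [read_alignment(p, name) for name, p in locus_paths.items()]
    return BarcodeLibrary(specimens, loci)
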