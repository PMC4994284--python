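"""Readers and writers for the formats the pipeline touches.

Supported formats:

* FASTA (fragments, reference, assembled chromosomes) — written uppercase,
  wrapped at 60 columns; case is preserved on read.
* BLAST tabular ``outfmt 6`` (12 columns) for pairwise alignments; BLAST's
  1-based inclusive coordinates are normalized to zero-based half-open
  ascending on read, with descending subject coordinates encoding reverse
  orientation.
* The fragment map: an 8-column TSV (fragment_id, fragment_length,
  fragment_start, fragment_end, orientation, chrom_id, chrom_start,
  chrom_end) recording where each fragment — or an inserted ``GAP`` — sits
  on an assembled chromosome.
* BED (0-based half-open) and GFF3 (1-based inclusive) annotations; all
  non-coordinate columns are preserved verbatim through read -> write.
* BED6 genome-browser tracks of fragment positions.

Everything in memory is zero-based half-open; conversions happen only at
format boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from chromodraft.core import (
    DIRECT,
    REVERSE,
    AlignmentRecord,
    ChromodraftError,
    Feature,
    InconsistentInputError,
)

PathLike = Union[str, Path]

#: fragment_id used by map records that represent inserted gap runs of 'N'.
GAP_ID = "GAP"

_IUPAC_NT = frozenset("ACGTUNRYSWKMBDHVacgtunryswkmbdhv")


class ParseError(ChromodraftError):
    """A malformed input file; the message names the file and line."""


class ValidationError(ChromodraftError):
    """Records that violate a format invariant (overlap, ordering, dupes)."""


class GenomeSequences(dict):
    """Ordered mapping of sequence id -> nucleotide string.

    A thin dict specialization that rejects duplicate ids and empty
    sequences, shared by fragments, reference chromosomes and assembled
    output.
    """

    def __setitem__(self, key: str, value: str) -> None:
        if key in self:
            raise ValidationError(f"duplicate sequence id {key!r}")
        if not value:
            raise ValidationError(f"sequence {key!r} is empty")
        super().__setitem__(key, value)


@dataclass(frozen=True)
class FragmentMapRecord:
    """One row of the fragment map: a fragment (or gap) on an assembled
    chromosome.  Orientation is '+' or '-'; gap records use fragment_id
    ``GAP`` and span ``chrom_end - chrom_start`` bases of 'N'."""

    fragment_id: str
    fragment_length: int
    fragment_start: int
    fragment_end: int
    orientation: str
    chrom_id: str
    chrom_start: int
    chrom_end: int

    def __post_init__(self) -> None:
        if self.orientation not in (DIRECT, REVERSE):
            raise ValidationError(
                f"map record {self.fragment_id!r}: orientation must be "
                f"'+' or '-', got {self.orientation!r}"
            )
        if self.chrom_end - self.chrom_start != self.fragment_end - self.fragment_start:
            raise ValidationError(
                f"map record {self.fragment_id!r}: chromosome span "
                f"[{self.chrom_start}, {self.chrom_end}) does not match "
                f"fragment span [{self.fragment_start}, {self.fragment_end})"
            )
        if not self.is_gap and self.fragment_end - self.fragment_start != self.fragment_length:
            raise ValidationError(
                f"map record {self.fragment_id!r}: fragment span does not "
                f"cover the full fragment length {self.fragment_length}"
            )
        if self.is_gap and self.fragment_length != self.chrom_end - self.chrom_start:
            raise ValidationError(
                f"gap record at {self.chrom_id}:[{self.chrom_start}, "
                f"{self.chrom_end}): length field {self.fragment_length} "
                "does not equal the spanned interval"
            )

    @property
    def is_gap(self) -> bool:
        return self.fragment_id == GAP_ID


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> GenomeSequences:
    """Read a FASTA file into a :class:`GenomeSequences` mapping.

    Sequence case is preserved.  Malformed headers, duplicate ids and
    non-IUPAC characters raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    sequences = GenomeSequences()
    current_id: Optional[str] = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(
                f"{path}:{header_line}: sequence {current_id!r} is empty"
            )
        if current_id in sequences:
            raise ParseError(
                f"{path}:{header_line}: duplicate sequence id {current_id!r}"
            )
        sequences[current_id] = seq

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0] if line[1:].split() else ""
                if not current_id:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if current_id is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence data before any header"
                    )
                bad = set(line) - _IUPAC_NT
                if bad:
                    raise ParseError(
                        f"{path}:{lineno}: non-IUPAC nucleotide character(s) "
                        f"{''.join(sorted(bad))!r} in sequence {current_id!r}"
                    )
                chunks.append(line)
        flush()
    if not sequences:
        raise ParseError(f"{path}: no FASTA records found")
    return sequences


def write_fasta(
    sequences: Mapping[str, str], path: PathLike, line_width: int = 60
) -> None:
    """Write sequences as uppercase FASTA wrapped at ``line_width`` columns."""
    records = (
        SeqRecord(Seq(seq.upper()), id=seq_id, description="")
        for seq_id, seq in sequences.items()
    )
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=line_width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

_BLAST_COLUMNS = 12


def parse_blast_tabular(path: PathLike) -> list[AlignmentRecord]:
    """Parse 12-column BLAST tabular output into alignment records.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Query/subject coordinates are 1-based
    inclusive; ``sstart > send`` encodes a reverse-strand hit.  All
    coordinates are normalized to zero-based half-open ascending.
    """
    path = Path(path)
    records: list[AlignmentRecord] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _BLAST_COLUMNS:
                raise ParseError(
                    f"{path}:{lineno}: expected {_BLAST_COLUMNS} tab-separated "
                    f"columns, found {len(fields)}"
                )
            try:
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                score = float(fields[11])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric coordinate or score: {exc}"
                ) from None
            orientation = DIRECT if sstart <= send else REVERSE
            records.append(
                AlignmentRecord(
                    fragment_id=fields[0],
                    fragment_start=min(qstart, qend) - 1,
                    fragment_end=max(qstart, qend),
                    ref_id=fields[1],
                    ref_start=min(sstart, send) - 1,
                    ref_end=max(sstart, send),
                    orientation=orientation,
                    score=score,
                )
            )
    return records


def write_blast_tabular(alignments: Iterable[AlignmentRecord], path: PathLike) -> None:
    """Write alignments as 12-column BLAST tabular lines (inverse of
    :func:`parse_blast_tabular`; identity/mismatch/gap/evalue columns are
    filled with exact-match placeholders)."""
    with open(path, "w") as handle:
        for aln in alignments:
            length = aln.fragment_end - aln.fragment_start
            if aln.orientation == DIRECT:
                sstart, send = aln.ref_start + 1, aln.ref_end
            else:
                sstart, send = aln.ref_end, aln.ref_start + 1
            handle.write(
                "\t".join(
                    str(x)
                    for x in (
                        aln.fragment_id,
                        aln.ref_id,
                        "100.00",
                        length,
                        0,
                        0,
                        aln.fragment_start + 1,
                        aln.fragment_end,
                        sstart,
                        send,
                        "0.0",
                        f"{aln.score:g}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Fragment map TSV


def validate_fragment_map(records: Sequence[FragmentMapRecord]) -> None:
    """Check that records on each chromosome are sorted and non-overlapping."""
    last: dict[str, FragmentMapRecord] = {}
    seen_ids: set[str] = set()
    for rec in records:
        if not rec.is_gap:
            if rec.fragment_id in seen_ids:
                raise ValidationError(
                    f"fragment {rec.fragment_id!r} appears twice in the map"
                )
            seen_ids.add(rec.fragment_id)
        prev = last.get(rec.chrom_id)
        if prev is not None and rec.chrom_start < prev.chrom_end:
            raise ValidationError(
                f"map records overlap or are unsorted on {rec.chrom_id}: "
                f"{prev.fragment_id!r} [{prev.chrom_start}, {prev.chrom_end}) "
                f"vs {rec.fragment_id!r} [{rec.chrom_start}, {rec.chrom_end})"
            )
        last[rec.chrom_id] = rec


def write_fragment_map(
    records: Sequence[FragmentMapRecord], path: PathLike
) -> None:
    """Write the fragment map as 8-column TSV after validating it."""
    validate_fragment_map(records)
    with open(path, "w") as handle:
        for rec in records:
            handle.write(
                "\t".join(
                    str(x)
                    for x in (
                        rec.fragment_id,
                        rec.fragment_length,
                        rec.fragment_start,
                        rec.fragment_end,
                        rec.orientation,
                        rec.chrom_id,
                        rec.chrom_start,
                        rec.chrom_end,
                    )
                )
                + "\n"
            )


def read_fragment_map(path: PathLike) -> list[FragmentMapRecord]:
    """Read an 8-column fragment map TSV and validate it."""
    path = Path(path)
    records: list[FragmentMapRecord] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise ParseError(
                    f"{path}:{lineno}: expected 8 tab-separated columns, "
                    f"found {len(fields)}"
                )
            try:
                records.append(
                    FragmentMapRecord(
                        fragment_id=fields[0],
                        fragment_length=int(fields[1]),
                        fragment_start=int(fields[2]),
                        fragment_end=int(fields[3]),
                        orientation=fields[4],
                        chrom_id=fields[5],
                        chrom_start=int(fields[6]),
                        chrom_end=int(fields[7]),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    validate_fragment_map(records)
    return records


# ---------------------------------------------------------------------------
# Annotations (BED / GFF3)

BED = "bed"
GFF3 = "gff3"


def read_features(path: PathLike, format: str) -> list[Feature]:
    """Read BED or GFF3 annotations into :class:`Feature` records.

    BED intervals are already zero-based half-open; GFF3's 1-based inclusive
    columns 4-5 are converted.  All non-coordinate columns are preserved
    verbatim in ``Feature.payload`` so writing reproduces the input.
    """
    if format == BED:
        return _read_bed(path)
    if format == GFF3:
        return _read_gff3(path)
    raise ValueError(f"unknown annotation format {format!r}")


def write_features(
    features: Iterable[Feature], path: PathLike, format: str
) -> None:
    """Write features in the given format, restoring preserved columns."""
    if format not in (BED, GFF3):
        raise ValueError(f"unknown annotation format {format!r}")
    with open(path, "w") as handle:
        for feat in features:
            handle.write(_format_feature(feat, format) + "\n")


def _read_bed(path: PathLike) -> list[Feature]:
    path = Path(path)
    features: list[Feature] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: BED needs at least 3 columns, "
                    f"found {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer BED coordinates"
                ) from None
            if start >= end:
                raise ParseError(
                    f"{path}:{lineno}: empty or inverted interval "
                    f"[{start}, {end})"
                )
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            features.append(
                Feature(
                    seq_id=fields[0],
                    start=start,
                    end=end,
                    strand=strand,
                    payload=(BED, tuple(fields[3:])),
                )
            )
    return features


def _read_gff3(path: PathLike) -> list[Feature]:
    path = Path(path)
    features: list[Feature] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}:{lineno}: GFF3 needs 9 columns, found {len(fields)}"
                )
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer GFF3 coordinates"
                ) from None
            start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            if start >= end or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: empty or inverted interval after "
                    f"normalization [{start}, {end})"
                )
            strand = fields[6] if fields[6] in "+-" else "."
            features.append(
                Feature(
                    seq_id=fields[0],
                    start=start,
                    end=end,
                    strand=strand,
                    payload=(GFF3, tuple(fields[1:3] + fields[5:6] + fields[7:9])),
                )
            )
    return features


def _format_feature(feat: Feature, format: str) -> str:
    tag = feat.payload[0] if feat.payload else None
    extra = feat.payload[1] if tag in (BED, GFF3) else ()
    if format == BED:
        if tag == BED:
            cols = list(extra)
            # re-slot the (possibly flipped) strand into column 6 if present
            if len(cols) >= 3:
                cols[2] = feat.strand
            elif len(cols) == 2:
                cols.append(feat.strand)
            return "\t".join([feat.seq_id, str(feat.start), str(feat.end), *cols])
        name = extra[1] if tag == GFF3 and len(extra) > 1 else "."
        return "\t".join(
            [feat.seq_id, str(feat.start), str(feat.end), name, "0", feat.strand]
        )
    # GFF3 output
    if tag == GFF3:
        source, ftype, score, phase, attributes = extra
    else:
        source, ftype, score, phase, attributes = ".", "region", ".", ".", "."
        if tag == BED and len(extra) >= 1:
            attributes = f"Name={extra[0]}"
    return "\t".join(
        [
            feat.seq_id,
            source,
            ftype,
            str(feat.start + 1),
            str(feat.end),
            score,
            feat.strand,
            phase,
            attributes,
        ]
    )


# ---------------------------------------------------------------------------
# Genome-browser track


def map_to_bed_track(records: Sequence[FragmentMapRecord], path: PathLike) -> None:
    """Write fragment positions as a BED6 browser track (gap records are
    not fragments and are omitted)."""
    with open(path, "w") as handle:
        for rec in records:
            if rec.is_gap:
                continue
            handle.write(
                "\t".join(
                    (
                        rec.chrom_id,
                        str(rec.chrom_start),
                        str(rec.chrom_end),
                        rec.fragment_id,
                        "0",
                        rec.orientation,
                    )
                )
                + "\n"
            )
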