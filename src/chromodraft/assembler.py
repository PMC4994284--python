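"""Arrange anchored fragments into draft chromosomes.

The pipeline: classify every fragment by its alignment-score ratio, place
anchored fragments on the reference frame, resolve overlaps between placed
neighbours by shifting the downstream fragment (and everything after it)
by ``overlap + gap_size`` base pairs, then emit chromosome sequences in
which fragments are separated by runs of 'N'.

Overlap resolution keeps the shift cumulative: once fragment B is pushed
right to clear fragment A, every fragment downstream of B moves by the
same amount, so reference-derived spacing between non-overlapping
neighbours is preserved and one overlap can never create another.
Unlocalized and unplaced fragments are excluded from the assembly and
reported in id lists instead.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio.Seq import Seq

from chromodraft.core import (
    ANCHORED,
    DIRECT,
    REVERSE,
    UNLOCALIZED,
    UNPLACED,
    AlignmentRecord,
    Feature,
    FragmentAnchor,
    FragmentClassification,
    InconsistentInputError,
    classify_fragment,
    transfer_region,
)
from chromodraft.io import (
    GAP_ID,
    FragmentMapRecord,
    GenomeSequences,
    validate_fragment_map,
)


@dataclass
class AssemblyResult:
    """Everything one assembly run produces: the fragment map, the assembled
    chromosome sequences (once emitted), and the ids excluded from the
    assembly.  Every input fragment lands in exactly one of the map, the
    unlocalized list or the unplaced list (alignment-free fragments count
    as unplaced)."""

    map: list[FragmentMapRecord]
    unlocalized_ids: list[str]
    unplaced_ids: list[str]
    chromosomes: GenomeSequences = field(default_factory=GenomeSequences)
    classifications: dict[str, FragmentClassification] = field(default_factory=dict)


@dataclass(frozen=True)
class ChromosomeStats:
    fragment_count: int
    assembled_length: int
    gap_bp: int


@dataclass(frozen=True)
class AssemblyStats:
    """Summary counts for one assembly run."""

    anchored_count: int
    unlocalized_count: int
    unplaced_count: int
    anchored_bp: int
    unlocalized_bp: int
    unplaced_bp: int
    per_chromosome: Mapping[str, ChromosomeStats]
    total_length: int
    total_gap_bp: int
    n_fraction: float


def layout_chromosome(
    anchors: Sequence[FragmentAnchor], gap_size: int
) -> list[FragmentMapRecord]:
    """Lay out the anchors of one reference chromosome into disjoint map
    records, inserting ``GAP`` records between fragments.

    Anchors are sorted by (placed_start, placed_end, fragment_id).  A
    cumulative shift starts at ``max(0, -first placed_start)`` (clamping
    fragments that overhang the reference start) and grows by
    ``overlap + gap_size`` whenever a fragment's shifted start would fall
    inside the previous fragment, so formerly overlapping neighbours end up
    separated by exactly ``gap_size`` and downstream spacing is preserved.
    """
    if gap_size < 0:
        raise InconsistentInputError(f"gap_size must be >= 0, got {gap_size}")
    if not anchors:
        return []
    ref_ids = {a.ref_id for a in anchors}
    if len(ref_ids) != 1:
        raise InconsistentInputError(
            f"layout_chromosome got anchors on multiple chromosomes: "
            f"{sorted(ref_ids)}"
        )
    seen: set[str] = set()
    for anchor in anchors:
        if anchor.fragment_id in seen:
            raise InconsistentInputError(
                f"duplicate anchor for fragment {anchor.fragment_id!r}"
            )
        seen.add(anchor.fragment_id)

    ordered = sorted(
        anchors, key=lambda a: (a.placed_start, a.placed_end, a.fragment_id)
    )
    chrom_id = ordered[0].ref_id
    shift = max(0, -ordered[0].placed_start)

    records: list[FragmentMapRecord] = []
    prev_end: Optional[int] = None
    for anchor in ordered:
        start = anchor.placed_start + shift
        if prev_end is not None and start < prev_end:
            overlap = prev_end - start
            shift += overlap + gap_size
            start = anchor.placed_start + shift
        if prev_end is not None and start > prev_end:
            records.append(_gap_record(chrom_id, prev_end, start))
        end = start + anchor.fragment_length
        records.append(
            FragmentMapRecord(
                fragment_id=anchor.fragment_id,
                fragment_length=anchor.fragment_length,
                fragment_start=0,
                fragment_end=anchor.fragment_length,
                orientation=anchor.orientation,
                chrom_id=chrom_id,
                chrom_start=start,
                chrom_end=end,
            )
        )
        prev_end = end
    return records


def _gap_record(chrom_id: str, start: int, end: int) -> FragmentMapRecord:
    return FragmentMapRecord(
        fragment_id=GAP_ID,
        fragment_length=end - start,
        fragment_start=0,
        fragment_end=end - start,
        orientation=DIRECT,
        chrom_id=chrom_id,
        chrom_start=start,
        chrom_end=end,
    )


def build_fragment_map(
    fragments: GenomeSequences,
    alignments: Sequence[AlignmentRecord],
    ratio_threshold: float,
    gap_size: int,
) -> AssemblyResult:
    """Classify all fragments and lay anchored ones out per chromosome.

    Fragments with no alignments are listed as unplaced.  Returns an
    :class:`AssemblyResult` whose ``chromosomes`` are not yet emitted (see
    :func:`emit_sequences`).
    """
    by_fragment: dict[str, list[AlignmentRecord]] = {}
    for aln in alignments:
        if aln.fragment_id not in fragments:
            raise InconsistentInputError(
                f"alignment references unknown fragment {aln.fragment_id!r}"
            )
        if aln.fragment_end > len(fragments[aln.fragment_id]):
            raise InconsistentInputError(
                f"alignment of {aln.fragment_id!r} ends at "
                f"{aln.fragment_end}, beyond the fragment length "
                f"{len(fragments[aln.fragment_id])}"
            )
        by_fragment.setdefault(aln.fragment_id, []).append(aln)

    classifications: dict[str, FragmentClassification] = {}
    unlocalized: list[str] = []
    unplaced: list[str] = []
    anchors_by_chrom: "OrderedDict[str, list[FragmentAnchor]]" = OrderedDict()

    for fragment_id, sequence in fragments.items():
        alns = by_fragment.get(fragment_id)
        if not alns:
            classification = FragmentClassification(fragment_id, UNPLACED)
        else:
            classification = classify_fragment(
                fragment_id, len(sequence), alns, ratio_threshold
            )
        classifications[fragment_id] = classification
        if classification.status == ANCHORED:
            anchor = classification.anchor
            anchors_by_chrom.setdefault(anchor.ref_id, []).append(anchor)
        elif classification.status == UNLOCALIZED:
            unlocalized.append(fragment_id)
        else:
            unplaced.append(fragment_id)

    records: list[FragmentMapRecord] = []
    for chrom_id in sorted(anchors_by_chrom):
        records.extend(layout_chromosome(anchors_by_chrom[chrom_id], gap_size))
    validate_fragment_map(records)

    return AssemblyResult(
        map=records,
        unlocalized_ids=unlocalized,
        unplaced_ids=unplaced,
        classifications=classifications,
    )


def emit_sequences(
    map_records: Sequence[FragmentMapRecord], fragments: GenomeSequences
) -> GenomeSequences:
    """Build chromosome sequences from the fragment map.

    Fragment intervals carry the fragment sequence (reverse-complemented
    for '-' records); gap intervals and any uncovered prefix are filled
    with 'N'.  Each chromosome ends at the chrom_end of its last record.
    """
    validate_fragment_map(map_records)
    pieces: "OrderedDict[str, list[str]]" = OrderedDict()
    cursor: dict[str, int] = {}
    for rec in map_records:
        parts = pieces.setdefault(rec.chrom_id, [])
        pos = cursor.get(rec.chrom_id, 0)
        if rec.chrom_start > pos:
            parts.append("N" * (rec.chrom_start - pos))
        if rec.is_gap:
            parts.append("N" * (rec.chrom_end - rec.chrom_start))
        else:
            if rec.fragment_id not in fragments:
                raise InconsistentInputError(
                    f"map references unknown fragment {rec.fragment_id!r}"
                )
            seq = fragments[rec.fragment_id]
            if len(seq) != rec.fragment_length:
                raise InconsistentInputError(
                    f"fragment {rec.fragment_id!r} is {len(seq)} bp but the "
                    f"map records {rec.fragment_length} bp"
                )
            if rec.orientation == REVERSE:
                seq = str(Seq(seq).reverse_complement())
            parts.append(seq)
        cursor[rec.chrom_id] = rec.chrom_end
    chromosomes = GenomeSequences()
    for chrom_id, parts in pieces.items():
        chromosomes[chrom_id] = "".join(parts)
    return chromosomes


def compute_stats(
    classifications: Mapping[str, FragmentClassification],
    map_records: Sequence[FragmentMapRecord],
    fragments: GenomeSequences,
) -> AssemblyStats:
    """Summarize an assembly run.

    Counts and total bp of anchored / unlocalized / unplaced fragments,
    per-chromosome fragment counts, assembled lengths and gap bp, and the
    overall fraction of 'N' positions contributed by gap records.
    """
    counts = {ANCHORED: 0, UNLOCALIZED: 0, UNPLACED: 0}
    bps = {ANCHORED: 0, UNLOCALIZED: 0, UNPLACED: 0}
    for fragment_id, classification in classifications.items():
        counts[classification.status] += 1
        bps[classification.status] += len(fragments.get(fragment_id, ""))

    per_chrom_frag: dict[str, int] = {}
    per_chrom_len: dict[str, int] = {}
    per_chrom_gap: dict[str, int] = {}
    for rec in map_records:
        per_chrom_len[rec.chrom_id] = max(
            per_chrom_len.get(rec.chrom_id, 0), rec.chrom_end
        )
        if rec.is_gap:
            per_chrom_gap[rec.chrom_id] = per_chrom_gap.get(rec.chrom_id, 0) + (
                rec.chrom_end - rec.chrom_start
            )
        else:
            per_chrom_frag[rec.chrom_id] = per_chrom_frag.get(rec.chrom_id, 0) + 1

    per_chromosome = {
        chrom_id: ChromosomeStats(
            fragment_count=per_chrom_frag.get(chrom_id, 0),
            assembled_length=per_chrom_len[chrom_id],
            gap_bp=per_chrom_gap.get(chrom_id, 0),
        )
        for chrom_id in sorted(per_chrom_len)
    }
    total_length = sum(s.assembled_length for s in per_chromosome.values())
    total_gap = sum(s.gap_bp for s in per_chromosome.values())
    return AssemblyStats(
        anchored_count=counts[ANCHORED],
        unlocalized_count=counts[UNLOCALIZED],
        unplaced_count=counts[UNPLACED],
        anchored_bp=bps[ANCHORED],
        unlocalized_bp=bps[UNLOCALIZED],
        unplaced_bp=bps[UNPLACED],
        per_chromosome=per_chromosome,
        total_length=total_length,
        total_gap_bp=total_gap,
        n_fraction=(total_gap / total_length) if total_length else 0.0,
    )


def transfer_annotations(
    features: Sequence[Feature], map_records: Sequence[FragmentMapRecord]
) -> tuple[list[Feature], list[tuple[Feature, str]]]:
    """Lift features from fragment coordinates onto assembled chromosomes.

    Features on fragments absent from the map (unplaced, unlocalized, or
    simply unknown) are returned in ``skipped`` with a reason.  Input order
    is preserved within each output list.
    """
    validate_fragment_map(map_records)
    placements = {rec.fragment_id: rec for rec in map_records if not rec.is_gap}
    transferred: list[Feature] = []
    skipped: list[tuple[Feature, str]] = []
    for feat in features:
        placement = placements.get(feat.seq_id)
        if placement is None:
            skipped.append((feat, f"fragment {feat.seq_id!r} is not in the map"))
            continue
        transferred.append(transfer_region(feat, placement))
    return transferred, skipped
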