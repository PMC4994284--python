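"""Coordinate algebra for anchoring fragments and transferring annotations.

All coordinates are zero-based half-open: the first base of a sequence is
position 0 and an interval [start, end) excludes its end position.  A
fragment of length ``L`` aligned to a reference chromosome over the region
``[fragment_start, fragment_end)`` of the fragment and
``[ref_start, ref_end)`` of the reference is *placed* by extrapolating the
alignment to the fragment's full extent:

direct orientation::

    placed_start = ref_start - fragment_start
    placed_end   = placed_start + L

reverse orientation (the fragment's reverse complement lies on the
reference forward strand)::

    placed_end   = ref_end + fragment_start
    placed_start = placed_end - L

Annotation transfer is the same algebra applied to a sub-interval of the
fragment: a region ``[s, e)`` of a fragment placed at
``[placed_start, placed_end)`` lands at ``[placed_start + s,
placed_start + e)`` in direct orientation and at ``[placed_end - e,
placed_end - s)`` in reverse orientation, with the feature strand flipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

#: Orientation / strand symbols used throughout the package.
DIRECT = "+"
REVERSE = "-"

#: Classification statuses for fragments.
ANCHORED = "anchored"
UNLOCALIZED = "unlocalized"
UNPLACED = "unplaced"


class ChromodraftError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(ChromodraftError):
    """An invalid parameter value (e.g. a ratio threshold not > 1)."""


class InconsistentInputError(ChromodraftError):
    """Inputs that contradict each other (e.g. alignment longer than fragment)."""


class OutOfBoundsError(ChromodraftError):
    """A region that does not fit inside its fragment or placement."""


def _check_orientation(orientation: str) -> None:
    if orientation not in (DIRECT, REVERSE):
        raise ParameterError(
            f"orientation must be '{DIRECT}' or '{REVERSE}', got {orientation!r}"
        )


@dataclass(frozen=True)
class AlignmentRecord:
    """One pairwise local alignment between a fragment and a reference chromosome.

    Coordinates are zero-based half-open and ascending on both sequences;
    reverse-strand hits are encoded by ``orientation`` rather than by
    descending coordinates.
    """

    fragment_id: str
    fragment_start: int
    fragment_end: int
    ref_id: str
    ref_start: int
    ref_end: int
    orientation: str
    score: float

    def __post_init__(self) -> None:
        if not 0 <= self.fragment_start < self.fragment_end:
            raise InconsistentInputError(
                f"alignment of {self.fragment_id!r}: fragment interval "
                f"[{self.fragment_start}, {self.fragment_end}) is not a valid "
                "zero-based half-open interval"
            )
        if not 0 <= self.ref_start < self.ref_end:
            raise InconsistentInputError(
                f"alignment of {self.fragment_id!r}: reference interval "
                f"[{self.ref_start}, {self.ref_end}) is not a valid "
                "zero-based half-open interval"
            )
        _check_orientation(self.orientation)
        if self.score < 0:
            raise InconsistentInputError(
                f"alignment of {self.fragment_id!r}: score {self.score} < 0"
            )


@dataclass(frozen=True)
class FragmentAnchor:
    """The winning alignment of an anchored fragment and its placement interval.

    ``placed_start`` may be negative when the fragment overhangs the start of
    the reference chromosome; layout clamps this downstream.
    """

    fragment_id: str
    fragment_length: int
    ref_id: str
    placed_start: int
    placed_end: int
    orientation: str
    best_score: float
    second_score: Optional[float] = None

    def __post_init__(self) -> None:
        _check_orientation(self.orientation)
        if self.placed_end - self.placed_start != self.fragment_length:
            raise InconsistentInputError(
                f"anchor of {self.fragment_id!r}: placement "
                f"[{self.placed_start}, {self.placed_end}) does not span "
                f"fragment length {self.fragment_length}"
            )


@dataclass(frozen=True)
class FragmentClassification:
    """Outcome of anchoring one fragment: anchored, unlocalized or unplaced."""

    fragment_id: str
    status: str
    anchor: Optional[FragmentAnchor] = None

    def __post_init__(self) -> None:
        if self.status not in (ANCHORED, UNLOCALIZED, UNPLACED):
            raise ParameterError(f"unknown status {self.status!r}")
        if (self.status == ANCHORED) != (self.anchor is not None):
            raise InconsistentInputError(
                f"fragment {self.fragment_id!r}: status {self.status!r} "
                "inconsistent with anchor presence"
            )


@dataclass(frozen=True)
class Feature:
    """An annotated interval on a fragment or chromosome, with strand.

    ``payload`` preserves all non-coordinate columns of the source record
    verbatim so that read -> transfer -> write keeps names, scores and
    attributes intact.  Strand is '+', '-' or '.' (unstranded).
    """

    seq_id: str
    start: int
    end: int
    strand: str = "."
    payload: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise InconsistentInputError(
                f"feature on {self.seq_id!r}: [{self.start}, {self.end}) is "
                "not a valid zero-based half-open interval"
            )
        if self.strand not in (DIRECT, REVERSE, "."):
            raise ParameterError(
                f"feature on {self.seq_id!r}: strand must be '+', '-' or '.', "
                f"got {self.strand!r}"
            )


def alignment_sort_key(aln: AlignmentRecord) -> tuple:
    """Deterministic ordering: score descending, then ref_id, ref_start,
    fragment_start ascending.  Used wherever the 'two greatest scores' are
    selected so that exact ties break reproducibly."""
    return (-aln.score, aln.ref_id, aln.ref_start, aln.fragment_start)


def fragment_interval(
    anchor_alignment: AlignmentRecord, fragment_length: int
) -> tuple[int, int]:
    """Extrapolate an alignment to the full-fragment placement interval.

    Returns ``(placed_start, placed_end)`` on the reference chromosome with
    ``placed_end - placed_start == fragment_length``.  ``placed_start`` may
    be negative when the fragment overhangs the reference start.
    """
    if fragment_length < anchor_alignment.fragment_end:
        raise InconsistentInputError(
            f"fragment {anchor_alignment.fragment_id!r}: length "
            f"{fragment_length} is shorter than the alignment end "
            f"{anchor_alignment.fragment_end}"
        )
    if anchor_alignment.orientation == DIRECT:
        placed_start = anchor_alignment.ref_start - anchor_alignment.fragment_start
        placed_end = placed_start + fragment_length
    else:
        placed_end = anchor_alignment.ref_end + anchor_alignment.fragment_start
        placed_start = placed_end - fragment_length
    return placed_start, placed_end


def classify_fragment(
    fragment_id: str,
    fragment_length: int,
    alignments: Sequence[AlignmentRecord],
    ratio_threshold: float,
) -> FragmentClassification:
    """Classify a fragment as anchored, unlocalized or unplaced.

    The two greatest alignment scores are compared: if their ratio strictly
    exceeds ``ratio_threshold`` the fragment is anchored at the best-scoring
    alignment.  Otherwise the fragment is *unplaced* if the two alignments
    lie on different reference chromosomes and *unlocalized* if they lie on
    the same chromosome.  A fragment with a single alignment is anchored
    (the ratio is treated as infinite: there is no competing evidence).

    Parameters
    ----------
    fragment_id : str
        Fragment the alignments belong to.
    fragment_length : int
        Full fragment length in bp; must cover every alignment.
    alignments : sequence of AlignmentRecord
        Non-empty; all records must carry ``fragment_id``.
    ratio_threshold : float
        Must be strictly greater than one.
    """
    if ratio_threshold <= 1:
        raise ParameterError(
            f"ratio_threshold must be greater than one, got {ratio_threshold}"
        )
    if not alignments:
        raise InconsistentInputError(
            f"fragment {fragment_id!r} has no alignments"
        )
    for aln in alignments:
        if aln.fragment_id != fragment_id:
            raise InconsistentInputError(
                f"alignment of {aln.fragment_id!r} passed for fragment "
                f"{fragment_id!r}"
            )

    ordered = sorted(alignments, key=alignment_sort_key)
    best = ordered[0]

    if len(ordered) == 1:
        anchored = True
        second = None
    else:
        second = ordered[1]
        # strict '>' : a ratio exactly at the threshold does not anchor
        anchored = second.score > 0 and best.score / second.score > ratio_threshold
        if second.score == 0:
            # a zero runner-up cannot contest a positive best score
            anchored = best.score > 0

    if anchored:
        placed_start, placed_end = fragment_interval(best, fragment_length)
        anchor = FragmentAnchor(
            fragment_id=fragment_id,
            fragment_length=fragment_length,
            ref_id=best.ref_id,
            placed_start=placed_start,
            placed_end=placed_end,
            orientation=best.orientation,
            best_score=best.score,
            second_score=None if second is None else second.score,
        )
        return FragmentClassification(fragment_id, ANCHORED, anchor)

    status = UNLOCALIZED if best.ref_id == second.ref_id else UNPLACED
    return FragmentClassification(fragment_id, status, None)


def transfer_region(region: Feature, placement) -> Feature:
    """Lift a feature from fragment coordinates onto the assembled chromosome.

    ``placement`` is the fragment's map record (``fragment_id``,
    ``fragment_length``, ``chrom_id``, ``chrom_start``, ``chrom_end``,
    ``orientation``).  Length is conserved; strand is flipped when the
    fragment is placed in reverse orientation ('.' stays '.').
    """
    if region.seq_id != placement.fragment_id:
        raise InconsistentInputError(
            f"feature on {region.seq_id!r} transferred with the placement of "
            f"{placement.fragment_id!r}"
        )
    if region.end > placement.fragment_length:
        raise OutOfBoundsError(
            f"feature [{region.start}, {region.end}) exceeds fragment "
            f"{placement.fragment_id!r} of length {placement.fragment_length}"
        )
    if placement.orientation == DIRECT:
        start = placement.chrom_start + region.start
        end = placement.chrom_start + region.end
        strand = region.strand
    else:
        start = placement.chrom_end - region.end
        end = placement.chrom_end - region.start
        strand = _flip_strand(region.strand)
    return replace(region, seq_id=placement.chrom_id, start=start, end=end, strand=strand)


def invert_transfer(chrom_region: Feature, placement) -> Feature:
    """Inverse of :func:`transfer_region`: chromosome coordinates back to the
    fragment.  ``transfer_region(invert_transfer(x)) == x`` for every region
    inside the placement interval."""
    if chrom_region.seq_id != placement.chrom_id:
        raise InconsistentInputError(
            f"feature on {chrom_region.seq_id!r} inverted with a placement on "
            f"{placement.chrom_id!r}"
        )
    if chrom_region.start < placement.chrom_start or chrom_region.end > placement.chrom_end:
        raise OutOfBoundsError(
            f"feature [{chrom_region.start}, {chrom_region.end}) lies outside "
            f"the placement [{placement.chrom_start}, {placement.chrom_end}) "
            f"of fragment {placement.fragment_id!r}"
        )
    if placement.orientation == DIRECT:
        start = chrom_region.start - placement.chrom_start
        end = chrom_region.end - placement.chrom_start
        strand = chrom_region.strand
    else:
        start = placement.chrom_end - chrom_region.end
        end = placement.chrom_end - chrom_region.start
        strand = _flip_strand(chrom_region.strand)
    return replace(
        chrom_region,
        seq_id=placement.fragment_id,
        start=start,
        end=end,
        strand=strand,
    )


def _flip_strand(strand: str) -> str:
    if strand == DIRECT:
        return REVERSE
    if strand == REVERSE:
        return DIRECT
    return strand
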