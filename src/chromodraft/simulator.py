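"""Synthetic genomes for end-to-end testing without an external aligner.

The simulator builds a random reference genome, shreds it into fragments
that tile each chromosome (optionally reverse-complemented and/or
overlapping), and emits the exact full-length alignments a perfect aligner
would report, plus the ground-truth placement of every fragment.  Two
kinds of confounders can be mixed in:

* *ambiguous* fragments carry two equal-score alignments on different
  chromosomes, which forces a score ratio of one and therefore an
  unplaced call at any threshold;
* *junk* fragments are random sequence with no alignments at all.

Simulated alignment scores are ``2 x alignment length`` — bit-score-like
in scale, and any positive monotone score gives the same classifications
because the ratio test is scale-invariant.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Seq import Seq

from chromodraft.core import (
    DIRECT,
    REVERSE,
    AlignmentRecord,
    ChromodraftError,
)
from chromodraft.io import FragmentMapRecord, GenomeSequences
from chromodraft.assembler import AssemblyResult

_BASES = "ACGT"


class ConfigError(ChromodraftError):
    """An infeasible simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated genome.

    ``overlap_bp`` makes each fragment overlap its predecessor on the
    reference by that many bases (it must stay below the minimum fragment
    length so shredding always advances).  ``n_ambiguous`` and
    ``n_unaligned`` add confounder fragments on top of the tiling.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 100_000
    fragment_length_range: tuple[int, int] = (1_000, 5_000)
    reverse_fraction: float = 0.5
    overlap_bp: int = 0
    n_ambiguous: int = 0
    n_unaligned: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.fragment_length_range
        if not 0 < lo <= hi <= self.chromosome_length:
            raise ConfigError(
                f"fragment_length_range {self.fragment_length_range} must "
                f"satisfy 0 < min <= max <= chromosome_length "
                f"({self.chromosome_length})"
            )
        if not 0.0 <= self.reverse_fraction <= 1.0:
            raise ConfigError(
                f"reverse_fraction must be in [0, 1], got {self.reverse_fraction}"
            )
        if self.overlap_bp < 0 or self.overlap_bp >= lo:
            raise ConfigError(
                f"overlap_bp must satisfy 0 <= overlap_bp < min fragment "
                f"length ({lo}), got {self.overlap_bp}"
            )
        if self.n_ambiguous > 0 and self.n_chromosomes < 2:
            raise ConfigError(
                "ambiguous fragments need at least two chromosomes"
            )
        if self.n_chromosomes < 1:
            raise ConfigError("need at least one chromosome")


def simulate(
    config: SimulationConfig,
) -> tuple[GenomeSequences, GenomeSequences, list[AlignmentRecord], list[FragmentMapRecord]]:
    """Generate (reference, fragments, alignments, truth map).

    Deterministic for a given ``config.seed``.  Every tiling fragment is an
    exact substring (or reverse complement of a substring) of the reference
    with one full-length alignment consistent with its truth record; with
    ``overlap_bp > 0`` the truth intervals of consecutive fragments overlap
    by that amount.
    """
    rng = random.Random(config.seed)

    reference = GenomeSequences()
    chrom_ids = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    for chrom_id in chrom_ids:
        reference[chrom_id] = "".join(
            rng.choice(_BASES) for _ in range(config.chromosome_length)
        )

    fragments = GenomeSequences()
    alignments: list[AlignmentRecord] = []
    truth: list[FragmentMapRecord] = []
    lo, hi = config.fragment_length_range

    for chrom_id in chrom_ids:
        chrom_seq = reference[chrom_id]
        pos = 0
        index = 0
        while pos < len(chrom_seq):
            length = rng.randint(lo, hi)
            end = min(pos + length, len(chrom_seq))
            index += 1
            fragment_id = f"{chrom_id}_frag{index:04d}"
            segment = chrom_seq[pos:end]
            reverse = rng.random() < config.reverse_fraction
            orientation = REVERSE if reverse else DIRECT
            fragments[fragment_id] = (
                str(Seq(segment).reverse_complement()) if reverse else segment
            )
            frag_len = end - pos
            alignments.append(
                AlignmentRecord(
                    fragment_id=fragment_id,
                    fragment_start=0,
                    fragment_end=frag_len,
                    ref_id=chrom_id,
                    ref_start=pos,
                    ref_end=end,
                    orientation=orientation,
                    score=2.0 * frag_len,
                )
            )
            truth.append(
                FragmentMapRecord(
                    fragment_id=fragment_id,
                    fragment_length=frag_len,
                    fragment_start=0,
                    fragment_end=frag_len,
                    orientation=orientation,
                    chrom_id=chrom_id,
                    chrom_start=pos,
                    chrom_end=end,
                )
            )
            if end == len(chrom_seq):
                break
            pos = end - config.overlap_bp

    for i in range(config.n_ambiguous):
        fragment_id = f"ambig{i + 1:04d}"
        length = rng.randint(lo, hi)
        home = chrom_ids[i % config.n_chromosomes]
        other = chrom_ids[(i + 1) % config.n_chromosomes]
        start = rng.randint(0, config.chromosome_length - length)
        fragments[fragment_id] = reference[home][start : start + length]
        for ref_id in (home, other):
            alignments.append(
                AlignmentRecord(
                    fragment_id=fragment_id,
                    fragment_start=0,
                    fragment_end=length,
                    ref_id=ref_id,
                    ref_start=start,
                    ref_end=start + length,
                    orientation=DIRECT,
                    score=2.0 * length,
                )
            )

    for i in range(config.n_unaligned):
        length = rng.randint(lo, hi)
        fragments[f"junk{i + 1:04d}"] = "".join(
            rng.choice(_BASES) for _ in range(length)
        )

    return reference, fragments, alignments, truth


@dataclass
class TruthReport:
    """Differences between an assembly result and the simulated truth.

    ``misplaced`` lists fragments whose chromosome or interval differs from
    truth; ``mis_oriented`` those with a flipped orientation; ``missing``
    truth fragments absent from the result map; ``neighbor_misplaced``
    fragments whose (previous, next) fragment neighbours differ from the
    truth neighbours — the order-level notion of misplacement, insensitive
    to coordinate shifts from gap insertion.
    """

    misplaced: list[str] = field(default_factory=list)
    mis_oriented: list[str] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)
    neighbor_misplaced: list[str] = field(default_factory=list)

    @property
    def total_errors(self) -> int:
        return (
            len(self.misplaced)
            + len(self.mis_oriented)
            + len(self.missing)
            + len(self.neighbor_misplaced)
        )


def _neighbors(records: Sequence[FragmentMapRecord]) -> dict[str, tuple[Optional[str], Optional[str]]]:
    by_chrom: dict[str, list[FragmentMapRecord]] = {}
    for rec in records:
        if not rec.is_gap:
            by_chrom.setdefault(rec.chrom_id, []).append(rec)
    result: dict[str, tuple[Optional[str], Optional[str]]] = {}
    for recs in by_chrom.values():
        recs = sorted(recs, key=lambda r: r.chrom_start)
        for i, rec in enumerate(recs):
            prev_id = recs[i - 1].fragment_id if i > 0 else None
            next_id = recs[i + 1].fragment_id if i < len(recs) - 1 else None
            result[rec.fragment_id] = (prev_id, next_id)
    return result


def truth_compare(
    result: AssemblyResult, truth: Sequence[FragmentMapRecord]
) -> TruthReport:
    """Compare an assembly's fragment map with the simulated truth map."""
    report = TruthReport()
    placed = {rec.fragment_id: rec for rec in result.map if not rec.is_gap}
    truth_by_id = {rec.fragment_id: rec for rec in truth if not rec.is_gap}

    for fragment_id, truth_rec in truth_by_id.items():
        got = placed.get(fragment_id)
        if got is None:
            report.missing.append(fragment_id)
            continue
        if (
            got.chrom_id != truth_rec.chrom_id
            or got.chrom_start != truth_rec.chrom_start
            or got.chrom_end != truth_rec.chrom_end
        ):
            report.misplaced.append(fragment_id)
        if got.orientation != truth_rec.orientation:
            report.mis_oriented.append(fragment_id)

    result_neighbors = _neighbors(result.map)
    truth_neighbors = _neighbors(truth)
    for fragment_id, truth_nbrs in truth_neighbors.items():
        got_nbrs = result_neighbors.get(fragment_id)
        if got_nbrs is not None and got_nbrs != truth_nbrs:
            report.neighbor_misplaced.append(fragment_id)
    return report
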