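"""Layout, sequence emission, statistics and annotation transfer."""

import random

import pytest

from chromodraft.assembler import (
    build_fragment_map,
    compute_stats,
    emit_sequences,
    layout_chromosome,
    transfer_annotations,
)
from chromodraft.core import (
    ANCHORED,
    DIRECT,
    REVERSE,
    AlignmentRecord,
    Feature,
    FragmentAnchor,
    InconsistentInputError,
)
from chromodraft.io import GAP_ID, FragmentMapRecord, GenomeSequences


def anchor(fragment_id, placed_start, placed_end, orientation=DIRECT,
           ref_id="chr1"):
    return FragmentAnchor(
        fragment_id=fragment_id,
        fragment_length=placed_end - placed_start,
        ref_id=ref_id,
        placed_start=placed_start,
        placed_end=placed_end,
        orientation=orientation,
        best_score=100.0,
    )


def intervals(records):
    return [(r.fragment_id, r.chrom_start, r.chrom_end) for r in records]


class TestLayoutChromosome:
    def test_overlap_resolved_by_overlap_plus_gap_shift(self):
        records = layout_chromosome(
            [anchor("A", 0, 100), anchor("B", 90, 190)], gap_size=20
        )
        assert intervals(records) == [
            ("A", 0, 100), (GAP_ID, 100, 120), ("B", 120, 220)
        ]

    def test_shift_is_cumulative_downstream(self):
        """Resolving the A/B overlap moves C by the same amount, preserving
        the B-C spacing in the reference frame."""
        records = layout_chromosome(
            [anchor("A", 0, 100), anchor("B", 90, 190), anchor("C", 300, 400)],
            gap_size=20,
        )
        non_gap = [r for r in records if not r.is_gap]
        assert intervals(non_gap) == [
            ("A", 0, 100), ("B", 120, 220), ("C", 330, 430)
        ]

    def test_disjoint_anchors_unchanged_with_materialized_gap(self):
        records = layout_chromosome(
            [anchor("A", 0, 100), anchor("B", 150, 250)], gap_size=37
        )
        assert intervals(records) == [
            ("A", 0, 100), (GAP_ID, 100, 150), ("B", 150, 250)
        ]

    def test_negative_start_clamped_to_zero(self):
        records = layout_chromosome([anchor("A", -10, 90)], gap_size=0)
        assert intervals(records) == [("A", 0, 100)]

    def test_clamp_shift_applies_downstream_too(self):
        records = layout_chromosome(
            [anchor("A", -10, 90), anchor("B", 200, 260)], gap_size=0
        )
        non_gap = [r for r in records if not r.is_gap]
        assert intervals(non_gap) == [("A", 0, 100), ("B", 210, 270)]

    def test_duplicate_fragment_id_rejected(self):
        with pytest.raises(InconsistentInputError, match="duplicate"):
            layout_chromosome([anchor("A", 0, 100), anchor("A", 200, 300)], 0)

    def test_mixed_chromosomes_rejected(self):
        with pytest.raises(InconsistentInputError):
            layout_chromosome(
                [anchor("A", 0, 100), anchor("B", 0, 100, ref_id="chr2")], 0
            )

    def test_empty_input_gives_empty_layout(self):
        assert layout_chromosome([], 10) == []

    @pytest.mark.parametrize("gap_size", [0, 1, 50])
    def test_randomized_overlaps_end_up_disjoint_and_ordered(self, gap_size, rng):
        """However the anchors overlap, the layout is disjoint, order-
        preserving, and formerly overlapping neighbours sit exactly
        gap_size apart."""
        for _ in range(50):
            anchors = []
            pos = rng.randint(-50, 50)
            for i in range(rng.randint(2, 12)):
                length = rng.randint(10, 200)
                anchors.append(anchor(f"f{i:02d}", pos, pos + length))
                pos += rng.randint(-length + 1, 300)
            ordered = sorted(
                anchors,
                key=lambda a: (a.placed_start, a.placed_end, a.fragment_id),
            )
            records = [r for r in layout_chromosome(anchors, gap_size)
                       if not r.is_gap]
            assert [r.fragment_id for r in records] == [a.fragment_id for a in ordered]
            for prev, cur, prev_a, cur_a in zip(
                records, records[1:], ordered, ordered[1:]
            ):
                assert cur.chrom_start >= prev.chrom_end
                ref_spacing = cur_a.placed_start - prev_a.placed_end
                if ref_spacing < 0:
                    assert cur.chrom_start - prev.chrom_end == gap_size
                else:
                    assert cur.chrom_start - prev.chrom_end == ref_spacing


class TestBuildFragmentMap:
    @staticmethod
    def tiling_fixture():
        fragments = GenomeSequences()
        alignments = []
        chrom = "".join(random.Random(3).choice("ACGT") for _ in range(300))
        for i, start in enumerate(range(0, 300, 100)):
            fid = f"f{i}"
            fragments[fid] = chrom[start:start + 100]
            alignments.append(AlignmentRecord(fid, 0, 100, "chr1", start,
                                              start + 100, DIRECT, 200.0))
        return fragments, alignments

    def test_unique_tiling_is_fully_anchored_without_gaps(self):
        fragments, alignments = self.tiling_fixture()
        result = build_fragment_map(fragments, alignments, 1.2, 10)
        assert not result.unplaced_ids and not result.unlocalized_ids
        assert [r.fragment_id for r in result.map] == ["f0", "f1", "f2"]
        assert not any(r.is_gap for r in result.map)

    def test_cross_chromosome_tie_is_unplaced(self):
        fragments = GenomeSequences()
        fragments["f1"] = "A" * 50
        alignments = [
            AlignmentRecord("f1", 0, 50, "chr1", 0, 50, DIRECT, 100.0),
            AlignmentRecord("f1", 0, 50, "chr2", 0, 50, DIRECT, 100.0),
        ]
        result = build_fragment_map(fragments, alignments, 1.5, 0)
        assert result.unplaced_ids == ["f1"]
        assert result.map == []

    def test_same_chromosome_weak_ratio_is_unlocalized(self):
        fragments = GenomeSequences()
        fragments["f1"] = "A" * 50
        alignments = [
            AlignmentRecord("f1", 0, 50, "chr1", 0, 50, DIRECT, 100.0),
            AlignmentRecord("f1", 0, 50, "chr1", 500, 550, DIRECT, 90.0),
        ]
        result = build_fragment_map(fragments, alignments, 1.5, 0)
        assert result.unlocalized_ids == ["f1"]

    def test_alignment_free_fragment_is_unplaced(self):
        fragments, alignments = self.tiling_fixture()
        fragments["orphan"] = "ACGT"
        result = build_fragment_map(fragments, alignments, 1.2, 0)
        assert "orphan" in result.unplaced_ids

    def test_partition_covers_every_fragment(self):
        fragments, alignments = self.tiling_fixture()
        fragments["orphan"] = "ACGT"
        result = build_fragment_map(fragments, alignments, 1.2, 0)
        placed = {r.fragment_id for r in result.map if not r.is_gap}
        assert (
            placed
            | set(result.unlocalized_ids)
            | set(result.unplaced_ids)
        ) == set(fragments)
        assert len(placed) + len(result.unlocalized_ids) + len(result.unplaced_ids) == len(fragments)

    def test_unknown_fragment_in_alignments_rejected(self):
        fragments, alignments = self.tiling_fixture()
        alignments.append(AlignmentRecord("ghost", 0, 10, "chr1", 0, 10,
                                          DIRECT, 10.0))
        with pytest.raises(InconsistentInputError, match="ghost"):
            build_fragment_map(fragments, alignments, 1.2, 0)

    def test_raising_threshold_never_anchors_more(self):
        fragments = GenomeSequences()
        alignments = []
        rng = random.Random(11)
        for i in range(30):
            fid = f"f{i}"
            fragments[fid] = "A" * 60
            s1 = rng.uniform(50, 200)
            s2 = rng.uniform(10, s1)
            alignments.append(AlignmentRecord(fid, 0, 60, "chr1", i * 100,
                                              i * 100 + 60, DIRECT, s1))
            alignments.append(AlignmentRecord(
                fid, 0, 60, rng.choice(["chr1", "chr2"]), 5000 + i * 100,
                5060 + i * 100, DIRECT, s2))
        anchored_sets = []
        for threshold in (1.1, 1.5, 2.0, 3.0, 5.0):
            result = build_fragment_map(fragments, alignments, threshold, 0)
            anchored_sets.append(
                {f for f, c in result.classifications.items()
                 if c.status == ANCHORED}
            )
        for bigger, smaller in zip(anchored_sets, anchored_sets[1:]):
            assert smaller <= bigger


class TestEmitSequences:
    def test_identity_placement(self):
        fragments = GenomeSequences()
        fragments["f1"] = "ACGTACGTAC"
        records = [FragmentMapRecord("f1", 10, 0, 10, "+", "chr1", 0, 10)]
        assert emit_sequences(records, fragments)["chr1"] == "ACGTACGTAC"

    def test_reverse_placement_with_leading_gap(self):
        fragments = GenomeSequences()
        fragments["f1"] = "ACGTACGTAC"
        records = [
            FragmentMapRecord("GAP", 5, 0, 5, "+", "chr1", 0, 5),
            FragmentMapRecord("f1", 10, 0, 10, "-", "chr1", 5, 15),
        ]
        assert emit_sequences(records, fragments)["chr1"] == "NNNNN" + "GTACGTACGT"

    def test_gap_between_fragments_is_exactly_n_run(self):
        fragments = GenomeSequences()
        fragments["f1"] = "AAAA"
        fragments["f2"] = "TTTT"
        records = [
            FragmentMapRecord("f1", 4, 0, 4, "+", "chr1", 0, 4),
            FragmentMapRecord("GAP", 20, 0, 20, "+", "chr1", 4, 24),
            FragmentMapRecord("f2", 4, 0, 4, "+", "chr1", 24, 28),
        ]
        assert emit_sequences(records, fragments)["chr1"] == "AAAA" + "N" * 20 + "TTTT"

    def test_chromosome_length_equals_last_record_end(self):
        fragments = GenomeSequences()
        fragments["f1"] = "ACGT"
        records = [FragmentMapRecord("f1", 4, 0, 4, "+", "chr1", 96, 100)]
        assert len(emit_sequences(records, fragments)["chr1"]) == 100

    def test_length_mismatch_names_fragment(self):
        fragments = GenomeSequences()
        fragments["f1"] = "ACG"
        records = [FragmentMapRecord("f1", 10, 0, 10, "+", "chr1", 0, 10)]
        with pytest.raises(InconsistentInputError, match="f1"):
            emit_sequences(records, fragments)

    def test_sequence_conservation_on_simulated_genome(self):
        """Every anchored fragment (or its reverse complement) occurs verbatim
        at its map interval in the assembled chromosome."""
        from Bio.Seq import Seq
        from chromodraft.simulator import SimulationConfig, simulate
        config = SimulationConfig(seed=5, n_chromosomes=2,
                                  chromosome_length=5_000,
                                  fragment_length_range=(200, 700))
        _, fragments, alignments, _ = simulate(config)
        result = build_fragment_map(fragments, alignments, 1.2, 10)
        chromosomes = emit_sequences(result.map, fragments)
        for rec in result.map:
            if rec.is_gap:
                continue
            got = chromosomes[rec.chrom_id][rec.chrom_start:rec.chrom_end]
            want = fragments[rec.fragment_id]
            if rec.orientation == REVERSE:
                want = str(Seq(want).reverse_complement())
            assert got == want


class TestComputeStats:
    def test_counts_and_gap_fraction(self):
        fragments = GenomeSequences()
        for fid, seq in (("f1", "A" * 40), ("f2", "C" * 60), ("f3", "G" * 30)):
            fragments[fid] = seq
        alignments = [
            AlignmentRecord("f1", 0, 40, "chr1", 0, 40, DIRECT, 80.0),
            AlignmentRecord("f2", 0, 60, "chr1", 60, 120, DIRECT, 120.0),
        ]
        result = build_fragment_map(fragments, alignments, 1.2, 0)
        stats = compute_stats(result.classifications, result.map, fragments)
        assert (stats.anchored_count, stats.unlocalized_count,
                stats.unplaced_count) == (2, 0, 1)
        assert stats.anchored_bp == 100
        assert stats.unplaced_bp == 30
        assert stats.total_length == 120
        assert stats.total_gap_bp == 20
        assert stats.n_fraction == pytest.approx(1 / 6)

    def test_empty_inputs_give_zero_stats(self):
        stats = compute_stats({}, [], GenomeSequences())
        assert stats.anchored_count == stats.total_length == 0
        assert stats.n_fraction == 0.0


class TestTransferAnnotations:
    @staticmethod
    def one_fragment_map(orientation):
        return [FragmentMapRecord("f1", 100, 0, 100, orientation,
                                  "chr1", 500, 600)]

    def test_direct_and_reverse_transfer(self):
        feat = Feature("f1", 10, 30, "+")
        moved, skipped = transfer_annotations(
            [feat], self.one_fragment_map("+"))
        assert not skipped
        assert (moved[0].start, moved[0].end, moved[0].strand) == (510, 530, "+")
        moved, _ = transfer_annotations([feat], self.one_fragment_map("-"))
        assert (moved[0].start, moved[0].end, moved[0].strand) == (570, 590, "-")

    def test_feature_on_absent_fragment_is_skipped_with_reason(self):
        feat = Feature("unplaced_frag", 0, 5, "+")
        moved, skipped = transfer_annotations([feat], self.one_fragment_map("+"))
        assert moved == []
        assert skipped[0][0] is feat
        assert "unplaced_frag" in skipped[0][1]

    def test_input_order_preserved(self):
        feats = [Feature("f1", i, i + 2, "+") for i in range(0, 20, 2)]
        moved, _ = transfer_annotations(feats, self.one_fragment_map("+"))
        assert [f.start for f in moved] == [500 + i for i in range(0, 20, 2)]
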