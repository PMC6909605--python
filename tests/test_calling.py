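"""Evidence assembly, hard filters, interval merging and coverage metrics."""

import numpy as np
import pysam
import pytest

from ecckit.calling import (
    CallingParams,
    CircleCall,
    DiscordantPair,
    allele_frequency_filter,
    assemble_circles,
    breakpoint_depth,
    call_circles,
    circle_score,
    compute_coverage_metrics,
    junction_from_placement,
    mapq_prefilter,
    merge_reciprocal,
)
from ecckit.extract import CandidateRead
from ecckit.io import GenomicInterval
from ecckit.realign import RealignedPlacement

from conftest import make_record, write_sam


def _placement(start, end, clip_side="right", clip_len=40, prob=1.0, name="s"):
    """Accepted placement implying junction (start, end)."""
    if clip_side == "right":
        placement = GenomicInterval("contig1", start, start + clip_len)
        anchor_start, anchor_end = end - 60, end
    else:
        placement = GenomicInterval("contig1", end - clip_len, end)
        anchor_start, anchor_end = start, start + 60
    return RealignedPlacement(
        read_name=name, contig="contig1", placement=placement, probability=prob,
        edit_distance=0, clip_side=clip_side, clip_length=clip_len,
        anchor_start=anchor_start, anchor_end=anchor_end, mapq=60,
    )


class TestJunctionOrientation:
    def test_right_clip_placed_left_is_circular(self):
        p = _placement(1000, 5000, "right")
        assert junction_from_placement(p) == ("contig1", 1000, 5000)

    def test_left_clip_placed_right_is_circular(self):
        p = _placement(1000, 5000, "left")
        assert junction_from_placement(p) == ("contig1", 1000, 5000)

    def test_outward_placement_is_deletion_type(self):
        p = RealignedPlacement(
            read_name="d", contig="contig1",
            placement=GenomicInterval("contig1", 6000, 6040),
            probability=1.0, edit_distance=0, clip_side="right", clip_length=40,
            anchor_start=4940, anchor_end=5000, mapq=60,
        )
        assert junction_from_placement(p) is None


class TestAssembleCircles:
    def test_three_splits_group_to_one_call(self):
        accepted = [_placement(1000, 5000, name=f"s{i}") for i in range(3)]
        calls = assemble_circles(accepted, [], slack=425)
        assert len(calls) == 1
        assert calls[0].n_split == 3
        assert (calls[0].interval.start, calls[0].interval.end) == (1000, 5000)

    def test_one_split_two_discordant_passes_support(self):
        accepted = [_placement(1000, 5000)]
        pairs = [
            DiscordantPair("contig1", 1100, 4900),
            DiscordantPair("contig1", 1000, 5000),
        ]
        calls = assemble_circles(accepted, pairs, slack=425)
        assert len(calls) == 1
        assert calls[0].n_split == 1
        assert calls[0].n_discordant == 2

    def test_discordant_only_cluster_produces_no_call(self):
        pairs = [DiscordantPair("contig1", 1000, 5000)] * 2
        assert assemble_circles([], pairs, slack=425) == []

    def test_single_split_alone_suppressed(self):
        assert assemble_circles([_placement(1000, 5000)], [], slack=425) == []

    def test_inconsistent_pair_not_attached(self):
        accepted = [_placement(1000, 5000), _placement(1000, 5000, name="s2")]
        pairs = [DiscordantPair("contig1", 8000, 9000)]
        calls = assemble_circles(accepted, pairs, slack=425)
        assert calls[0].n_discordant == 0

    def test_nucleotide_resolution_grouping(self):
        accepted = [_placement(1000, 5000), _placement(1001, 5000, name="s2")]
        calls = assemble_circles(accepted, [], slack=425)
        # junctions differing by 1 nt stay separate and each fails support alone
        assert calls == []


class TestMapqPrefilter:
    def test_high_mapq_kept(self):
        cands = [CandidateRead(make_record("a", mapq=60), "discordant")]
        assert len(list(mapq_prefilter(iter(cands)))) == 1

    def test_boundary_twenty_kept_nineteen_dropped(self):
        kept = CandidateRead(make_record("k", mapq=20), "discordant")
        dropped = CandidateRead(make_record("d", mapq=19), "discordant")
        out = list(mapq_prefilter(iter([kept, dropped])))
        assert [c.record.query_name for c in out] == ["k"]

    def test_low_mapq_secondary_split_rerouted(self):
        rec = make_record("sec", mapq=5, cigar=(("M", 60), ("S", 40)), flag=0x100)
        cand = CandidateRead(rec, "soft_clip", "right", 40)
        out = list(mapq_prefilter(iter([cand])))
        assert len(out) == 1
        assert out[0].realign_only is True

    def test_pair_with_one_low_mapq_mate_dropped(self):
        from ecckit.calling import collect_discordant_pairs

        r1 = make_record("p", pos=1000, mapq=19, flag=0x1 | 0x40)
        r2 = make_record("p", pos=5000, mapq=60, flag=0x1 | 0x80)
        pairs = collect_discordant_pairs(
            [CandidateRead(r1, "discordant"), CandidateRead(r2, "discordant")]
        )
        assert pairs == []


class TestAlleleFrequencyFilter:
    def test_boundary_exactly_point_one_filtered(self):
        call = CircleCall(GenomicInterval("c", 0, 100), n_split=5)
        assert allele_frequency_filter(call, breakpoint_depth=50.0) is False

    def test_above_threshold_kept(self):
        call = CircleCall(GenomicInterval("c", 0, 100), n_split=3)
        assert allele_frequency_filter(call, breakpoint_depth=10.0) is True
        assert call.allele_frequency == pytest.approx(0.3)

    def test_low_frequency_filtered(self):
        call = CircleCall(GenomicInterval("c", 0, 100), n_split=1)
        assert allele_frequency_filter(call, breakpoint_depth=100.0) is False

    def test_zero_depth_with_evidence_kept(self):
        call = CircleCall(GenomicInterval("c", 0, 100), n_split=2)
        assert allele_frequency_filter(call, breakpoint_depth=0.0) is True


class TestMergeReciprocal:
    def _call(self, start, end, n_split=2, n_disc=1, score=10.0):
        return CircleCall(
            GenomicInterval("c", start, end), n_discordant=n_disc, n_split=n_split,
            circle_score=score,
        )

    def test_identical_intervals_merged_support_summed(self):
        merged = merge_reciprocal([self._call(0, 1000), self._call(0, 1000)])
        assert len(merged) == 1
        assert merged[0].n_split == 4
        assert merged[0].circle_score == pytest.approx(20.0)

    def test_boundary_fraction_merged(self):
        merged = merge_reciprocal([self._call(0, 1000), self._call(0, 990)])
        assert len(merged) == 1
        assert (merged[0].interval.start, merged[0].interval.end) == (0, 1000)

    def test_half_overlap_not_merged(self):
        merged = merge_reciprocal([self._call(0, 1000), self._call(500, 1500)])
        assert len(merged) == 2

    def test_transitive_merging(self):
        merged = merge_reciprocal(
            [self._call(0, 1000), self._call(0, 995), self._call(5, 1000)],
            fraction=0.99,
        )
        assert len(merged) == 1

    def test_no_residual_redundancy(self, run_30x):
        calls = run_30x.calls
        for i, a in enumerate(calls):
            for b in calls[i + 1 :]:
                if a.interval.contig != b.interval.contig:
                    continue
                ov = a.interval.overlap(b.interval)
                assert not (
                    ov >= 0.99 * len(a.interval) and ov >= 0.99 * len(b.interval)
                )


class TestCircleScore:
    @pytest.mark.parametrize(
        "supports,expected",
        [([], 0.0), ([(40, 1.0)], 40.0), ([(40, 1.0), (10, 0.995)], 49.95)],
    )
    def test_sum_of_length_probability_products(self, supports, expected):
        assert circle_score(supports) == pytest.approx(expected)


def _uniform_bam(tmp_path, contig_len=4000, read_len=50, span=(0, 3000)):
    """One 50-nt read starting at every position in span: uniform interior depth."""
    recs = [
        make_record(f"u{p}", pos=p, cigar=(("M", read_len),), flag=0x1 | 0x40)
        for p in range(*span)
    ]
    sam = write_sam(tmp_path / "u.sam", recs, contigs=(("contig1", contig_len),),
                    sort_order="coordinate")
    bam = str(tmp_path / "u.bam")
    pysam.sort("-o", bam, sam)
    pysam.index(bam)
    return bam


class TestCoverageMetrics:
    def test_uniform_coverage_interior_circle(self, tmp_path):
        bam_path = _uniform_bam(tmp_path)
        with pysam.AlignmentFile(bam_path) as bam:
            mean, sd, unc, inc_s, inc_e = compute_coverage_metrics(
                GenomicInterval("contig1", 1000, 2000), bam
            )
        assert mean == pytest.approx(50.0)
        assert sd == pytest.approx(0.0)
        assert unc == 0.0
        # uniform read-start density: 100-nt window over 300-nt window
        assert inc_s == pytest.approx(1 / 3)
        assert inc_e == pytest.approx(1 / 3)

    def test_no_reads_in_circle(self, tmp_path):
        bam_path = _uniform_bam(tmp_path, span=(0, 100))
        with pysam.AlignmentFile(bam_path) as bam:
            mean, sd, unc, _, _ = compute_coverage_metrics(
                GenomicInterval("contig1", 2000, 3000), bam
            )
        assert (mean, sd, unc) == (0.0, 0.0, 1.0)

    def test_reads_only_inside_circle_ratio_one(self, tmp_path):
        bam_path = _uniform_bam(tmp_path, span=(1000, 1950))
        with pysam.AlignmentFile(bam_path) as bam:
            _, _, _, inc_s, inc_e = compute_coverage_metrics(
                GenomicInterval("contig1", 1000, 2000), bam
            )
        assert inc_s == pytest.approx(1.0)
        assert inc_e == pytest.approx(1.0)

    def test_breakpoint_depth_mean_of_two_positions(self, tmp_path):
        bam_path = _uniform_bam(tmp_path)
        with pysam.AlignmentFile(bam_path) as bam:
            depth = breakpoint_depth(bam, GenomicInterval("contig1", 1000, 2000))
        assert depth == pytest.approx(50.0)


class TestCallCirclesEndToEnd:
    def test_exact_recovery_on_error_free_simulation(self, run_errorfree):
        truth = {(t.contig, t.start, t.end) for t in run_errorfree.truth}
        called = {
            (c.interval.contig, c.interval.start, c.interval.end)
            for c in run_errorfree.calls
        }
        assert truth == called

    def test_emitted_calls_satisfy_hard_filters(self, run_30x):
        for c in run_30x.calls:
            assert c.n_split >= 1
            assert c.n_split + c.n_discordant >= 2
            assert c.allele_frequency > 0.1 or c.allele_frequency == 0.0

    def test_empty_candidate_set_empty_output(self, run_errorfree, tmp_path):
        empty = write_sam(tmp_path / "none.sam", [], contigs=(("contig1", 1_000_000),))
        calls = call_circles(empty, run_errorfree.coord_bam, run_errorfree.genome)
        assert calls == []
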