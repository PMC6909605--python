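"""Circle calling: evidence combination, hard filters and output metrics.

Accepted clip realignments define junctions at nucleotide resolution; a
junction whose clip was placed back INSIDE the read's anchor span (right
clip placed left of its anchor, left clip placed right) is a circular-DNA
junction, whereas outward placements indicate deletions and are dropped.
Junctions are grouped exactly by (start, end), discordant pairs whose
outer span is consistent with a junction are attached, and calls must then
survive the hard filters: at least two breakpoint reads of which at least
one is a split read; allele frequency (split reads / mean depth at the two
junction nucleotides) above 0.1; and a mapping-quality prefilter at 20.
Redundant intervals overlapping reciprocally by 0.99 are merged, and
coverage summary metrics are computed from the full alignment file.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .extract import CandidateRead, read_candidates
from .graph import GraphParams, build_graph, cluster_candidates, edge_weight, prune_graph
from .io import (
    GenomicInterval,
    InsertSizeModel,
    ReferenceGenome,
    estimate_insert_size_from_file,
    write_circles_bed,
)
from .realign import GraphRealigner, RealignedPlacement, RealignmentParams

MAPQ_MIN = 20


@dataclass
class CallingParams:
    mapq_min: int = MAPQ_MIN
    min_breakpoint_reads: int = 2      # split + discordant
    min_split_reads: int = 1
    allele_frequency_min: float = 0.1  # calls with AF <= this are removed
    merge_fraction: float = 0.99


@dataclass
class CircleCall:
    interval: GenomicInterval
    n_discordant: int = 0
    n_split: int = 0
    circle_score: float = 0.0
    mean_coverage: float = 0.0
    sd_coverage: float = 0.0
    fraction_uncovered: float = 0.0
    coverage_increase_start: float = 1.0
    coverage_increase_end: float = 1.0
    allele_frequency: float = 0.0
    split_supports: list[tuple[int, float]] = field(default_factory=list)


def mapq_prefilter(
    candidates: Iterable[CandidateRead],
    mapq_min: int = MAPQ_MIN,
) -> Iterator[CandidateRead]:
    """Drop discordant reads and split-read primary alignments below the
    mapping-quality threshold. Secondary split alignments below the
    threshold are NOT removed: they are flagged realign-only so they can
    re-enter via the realignment model (but never count as direct split
    support)."""
    for cand in candidates:
        rec = cand.record
        if rec.mapq >= mapq_min:
            yield cand
        elif rec.is_secondary and cand.category in ("soft_clip", "hard_clip"):
            cand.realign_only = True
            yield cand


def circle_score(split_supports: Sequence[tuple[int, float]]) -> float:
    """Sum over split reads of clip length x realignment probability."""
    return float(sum(length * prob for length, prob in split_supports))


def junction_from_placement(p: RealignedPlacement) -> tuple[str, int, int] | None:
    """Circle junction implied by an accepted placement, or None when the
    placement implies a deletion-type (outward) junction."""
    if p.clip_side == "right":
        if p.placement.start < p.anchor_start:
            return (p.contig, p.placement.start, p.anchor_end)
        return None
    if p.clip_side == "left":
        if p.placement.end > p.anchor_end:
            return (p.contig, p.anchor_start, p.placement.end)
        return None
    return None


@dataclass
class DiscordantPair:
    contig: str
    outer_start: int
    outer_end: int


def collect_discordant_pairs(
    candidates: Iterable[CandidateRead],
    mapq_min: int = MAPQ_MIN,
) -> list[DiscordantPair]:
    """Pair up discordant candidate records by query name; a pair is used
    only when both mates are present with MAPQ >= threshold."""
    by_name: dict[str, list] = {}
    for cand in candidates:
        if cand.category != "discordant":
            continue
        by_name.setdefault(cand.record.query_name, []).append(cand.record)
    pairs = []
    for _name, recs in by_name.items():
        if len(recs) < 2:
            continue
        if any(r.mapq < mapq_min for r in recs):
            continue
        if recs[0].contig != recs[1].contig:
            continue
        start = min(r.pos for r in recs)
        end = max(r.reference_end for r in recs)
        pairs.append(DiscordantPair(recs[0].contig, start, end))
    return pairs


def assemble_circles(
    accepted: Sequence[RealignedPlacement],
    discordant_pairs: Sequence[DiscordantPair],
    slack: float,
    params: CallingParams | None = None,
) -> list[CircleCall]:
    """Group split junctions at nucleotide resolution, attach consistent
    discordant pairs, and apply the read-support filter.

    A discordant pair is consistent with a junction when its outer span is
    contained in the junction interval extended by ``slack`` (mu + 5*sigma
    of the insert model) on both sides; each pair is attached to the
    smallest consistent junction. Discordant-only groups never produce a
    call (at least one split read is required).
    """
    params = params or CallingParams()
    groups: dict[tuple[str, int, int], list[RealignedPlacement]] = {}
    for p in accepted:
        junction = junction_from_placement(p)
        if junction is None:
            continue
        groups.setdefault(junction, []).append(p)

    junctions = sorted(groups, key=lambda j: (j[0], j[2] - j[1]))
    attach_counts = {j: 0 for j in junctions}
    for pair in discordant_pairs:
        for j in junctions:  # smallest span first
            contig, s, e = j
            if (
                pair.contig == contig
                and pair.outer_start >= s - slack
                and pair.outer_end <= e + slack
            ):
                attach_counts[j] += 1
                break

    calls = []
    for junction, members in groups.items():
        contig, s, e = junction
        n_split = len(members)
        n_disc = attach_counts[junction]
        if n_split < params.min_split_reads:
            continue
        if n_split + n_disc < params.min_breakpoint_reads:
            continue
        supports = [(m.clip_length, m.probability) for m in members]
        calls.append(
            CircleCall(
                interval=GenomicInterval(contig, s, e),
                n_discordant=n_disc,
                n_split=n_split,
                circle_score=circle_score(supports),
                split_supports=supports,
            )
        )
    calls.sort(key=lambda c: (c.interval.contig, c.interval.start, c.interval.end))
    return calls


def allele_frequency_filter(circle: CircleCall, breakpoint_depth: float,
                            threshold: float = 0.1) -> bool:
    """Keep iff split reads / mean junction depth exceeds the threshold.
    Zero depth with split evidence present keeps the call (degenerate
    denominator, positive evidence)."""
    if breakpoint_depth <= 0:
        return circle.n_split > 0
    circle.allele_frequency = circle.n_split / breakpoint_depth
    return circle.allele_frequency > threshold


def merge_reciprocal(circles: list[CircleCall], fraction: float = 0.99) -> list[CircleCall]:
    """Transitively merge calls overlapping reciprocally by ``fraction`` of
    BOTH intervals; merged calls span the union and sum their support."""
    if not circles:
        return []
    circles = sorted(circles, key=lambda c: (c.interval.contig, c.interval.start, c.interval.end))
    n = len(circles)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        a = circles[i].interval
        for j in range(i + 1, n):
            b = circles[j].interval
            if b.contig != a.contig or b.start >= a.end:
                break
            ov = a.overlap(b)
            if ov >= fraction * len(a) and ov >= fraction * len(b):
                union(i, j)

    merged: dict[int, CircleCall] = {}
    for i, c in enumerate(circles):
        root = find(i)
        if root not in merged:
            merged[root] = CircleCall(
                interval=c.interval,
                n_discordant=c.n_discordant,
                n_split=c.n_split,
                circle_score=c.circle_score,
                allele_frequency=c.allele_frequency,
                split_supports=list(c.split_supports),
            )
        else:
            m = merged[root]
            m.interval = GenomicInterval(
                m.interval.contig,
                min(m.interval.start, c.interval.start),
                max(m.interval.end, c.interval.end),
            )
            m.n_discordant += c.n_discordant
            m.n_split += c.n_split
            m.circle_score += c.circle_score
            m.allele_frequency = max(m.allele_frequency, c.allele_frequency)
            m.split_supports.extend(c.split_supports)
    out = list(merged.values())
    out.sort(key=lambda c: (c.interval.contig, c.interval.start, c.interval.end))
    return out


def _coverage_read_ok(read: pysam.AlignedSegment) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
    )


def breakpoint_depth(bam: pysam.AlignmentFile, interval: GenomicInterval) -> float:
    """Mean depth at the two junction nucleotides (start and end-1)."""
    depths = []
    for pos in (interval.start, interval.end - 1):
        cov = bam.count_coverage(
            interval.contig, pos, pos + 1, quality_threshold=0,
            read_callback=_coverage_read_ok,
        )
        depths.append(sum(c[0] for c in cov))
    return float(np.mean(depths))


def compute_coverage_metrics(
    circle: GenomicInterval,
    bam: pysam.AlignmentFile,
) -> tuple[float, float, float, float, float]:
    """(mean, population sd, fraction uncovered, increase_start,
    increase_end) over the circle interval, counting primary non-duplicate
    alignments.

    The increase ratios compare the number of reads starting (resp. ending)
    in the 100-nt window just inside each boundary with the same window
    extended 200 nt outward; an empty denominator yields 1.0.
    """
    contig_len = bam.get_reference_length(circle.contig)
    start, end = circle.start, min(circle.end, contig_len)
    cov = bam.count_coverage(
        circle.contig, start, end, quality_threshold=0,
        read_callback=_coverage_read_ok,
    )
    depth = np.asarray(cov).sum(axis=0)
    mean = float(depth.mean()) if depth.size else 0.0
    sd = float(depth.std()) if depth.size else 0.0
    uncovered = float((depth == 0).mean()) if depth.size else 1.0

    win_in_s = (start, min(start + 100, contig_len))
    win_out_s = (max(0, start - 200), win_in_s[1])
    n_start_in = n_start_out = 0
    for read in bam.fetch(circle.contig, win_out_s[0], win_out_s[1]):
        if not _coverage_read_ok(read):
            continue
        rs = read.reference_start
        if win_in_s[0] <= rs < win_in_s[1]:
            n_start_in += 1
        if win_out_s[0] <= rs < win_out_s[1]:
            n_start_out += 1
    inc_start = n_start_in / n_start_out if n_start_out else 1.0

    win_in_e = (max(0, end - 100), end)          # reads ending in (end-100, end]
    win_out_e = (win_in_e[0], min(end + 200, contig_len))
    n_end_in = n_end_out = 0
    for read in bam.fetch(circle.contig, win_in_e[0], min(win_out_e[1] + 1, contig_len)):
        if not _coverage_read_ok(read):
            continue
        re_ = read.reference_end
        if re_ is None:
            continue
        if win_in_e[0] < re_ <= win_in_e[1]:
            n_end_in += 1
        if win_out_e[0] < re_ <= win_out_e[1]:
            n_end_out += 1
    inc_end = n_end_in / n_end_out if n_end_out else 1.0
    return mean, sd, uncovered, inc_start, inc_end


def call_circles(
    candidates_path: str | os.PathLike,
    bam_path: str | os.PathLike,
    fasta_path: str | os.PathLike,
    graph_params: GraphParams | None = None,
    realign_params: RealignmentParams | None = None,
    calling_params: CallingParams | None = None,
    insert_model: InsertSizeModel | None = None,
    output_path: str | os.PathLike | None = None,
) -> list[CircleCall]:
    """End-to-end calling from a coordinate-sorted candidate file plus the
    full coordinate-sorted, indexed alignment file and the reference.

    Pipeline: MAPQ prefilter -> cluster -> graph build/weight/prune ->
    guided realignment -> junction assembly + support filter -> allele
    frequency filter -> reciprocal merge -> coverage metrics.
    """
    graph_params = graph_params or GraphParams()
    realign_params = realign_params or RealignmentParams()
    calling_params = calling_params or CallingParams()

    if insert_model is None:
        insert_model = estimate_insert_size_from_file(bam_path)
    slack = insert_model.mu + graph_params.extension_sigmas * insert_model.sigma

    reference = ReferenceGenome(fasta_path)
    accepted: list[RealignedPlacement] = []
    all_discordant: list[CandidateRead] = []

    filtered = mapq_prefilter(read_candidates(candidates_path), calling_params.mapq_min)
    for cluster in cluster_candidates(filtered, graph_params):
        graph = build_graph(cluster)
        edge_weight(graph, graph_params.weight_mode)
        prune_graph(graph, graph_params)
        realigner = None
        for cand in cluster:
            if cand.category == "discordant":
                all_discordant.append(cand)
            has_soft = cand.record.cigar and (
                cand.record.cigar[0][0] == "S" or cand.record.cigar[-1][0] == "S"
            )
            if not has_soft:
                continue
            if realigner is None:
                if not graph.nodes:
                    break
                realigner = GraphRealigner(
                    graph, reference, insert_model, realign_params, graph_params
                )
            result = realigner.realign(cand)
            if isinstance(result, RealignedPlacement):
                accepted.append(result)

    pairs = collect_discordant_pairs(all_discordant, calling_params.mapq_min)
    raw_calls = assemble_circles(accepted, pairs, slack, calling_params)

    with pysam.AlignmentFile(str(bam_path)) as bam:
        kept = [
            c for c in raw_calls
            if allele_frequency_filter(
                c, breakpoint_depth(bam, c.interval), calling_params.allele_frequency_min
            )
        ]
        merged = merge_reciprocal(kept, calling_params.merge_fraction)
        for c in merged:
            (
                c.mean_coverage,
                c.sd_coverage,
                c.fraction_uncovered,
                c.coverage_increase_start,
                c.coverage_increase_end,
            ) = compute_coverage_metrics(c.interval, bam)
    reference.close()
    if output_path is not None:
        write_circles_bed(merged, output_path)
    return merged
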