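"""Breakpoint-graph construction.

Candidate reads are clustered by genomic proximity (single linkage, gap
threshold K). Each cluster yields a weighted graph G = (N, E): nodes are
genomic regions containing at least one breakpoint of unknown exact
position; edges connect a node to the regions its members' discordant
mates and supplementary alignments point at, i.e. putative circle
junctions. Edge weights are derived from the mapping qualities of the
supporting placements and normalised over the graph; low-weight edges are
pruned before realignment. Node intervals are finally extended by
mu + n*sigma of the insert-size distribution so that regions seeded only
by discordant reads still contain the actual breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .extract import CandidateRead
from .io import GenomicInterval, InsertSizeModel


@dataclass
class GraphParams:
    cluster_distance: int = 500      # K: max gap between neighbouring candidate starts
    prune_threshold: float = 0.01
    extension_sigmas: float = 5.0
    weight_mode: str = "correct_mapping"   # or "as_printed"

    def __post_init__(self) -> None:
        if self.cluster_distance <= 0:
            raise ValueError("cluster_distance must be positive")
        if not (0.0 <= self.prune_threshold < 1.0):
            raise ValueError("prune_threshold must lie in [0, 1)")
        if self.weight_mode not in ("correct_mapping", "as_printed"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")


@dataclass
class BreakpointNode:
    interval: GenomicInterval
    member_reads: list[CandidateRead] = field(default_factory=list)

    def contains(self, pos: int) -> bool:
        return self.interval.start <= pos < self.interval.end

    @property
    def has_soft_clip_member(self) -> bool:
        return any(
            m.record.cigar and (m.record.cigar[0][0] == "S" or m.record.cigar[-1][0] == "S")
            for m in self.member_reads
        )


@dataclass
class BreakpointEdge:
    node_a: BreakpointNode
    node_b: BreakpointNode
    support: list[tuple[str, int]] = field(default_factory=list)  # (source, mapq)
    weight: float = 0.0


@dataclass
class BreakpointGraph:
    nodes: list[BreakpointNode] = field(default_factory=list)
    edges: list[BreakpointEdge] = field(default_factory=list)
    degenerate: bool = False

    def node_at(self, pos: int) -> BreakpointNode | None:
        for node in self.nodes:
            if node.contains(pos):
                return node
        return None

    def neighbours(self, node: BreakpointNode) -> list[BreakpointNode]:
        out = []
        for edge in self.edges:
            if edge.node_a is node:
                out.append(edge.node_b)
            elif edge.node_b is node:
                out.append(edge.node_a)
        return out


def cluster_candidates(
    candidates: Iterable[CandidateRead],
    params: GraphParams | None = None,
) -> Iterator[list[CandidateRead]]:
    """Single-linkage clustering of coordinate-sorted candidates.

    Consecutive reads on the same contig whose alignment starts are less
    than K apart chain into one cluster; a gap >= K or a contig change
    starts a new one.
    """
    params = params or GraphParams()
    cluster: list[CandidateRead] = []
    prev_contig: str | None = None
    prev_pos = 0
    for cand in candidates:
        contig, pos = cand.record.contig, cand.record.pos
        if cluster and (contig != prev_contig or pos - prev_pos >= params.cluster_distance):
            yield cluster
            cluster = []
        cluster.append(cand)
        prev_contig, prev_pos = contig, pos
    if cluster:
        yield cluster


def _merge_member_intervals(cluster: list[CandidateRead]) -> list[tuple[int, int]]:
    """Maximal runs of overlapping/adjacent member alignment spans."""
    spans = sorted(
        (c.record.pos, c.record.reference_end) for c in cluster
    )
    merged: list[list[int]] = []
    for start, end in spans:
        if merged and start <= merged[-1][1]:          # 0-gap adjacency merges
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def build_graph(cluster: list[CandidateRead]) -> BreakpointGraph:
    """Construct the breakpoint graph of one cluster.

    Nodes are the merged alignment spans of the members; every member's
    discordant mate position and supplementary placements add an edge from
    the member's node to the node containing the target position, creating
    a new target node when the position falls outside all existing nodes.
    Parallel support accumulates on a single edge per node pair.
    """
    if not cluster:
        raise ValueError("empty cluster")
    contig = cluster[0].record.contig
    graph = BreakpointGraph(
        nodes=[
            BreakpointNode(GenomicInterval(contig, s, e))
            for s, e in _merge_member_intervals(cluster)
        ]
    )
    for cand in cluster:
        node = graph.node_at(cand.record.pos)
        if node is not None:
            node.member_reads.append(cand)

    edge_index: dict[tuple[int, int], BreakpointEdge] = {}
    node_order = {id(n): i for i, n in enumerate(graph.nodes)}

    def _target_node(pos: int, span: int) -> BreakpointNode:
        node = graph.node_at(pos)
        if node is None:
            node = BreakpointNode(GenomicInterval(contig, pos, pos + max(1, span)))
            node_order[id(node)] = len(graph.nodes)
            graph.nodes.append(node)
        return node

    def _add_support(a: BreakpointNode, b: BreakpointNode, source: str, mapq: int) -> None:
        ia, ib = node_order[id(a)], node_order[id(b)]
        key = (min(ia, ib), max(ia, ib))
        edge = edge_index.get(key)
        if edge is None:
            edge = BreakpointEdge(a if ia <= ib else b, b if ia <= ib else a)
            edge_index[key] = edge
            graph.edges.append(edge)
        edge.support.append((source, mapq))

    for cand in cluster:
        rec = cand.record
        node = graph.node_at(rec.pos)
        if node is None:
            continue
        if cand.category == "discordant" and rec.mate_contig == contig and not rec.mate_unmapped:
            mate_node = _target_node(rec.mate_pos, rec.query_length or len(rec.sequence) or 100)
            _add_support(node, mate_node, "discordant_mate", rec.mapq)
        for sa_contig, sa_pos, _strand, _cigar, sa_mapq in rec.supplementary_placements:
            if sa_contig != contig:
                continue
            sa_node = _target_node(sa_pos, rec.query_length or 100)
            _add_support(node, sa_node, "supplementary", sa_mapq)
    return graph


def edge_weight(graph: BreakpointGraph, mode: str = "correct_mapping") -> None:
    """Assign normalised mapping-quality-based weights to every edge.

    Per supporting placement with mapping quality Q the contribution is
    10^(-Q/10) in ``as_printed`` mode (the literal published equation) or
    1 - 10^(-Q/10) in ``correct_mapping`` mode (the probability the
    placement is right; default). Each edge's weight is its summed
    contribution divided by the total over all edges, so weights sum to 1.
    A graph whose total contribution is zero is flagged degenerate and all
    weights are set to 0.
    """
    def contrib(q: int) -> float:
        p_wrong = 10.0 ** (-q / 10.0)
        return p_wrong if mode == "as_printed" else 1.0 - p_wrong

    sums = [sum(contrib(q) for _src, q in e.support) for e in graph.edges]
    total = sum(sums)
    if total <= 0.0:
        for edge in graph.edges:
            edge.weight = 0.0
        graph.degenerate = bool(graph.edges)
        return
    for edge, s in zip(graph.edges, sums):
        edge.weight = s / total


def prune_graph(graph: BreakpointGraph, params: GraphParams | None = None) -> BreakpointGraph:
    """Drop edges below the weight threshold, then nodes left without any
    edge and without a soft-clipped member. Surviving weights are NOT
    renormalised."""
    params = params or GraphParams()
    graph.edges = [e for e in graph.edges if e.weight >= params.prune_threshold]
    connected = set()
    for e in graph.edges:
        connected.add(id(e.node_a))
        connected.add(id(e.node_b))
    graph.nodes = [
        n for n in graph.nodes if id(n) in connected or n.has_soft_clip_member
    ]
    return graph


def extend_node_interval(
    node: BreakpointNode,
    model: InsertSizeModel,
    params: GraphParams | None = None,
    contig_length: int | None = None,
) -> GenomicInterval:
    """Symmetric extension of both node ends by mu + extension_sigmas*sigma,
    clamped to [0, contig length]."""
    params = params or GraphParams()
    ext = int(round(model.mu + params.extension_sigmas * model.sigma))
    start = max(0, node.interval.start - ext)
    end = node.interval.end + ext
    if contig_length is not None:
        end = min(end, contig_length)
        start = min(start, max(0, end - 1))
    return GenomicInterval(node.interval.contig, start, end)
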