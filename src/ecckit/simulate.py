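"""Circle-enriched sequencing simulator.

Emulates a Circle-Seq experiment: circles are excised from a (mutated copy
of a) reference genome and paired-end reads are sampled from the circular
sequence, so that a single fragment model produces all three read classes —
split reads (a read crosses the junction), discordant pairs (the insert
crosses the junction but neither read does) and ordinary concordant pairs.

Outputs are paired FASTQ, a truth BED with the circle coordinates on the
original reference, and optionally a "truth SAM" giving every read its
correct linear placement: split reads get soft-clipped primary alignments
and, when the clipped part is at least ``min_supplementary_clip`` long,
a BWA-style supplementary alignment with reciprocal SA tags. The truth SAM
lets the whole caller run without an external aligner.

Genetic variation is modelled by mutating the reference before excising
circles (i.i.d. substitutions plus geometric-length indels), and sequencing
noise by a uniform per-base error rate with matching phred qualities.
"""

from __future__ import annotations

import math
import os
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .io import GenomicInterval

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
BASES = np.frombuffer(b"ACGT", dtype="S1")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationParams:
    """Study conditions for the simulated Circle-Seq experiment.

    Defaults follow the benchmark design: 2x100 nt reads, insert size
    N(300, 25), circle lengths uniform on [150, 10000] nt, reference
    substitution/indel rates 0.001/0.0001, and a HiSeq-magnitude per-base
    sequencing error rate of 0.001 (phred ~30).
    """

    n_reads: int | None = None          # total read pairs; overrides coverage
    coverage: float = 30.0              # mean depth per circle if n_reads unset
    read_length: int = 100
    insert_mu: float = 300.0
    insert_sigma: float = 25.0
    circle_length_min: int = 150
    circle_length_max: int = 10_000
    substitution_rate: float = 0.001
    indel_rate: float = 0.0001
    base_error_rate: float = 0.001
    min_supplementary_clip: int = 20    # clip length at which an aligner reports a split alignment
    seed: int = 1

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.indel_rate, self.base_error_rate):
            if not (0.0 <= rate < 1.0):
                raise ValueError("rates must lie in [0, 1)")
        if self.insert_mu <= 0:
            raise ValueError("insert_mu must be positive")

    @property
    def base_quality(self) -> int:
        if self.base_error_rate <= 0:
            return 40
        return max(2, min(40, round(-10.0 * math.log10(self.base_error_rate))))


@dataclass
class SimulatedCircle:
    """Ground truth for one circle: coordinates on the original reference
    plus mutated-genome coordinates the reads were drawn from."""

    interval: GenomicInterval            # original reference coordinates
    mut_start: int                       # mutated-genome coordinates
    mut_end: int
    n_split_truth: int = 0
    n_discordant_truth: int = 0
    n_concordant_truth: int = 0


@dataclass
class Variant:
    contig: str
    pos: int                             # original reference coordinate
    ref: str
    alt: str
    kind: str                            # substitution | insertion | deletion


class CoordinateMap:
    """Monotone map from mutated-genome to original-reference coordinates."""

    def __init__(self) -> None:
        self.mut_anchors: list[int] = [0]
        self.orig_anchors: list[int] = [0]

    def add_anchor(self, mut_pos: int, orig_pos: int) -> None:
        self.mut_anchors.append(mut_pos)
        self.orig_anchors.append(orig_pos)

    def to_original(self, mut_pos: int) -> int:
        i = bisect_right(self.mut_anchors, mut_pos) - 1
        return self.orig_anchors[i] + (mut_pos - self.mut_anchors[i])


def generate_synthetic_genome(
    path: str | os.PathLike,
    n_contigs: int = 1,
    contig_length: int = 1_000_000,
    gc: float = 0.5,
    seed: int = 1,
) -> str:
    """Write a random i.i.d. genome with the given GC fraction as FASTA."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    with open(path, "w") as out:
        for i in range(n_contigs):
            seq = rng.choice(BASES, size=contig_length, p=p).tobytes().decode()
            out.write(f">contig{i + 1}\n")
            for j in range(0, contig_length, 80):
                out.write(seq[j : j + 80] + "\n")
    return str(path)


def mutate_reference(
    sequences: dict[str, str],
    params: SimulationParams,
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[Variant], dict[str, CoordinateMap]]:
    """Introduce substitutions and indels; return the mutated sequences, the
    variant list, and per-contig coordinate maps back to the original.

    Substitutions are i.i.d. per base (uniform over the three alternatives);
    indel events occur at ``indel_rate`` per base with lengths geometric(0.7)
    capped at 10, insertions and deletions equally likely.
    """
    mutated: dict[str, str] = {}
    variants: list[Variant] = []
    maps: dict[str, CoordinateMap] = {}
    for contig, seq in sequences.items():
        n = len(seq)
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        if params.substitution_rate > 0:
            sub_pos = np.flatnonzero(rng.random(n) < params.substitution_rate)
            for p in sub_pos:
                ref = arr[p].decode()
                alts = [b for b in "ACGT" if b != ref]
                alt = alts[rng.integers(3)]
                arr[p] = alt.encode()
                variants.append(Variant(contig, int(p), ref, alt, "substitution"))
        subbed = arr.tobytes().decode()

        cmap = CoordinateMap()
        if params.indel_rate > 0:
            indel_pos = np.flatnonzero(rng.random(n) < params.indel_rate)
        else:
            indel_pos = np.array([], dtype=int)
        pieces: list[str] = []
        cursor = 0          # original coordinate
        mut_len = 0
        for p in indel_pos:
            p = int(p)
            if p < cursor:
                continue
            length = int(min(10, rng.geometric(0.7)))
            pieces.append(subbed[cursor:p])
            mut_len += p - cursor
            if rng.random() < 0.5:  # insertion after position p
                ins = rng.choice(BASES, size=length).tobytes().decode()
                pieces.append(ins)
                variants.append(Variant(contig, p, "", ins, "insertion"))
                mut_len += length
                cursor = p
                cmap.add_anchor(mut_len, cursor)
            else:                    # deletion of [p, p+length)
                variants.append(Variant(contig, p, seq[p : p + length], "", "deletion"))
                cursor = min(n, p + length)
                cmap.add_anchor(mut_len, cursor)
        pieces.append(subbed[cursor:])
        mutated[contig] = "".join(pieces)
        maps[contig] = cmap
    return mutated, variants, maps


def sample_circles(
    sequences: dict[str, str],
    n_circles: int,
    params: SimulationParams,
    rng: np.random.Generator,
    maps: dict[str, CoordinateMap] | None = None,
) -> list[SimulatedCircle]:
    """Sample circle coordinates on the (mutated) genome: lengths uniform on
    [circle_length_min, circle_length_max], starts uniform over the valid
    range of a contig chosen proportionally to its length."""
    contigs = list(sequences)
    lens = np.array([len(sequences[c]) for c in contigs], dtype=float)
    if any(lens < params.circle_length_max):
        usable = lens >= params.circle_length_max
        if not usable.any():
            raise ValueError("no contig long enough to place a circle")
        lens = lens * usable
    weights = lens / lens.sum()
    out: list[SimulatedCircle] = []
    for _ in range(n_circles):
        ci = int(rng.choice(len(contigs), p=weights))
        contig = contigs[ci]
        clen = len(sequences[contig])
        length = int(rng.integers(params.circle_length_min, params.circle_length_max + 1))
        length = min(length, clen)
        start = int(rng.integers(0, clen - length + 1))
        end = start + length
        if maps is not None:
            cmap = maps[contig]
            ostart, oend = cmap.to_original(start), cmap.to_original(end)
        else:
            ostart, oend = start, end
        if oend <= ostart:
            oend = ostart + 1
        out.append(
            SimulatedCircle(
                interval=GenomicInterval(contig, ostart, oend),
                mut_start=start,
                mut_end=end,
            )
        )
    return out


@dataclass
class _SimRead:
    """One simulated read in genome-forward orientation."""

    name: str
    seq: str                 # genome-forward sequence (with errors)
    quals: np.ndarray
    is_reverse: bool
    is_first: bool
    category: str            # split | discordant | concordant
    # primary placement, mutated-genome coordinates
    pos: int
    cigar: str
    # supplementary placement for long clips, or None
    supp: tuple[int, str] | None = None        # (pos, cigar) of the clipped part
    clip_side: str = "none"
    clip_len: int = 0


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n = len(seq)
    k = rng.binomial(n, rate)
    if k == 0:
        return seq
    pos = rng.choice(n, size=k, replace=False)
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    for p in pos:
        ref = arr[p].decode()
        alts = [b for b in "ACGT" if b != ref]
        arr[p] = alts[rng.integers(3)].encode()
    return arr.tobytes().decode()


def _circ_slice(circ: str, start: int, length: int) -> str:
    """Slice of the circular sequence starting at ``start`` (mod len)."""
    L = len(circ)
    start %= L
    s = circ[start : start + length]
    while len(s) < length:
        s += circ[: length - len(s)]
    return s


def _placement(offset: int, length: int, circle_start: int, circle_len: int,
               min_supp: int) -> tuple[int, str, tuple[int, str] | None, str, int]:
    """Linear placement of a read covering circle offsets [offset, offset+length).

    Returns (pos, cigar, supplementary (pos, cigar) or None, clip_side, clip_len)
    in mutated-genome coordinates. A read crossing the junction is anchored on
    its longer part; the shorter part becomes the soft clip.
    """
    L = circle_len
    offset %= L
    if offset + length <= L:
        return circle_start + offset, f"{length}M", None, "none", 0
    part1 = L - offset                     # maps at circle end
    part2 = length - part1                 # wraps to circle start
    if part1 >= part2:
        pos = circle_start + offset
        cigar = f"{part1}M{part2}S"
        supp = (circle_start, f"{part1}H{part2}M") if part2 >= min_supp else None
        return pos, cigar, supp, "right", part2
    pos = circle_start
    cigar = f"{part1}S{part2}M"
    # the clipped part1 is the READ's first part, so its own alignment
    # hard-clips the trailing part2
    supp = (circle_start + offset, f"{part1}M{part2}H") if part1 >= min_supp else None
    return pos, cigar, supp, "left", part1


def simulate_reads(
    circle: SimulatedCircle,
    contig_seq: str,
    n_pairs: int,
    params: SimulationParams,
    rng: np.random.Generator,
    name_prefix: str = "sim",
) -> list[tuple[_SimRead, _SimRead]]:
    """Sample ``n_pairs`` paired fragments from one circle.

    Fragment starts are uniform on the circle; insert lengths are
    N(insert_mu, insert_sigma) truncated to [read_length, circle length]
    (upper bound applies when the circle is shorter than the typical
    insert). Reads overlapping the junction become split reads, fragments
    whose insert spans the junction become discordant pairs, everything
    else is concordant. Read 1 is always the fragment's forward-strand read
    (see inline note), so junction-spanning pairs carry the canonical
    discordant orientation signature.
    """
    L = circle.mut_end - circle.mut_start
    rl = params.read_length
    circ = contig_seq[circle.mut_start : circle.mut_end]
    lo = min(rl, L)
    hi = max(lo, min(L, int(round(params.insert_mu + 10 * params.insert_sigma))))
    inserts = np.clip(
        np.round(rng.normal(params.insert_mu, params.insert_sigma, size=n_pairs)),
        lo, hi,
    ).astype(int)
    starts = rng.integers(0, L, size=n_pairs)
    pairs: list[tuple[_SimRead, _SimRead]] = []
    for i in range(n_pairs):
        f, ins = int(starts[i]), int(inserts[i])
        rl_eff = min(rl, ins)
        t = (f + ins - rl_eff) % L
        fwd_wraps = f + rl_eff > L
        rev_wraps = t + rl_eff > L
        if fwd_wraps or rev_wraps:
            category = "split"
        elif f + ins > L:
            category = "discordant"
        else:
            category = "concordant"
        name = f"{name_prefix}:{i}:{category[0]}"
        reads = []
        # read 1 is the fragment's forward-strand read: on a junction-spanning
        # fragment the reverse-strand read 2 maps leftmost on the genome,
        # which is exactly the discordant orientation signature
        for offset, is_rev, is_first in ((f, False, True), (t, True, False)):
            seq = _apply_errors(_circ_slice(circ, offset, rl_eff), params.base_error_rate, rng)
            pos, cigar, supp, side, clip_len = _placement(
                offset, rl_eff, circle.mut_start, L, params.min_supplementary_clip
            )
            reads.append(
                _SimRead(
                    name=name, seq=seq,
                    quals=np.full(rl_eff, params.base_quality, dtype=np.uint8),
                    is_reverse=is_rev, is_first=is_first, category=category,
                    pos=pos, cigar=cigar, supp=supp, clip_side=side, clip_len=clip_len,
                )
            )
        n_split_here = sum(1 for r in reads if r.clip_side != "none")
        circle.n_split_truth += n_split_here
        if category == "discordant":
            circle.n_discordant_truth += 1
        elif category == "concordant":
            circle.n_concordant_truth += 1
        pairs.append((reads[0], reads[1]))
    return pairs


def _pairs_for_circle(length: int, params: SimulationParams) -> int:
    return max(1, int(round(params.coverage * length / (2.0 * params.read_length))))


def write_truth(circles: list[SimulatedCircle], path: str | os.PathLike) -> None:
    """Truth BED: contig, start, end plus per-class truth read counts."""
    with open(path, "w") as out:
        for c in circles:
            out.write(
                f"{c.interval.contig}\t{c.interval.start}\t{c.interval.end}\t"
                f"{c.n_split_truth}\t{c.n_discordant_truth}\t{c.n_concordant_truth}\n"
            )


def _parse_cigar_len(cigar: str) -> int:
    total, num = 0, ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MIS=X":
                total += int(num)
            num = ""
    return total


def _sam_flag(read: _SimRead, mate: _SimRead, supplementary: bool = False) -> int:
    flag = 0x1
    if read.category == "concordant":
        flag |= 0x2
    if read.is_reverse:
        flag |= 0x10
    if mate.is_reverse:
        flag |= 0x20
    flag |= 0x40 if read.is_first else 0x80
    if supplementary:
        flag |= 0x800
    return flag


def simulate_dataset(
    reference_path: str | os.PathLike,
    out_dir: str | os.PathLike,
    n_circles: int,
    params: SimulationParams,
    truth_sam: bool = True,
) -> dict[str, str]:
    """Run the full simulation and write FASTQ pair, truth BED and truth SAM.

    Returns a dict of output paths. The truth SAM places reads on the
    ORIGINAL reference coordinates (indel coordinate shifts mapped back),
    emitting soft-clipped primaries for split reads and supplementary
    alignments with SA tags for clips >= ``params.min_supplementary_clip``.
    """
    from pyfaidx import Fasta

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)

    fasta = Fasta(str(reference_path), sequence_always_upper=True)
    sequences = {name: str(fasta[name][:]) for name in fasta.keys()}
    orig_lengths = {name: len(seq) for name, seq in sequences.items()}
    fasta.close()

    mutated, variants, maps = mutate_reference(sequences, params, rng)
    del sequences
    circles = sample_circles(mutated, n_circles, params, rng, maps=maps)

    total_len = sum(c.mut_end - c.mut_start for c in circles)
    if params.n_reads is not None:
        alloc = [
            max(1, int(round(params.n_reads * (c.mut_end - c.mut_start) / total_len)))
            for c in circles
        ]
    else:
        alloc = [_pairs_for_circle(c.mut_end - c.mut_start, params) for c in circles]

    paths = {
        "fastq1": str(out_dir / "reads_1.fastq"),
        "fastq2": str(out_dir / "reads_2.fastq"),
        "truth_bed": str(out_dir / "truth.bed"),
    }
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "queryname"},
            "SQ": [{"SN": c, "LN": n} for c, n in orig_lengths.items()],
        }
    )
    sam_out = None
    if truth_sam:
        paths["truth_sam"] = str(out_dir / "truth.sam")
        sam_out = pysam.AlignmentFile(paths["truth_sam"], "w", header=header)

    fq1 = open(paths["fastq1"], "w")
    fq2 = open(paths["fastq2"], "w")
    try:
        for idx, (circle, n_pairs) in enumerate(zip(circles, alloc)):
            contig = circle.interval.contig
            cmap = maps[contig]
            clen = orig_lengths[contig]
            pairs = simulate_reads(
                circle, mutated[contig], n_pairs, params, rng,
                name_prefix=f"sim{idx}",
            )
            for r1, r2 in pairs:
                for read, mate in ((r1, r2), (r2, r1)):
                    fq = fq1 if read.is_first else fq2
                    seq = revcomp(read.seq) if read.is_reverse else read.seq
                    quals = read.quals[::-1] if read.is_reverse else read.quals
                    qual = "".join(chr(int(q) + 33) for q in quals)
                    fq.write(f"@{read.name}\n{seq}\n+\n{qual}\n")
                if sam_out is not None:
                    _write_sam_pair(sam_out, header, contig, clen, cmap, r1, r2)
    finally:
        fq1.close()
        fq2.close()
        if sam_out is not None:
            sam_out.close()

    write_truth(circles, paths["truth_bed"])
    with open(out_dir / "variants.tsv", "w") as vf:
        for v in variants:
            vf.write(f"{v.contig}\t{v.pos}\t{v.kind}\t{v.ref}\t{v.alt}\n")
    paths["variants"] = str(out_dir / "variants.tsv")
    return paths


def _map_pos(cmap: CoordinateMap, pos: int, clen: int) -> int:
    return max(0, min(clen - 1, cmap.to_original(pos)))


def _write_sam_pair(sam_out, header, contig, clen, cmap, r1: _SimRead, r2: _SimRead) -> None:
    mapq = 60
    placements = {}
    for read in (r1, r2):
        placements[id(read)] = _map_pos(cmap, read.pos, clen)
    for read, mate in ((r1, r2), (r2, r1)):
        pos = placements[id(read)]
        mate_pos = placements[id(mate)]
        aln = pysam.AlignedSegment(header)
        aln.query_name = read.name
        aln.flag = _sam_flag(read, mate)
        aln.reference_id = header.get_tid(contig)
        aln.reference_start = pos
        aln.mapping_quality = mapq
        aln.cigarstring = read.cigar
        aln.query_sequence = read.seq
        aln.query_qualities = read.quals.tolist()
        aln.next_reference_id = aln.reference_id
        aln.next_reference_start = mate_pos
        left = min(pos, mate_pos)
        right_end = max(pos + len(read.seq), mate_pos + len(mate.seq))
        span = right_end - left
        leftmost = pos < mate_pos or (pos == mate_pos and not read.is_reverse)
        aln.template_length = span if leftmost else -span
        supp_sa = None
        if read.supp is not None:
            supp_pos = _map_pos(cmap, read.supp[0], clen)
            strand = "-" if read.is_reverse else "+"
            supp_sa = f"{contig},{supp_pos + 1},{strand},{read.supp[1]},{mapq},0;"
            aln.set_tag("SA", supp_sa)
        sam_out.write(aln)
        if read.supp is not None:
            supp_pos = _map_pos(cmap, read.supp[0], clen)
            supp = pysam.AlignedSegment(header)
            supp.query_name = read.name
            supp.flag = _sam_flag(read, mate, supplementary=True)
            supp.reference_id = header.get_tid(contig)
            supp.reference_start = supp_pos
            supp.mapping_quality = mapq
            supp_cigar = read.supp[1]
            supp.cigarstring = supp_cigar
            # hard-clipped record carries only the aligned bases
            if supp_cigar.endswith("M"):          # leading hard clip: NNH MMM
                hard = int(supp_cigar[: supp_cigar.index("H")])
                supp.query_sequence = read.seq[hard:]
                supp.query_qualities = read.quals[hard:].tolist()
            else:                                 # trailing hard clip: MMM NNH
                m = int(supp_cigar[: supp_cigar.index("M")])
                supp.query_sequence = read.seq[:m]
                supp.query_qualities = read.quals[:m].tolist()
            supp.next_reference_id = supp.reference_id
            supp.next_reference_start = placements[id(mate)]
            strand = "-" if read.is_reverse else "+"
            supp.set_tag("SA", f"{contig},{pos + 1},{strand},{read.cigar},{mapq},0;")
            sam_out.write(supp)


def sort_alignment(path: str, out_path: str, by_name: bool = False, index: bool = False) -> str:
    """Sort (and optionally index) a SAM/BAM file via pysam/samtools."""
    args = ["-o", out_path]
    if by_name:
        args = ["-n"] + args
    pysam.sort(*args, str(path))
    if index and not by_name:
        pysam.index(out_path)
    return out_path
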