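"""Candidate-read extraction.

One pass through a name-sorted alignment file keeps only reads that can
carry circular-DNA evidence: discordant pairs (opposite orientation with
the second-in-pair read leftmost), soft-clipped reads and hard-clipped
reads. Concordant, fully aligned pairs are dropped, as are interchromosomal
pairs — the caller models intrachromosomal junctions only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Iterator

import pysam

from .io import ReadRecord, read_alignment_stream, record_to_pysam

#: BAM tag carrying the candidate category through the candidate file.
CATEGORY_TAG = "cc"
_CATEGORY_CODE = {"discordant": "D", "soft_clip": "S", "hard_clip": "H"}
_CODE_CATEGORY = {v: k for k, v in _CATEGORY_CODE.items()}


@dataclass
class CandidateRead:
    record: ReadRecord
    category: str                 # discordant | soft_clip | hard_clip
    clip_side: str = "none"       # left | right | none
    clip_length: int = 0
    realign_only: bool = False    # low-MAPQ secondary split: realign, never direct support

    def __post_init__(self) -> None:
        if self.category == "soft_clip" and (self.clip_length < 1 or self.clip_side == "none"):
            raise ValueError("soft_clip candidate requires a terminal clip")


def is_discordant(read1: ReadRecord, read2: ReadRecord) -> bool:
    """Literal circle-orientation rule: the mates aligned in opposite
    orientation and the second-in-pair read is leftmost.

    ``read1``/``read2`` are identified by their first/second-in-pair flags,
    not argument order. Unmapped mates are not evaluable -> False.
    """
    if read1.is_unmapped or read2.is_unmapped:
        return False
    first = read1 if read1.is_first else read2
    second = read2 if read1.is_first else read1
    if first.is_reverse == second.is_reverse:
        return False
    return second.pos < first.pos


def classify_clip(record: ReadRecord) -> tuple[str, str, int]:
    """Category, side and length of the largest terminal clip of a CIGAR.

    Returns ("none", "none", 0) when no S/H operation is present. Soft
    clips take precedence over hard clips when both terminal operations
    exist (the soft clip carries sequence to realign).
    """
    if not record.cigar:
        return "none", "none", 0
    clips = []  # (length, side, op)
    op0, n0 = record.cigar[0]
    if op0 in ("S", "H"):
        clips.append((n0, "left", op0))
    if len(record.cigar) > 1:
        op1, n1 = record.cigar[-1]
        if op1 in ("S", "H"):
            clips.append((n1, "right", op1))
    if not clips:
        return "none", "none", 0
    soft = [c for c in clips if c[2] == "S"]
    pool = soft if soft else clips
    length, side, op = max(pool, key=lambda c: c[0])
    return ("soft_clip" if op == "S" else "hard_clip"), side, length


def extract_candidates(stream: Iterable[ReadRecord]) -> Iterator[CandidateRead]:
    """Emit candidate reads from a name-sorted record stream.

    Per template: the primary pair is emitted as discordant when the
    orientation/order rule holds (both categories dropped otherwise unless
    clipped); non-discordant members with terminal clips are emitted as
    soft/hard-clip candidates. Interchromosomal pairs are dropped entirely;
    secondary and supplementary records are skipped (supplementary
    placements travel on the primary's SA tag). Singleton templates are
    processed for clips only.
    """
    for _, group in groupby(stream, key=lambda r: r.query_name):
        primaries = [
            r for r in group
            if not r.is_secondary and not r.is_supplementary and not r.is_unmapped
        ]
        if not primaries:
            continue
        first = next((r for r in primaries if r.is_first), None)
        second = next((r for r in primaries if r.is_second), None)
        if first is not None and second is not None:
            if first.contig != second.contig:
                continue
            if is_discordant(first, second):
                for rec in (first, second):
                    _, side, length = classify_clip(rec)
                    yield CandidateRead(rec, "discordant", side, length)
                continue
        for rec in primaries:
            category, side, length = classify_clip(rec)
            if category != "none":
                yield CandidateRead(rec, category, side, length)


def write_candidates(
    candidates: Iterable[CandidateRead],
    path: str | os.PathLike,
    template_header: pysam.AlignmentHeader,
) -> int:
    """Write candidates as SAM/BAM, tagging each record with its category."""
    mode = "wb" if str(path).endswith(".bam") else "w"
    n = 0
    header_dict = template_header.to_dict()
    header_dict.setdefault("HD", {})["SO"] = "unsorted"
    header = pysam.AlignmentHeader.from_dict(header_dict)
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for cand in candidates:
            aln = record_to_pysam(cand.record, header)
            aln.set_tag(CATEGORY_TAG, _CATEGORY_CODE[cand.category])
            out.write(aln)
            n += 1
    return n


def read_candidates(path: str | os.PathLike) -> Iterator[CandidateRead]:
    """Read back a candidate file written by :func:`write_candidates`."""
    for rec in read_alignment_stream(path):
        code = rec.tags.get(CATEGORY_TAG)
        if code is None:
            category, side, length = classify_clip(rec)
            if category == "none":
                category = "discordant"
        else:
            category = _CODE_CATEGORY[code]
            _, side, length = classify_clip(rec)
        yield CandidateRead(rec, category, side, length)


def extract_to_file(
    input_path: str | os.PathLike,
    output_path: str | os.PathLike,
) -> int:
    """CLI backend: extract candidates from a name-sorted file to SAM/BAM."""
    with pysam.AlignmentFile(str(input_path), check_sq=False) as fh:
        header = fh.header
    stream = read_alignment_stream(input_path)
    return write_candidates(extract_candidates(stream), output_path, header)
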