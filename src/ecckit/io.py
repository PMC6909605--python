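"""Alignment, reference and interval I/O.

Thin wrappers around pysam and pyfaidx that expose the handful of records
the circle-detection pipeline needs: alignment rows (:class:`ReadRecord`),
the insert-size model estimated from concordant pairs, genomic intervals,
and the tab-separated circle output table.

All internal coordinates are 0-based half-open; the single conversion from
SAM's 1-based convention happens inside pysam at parse time.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import pysam
from pyfaidx import Fasta

# CIGAR operation codes as used by pysam (BAM encoding).
CIGAR_OPS = "MIDNSHP=X"
QUERY_CONSUMING = {"M", "I", "S", "=", "X"}
REF_CONSUMING = {"M", "D", "N", "=", "X"}

#: Columns of the circle output table, in order.
CIRCLE_COLUMNS = (
    "contig",
    "start",
    "end",
    "discordant_reads",
    "split_reads",
    "circle_score",
    "mean_coverage",
    "sd_coverage",
    "fraction_uncovered",
    "coverage_increase_start",
    "coverage_increase_end",
)


class SortOrderError(ValueError):
    """Alignment file sort order does not match what the caller expects."""


class InsufficientDataError(ValueError):
    """Not enough usable records to estimate a model."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on one contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class InsertSizeModel:
    """Mean/s.d. of absolute template length of concordant proper pairs."""

    mu: float
    sigma: float
    n_observations: int

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_observations < 2:
            raise ValueError("need >= 2 observations")

    @property
    def extension(self) -> float:
        """Default search-space extension mu + 5*sigma (see graph module)."""
        return self.mu + 5.0 * self.sigma


@dataclass
class ReadRecord:
    """One alignment row, decoupled from the pysam handle that produced it.

    ``supplementary_placements`` holds (contig, pos, strand, cigar, mapq)
    tuples parsed from the SA tag; ``pos`` there is 0-based.
    """

    query_name: str
    contig: str | None
    pos: int
    cigar: tuple[tuple[str, int], ...]
    mapq: int
    flag: int
    mate_contig: str | None
    mate_pos: int
    template_length: int
    sequence: str
    base_qualities: tuple[int, ...]
    tags: dict = field(default_factory=dict)
    supplementary_placements: tuple[tuple[str, int, str, str, int], ...] = ()

    # -- flag helpers -------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flag & 0x1)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & 0x4)

    @property
    def mate_unmapped(self) -> bool:
        return bool(self.flag & 0x8)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 0x10)

    @property
    def is_first(self) -> bool:
        return bool(self.flag & 0x40)

    @property
    def is_second(self) -> bool:
        return bool(self.flag & 0x80)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & 0x100)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & 0x400)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & 0x800)

    @property
    def is_proper_pair(self) -> bool:
        return bool(self.flag & 0x2)

    # -- CIGAR arithmetic ---------------------------------------------
    @property
    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in QUERY_CONSUMING)

    @property
    def reference_span(self) -> int:
        return sum(n for op, n in self.cigar if op in REF_CONSUMING)

    @property
    def reference_end(self) -> int:
        return self.pos + self.reference_span

    def validate(self) -> None:
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        if self.sequence and self.sequence != "*":
            if len(self.sequence) != self.query_length:
                raise ValueError(
                    f"{self.query_name}: sequence length {len(self.sequence)} "
                    f"!= query-consuming CIGAR sum {self.query_length}"
                )
            if self.base_qualities and len(self.base_qualities) != len(self.sequence):
                raise ValueError("base_qualities length != sequence length")


def _parse_sa_tag(sa: str) -> tuple[tuple[str, int, str, str, int], ...]:
    out = []
    for part in sa.rstrip(";").split(";"):
        if not part:
            continue
        contig, pos, strand, cigar, mapq, _nm = part.split(",")
        out.append((contig, int(pos) - 1, strand, cigar, int(mapq)))
    return tuple(out)


def record_from_pysam(aln: pysam.AlignedSegment) -> ReadRecord:
    cigar = tuple(
        (CIGAR_OPS[op], n) for op, n in (aln.cigartuples or ())
    )
    quals = tuple(aln.query_qualities) if aln.query_qualities is not None else ()
    tags = dict(aln.get_tags())
    sa = tags.get("SA")
    rec = ReadRecord(
        query_name=aln.query_name,
        contig=aln.reference_name,
        pos=aln.reference_start if aln.reference_start >= 0 else 0,
        cigar=cigar,
        mapq=aln.mapping_quality,
        flag=aln.flag,
        mate_contig=aln.next_reference_name,
        mate_pos=aln.next_reference_start,
        template_length=aln.template_length,
        sequence=aln.query_sequence or "",
        base_qualities=quals,
        tags=tags,
        supplementary_placements=_parse_sa_tag(sa) if sa else (),
    )
    rec.validate()
    return rec


def record_to_pysam(rec: ReadRecord, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    aln = pysam.AlignedSegment(header)
    aln.query_name = rec.query_name
    aln.flag = rec.flag
    if rec.contig is not None:
        aln.reference_id = header.get_tid(rec.contig)
        aln.reference_start = rec.pos
    aln.mapping_quality = rec.mapq
    aln.cigartuples = [(CIGAR_OPS.index(op), n) for op, n in rec.cigar]
    if rec.mate_contig is not None:
        aln.next_reference_id = header.get_tid(rec.mate_contig)
        aln.next_reference_start = rec.mate_pos
    aln.template_length = rec.template_length
    aln.query_sequence = rec.sequence or None
    if rec.base_qualities:
        aln.query_qualities = list(rec.base_qualities)
    for key, val in rec.tags.items():
        aln.set_tag(key, val)
    return aln


def read_alignment_stream(path: str | os.PathLike, expected_sort: str | None = None) -> Iterator[ReadRecord]:
    """Yield every record of a SAM/BAM file as a :class:`ReadRecord`.

    If ``expected_sort`` ("queryname" or "coordinate") is given, the
    header's declared SO field must match, otherwise :class:`SortOrderError`
    is raised. "name" is accepted as an alias for "queryname".
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if expected_sort == "name":
        expected_sort = "queryname"
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        if expected_sort is not None:
            declared = fh.header.get("HD", {}).get("SO", "unknown")
            if declared != expected_sort:
                raise SortOrderError(
                    f"{path}: header declares sort order {declared!r}, "
                    f"expected {expected_sort!r}"
                )
        for aln in fh:
            yield record_from_pysam(aln)


def is_concordant_unclipped(rec: ReadRecord) -> bool:
    """Usable for insert-size estimation: aligner-flagged proper pair,
    primary, both mapped, no clipped bases."""
    return (
        rec.is_paired
        and rec.is_proper_pair
        and not rec.is_unmapped
        and not rec.mate_unmapped
        and not rec.is_secondary
        and not rec.is_supplementary
        and not any(op in ("S", "H") for op, _ in rec.cigar)
    )


def estimate_insert_size(stream: Iterator[ReadRecord], sample_size: int = 100_000) -> InsertSizeModel:
    """Sample mean/s.d. of absolute template length over concordant pairs.

    Each pair is counted once via the member with positive template length.
    Raises :class:`InsufficientDataError` below 2 usable pairs.
    """
    lengths: list[int] = []
    for rec in stream:
        if len(lengths) >= sample_size:
            break
        if is_concordant_unclipped(rec) and rec.template_length > 0:
            lengths.append(rec.template_length)
    n = len(lengths)
    if n < 2:
        raise InsufficientDataError(
            f"only {n} concordant proper pairs found; need >= 2"
        )
    mu = sum(lengths) / n
    var = sum((x - mu) ** 2 for x in lengths) / (n - 1)
    return InsertSizeModel(mu=mu, sigma=math.sqrt(var), n_observations=n)


def estimate_insert_size_from_file(path: str | os.PathLike, sample_size: int = 100_000) -> InsertSizeModel:
    return estimate_insert_size(read_alignment_stream(path), sample_size)


class ReferenceGenome:
    """Indexed FASTA access with clamped, uppercase, half-open fetches."""

    def __init__(self, path: str | os.PathLike):
        self._fasta = Fasta(str(path), sequence_always_upper=True)

    def contigs(self) -> list[str]:
        return list(self._fasta.keys())

    def contig_length(self, contig: str) -> int:
        return len(self._fasta[contig])

    def fetch(self, interval: GenomicInterval) -> str:
        return self.fetch_region(interval.contig, interval.start, interval.end)

    def fetch_region(self, contig: str, start: int, end: int) -> str:
        if contig not in self._fasta:
            raise KeyError(f"unknown contig {contig!r}")
        length = len(self._fasta[contig])
        start = max(0, min(start, length))
        end = max(start, min(end, length))
        if end == start:
            return ""
        return str(self._fasta[contig][start:end])

    def close(self) -> None:
        self._fasta.close()


def fetch_sequence(reference: ReferenceGenome, interval: GenomicInterval) -> str:
    """Uppercase reference sequence for ``interval``, clamped to the contig."""
    return reference.fetch(interval)


def write_circles_bed(circles: Sequence, path: str | os.PathLike) -> None:
    """Write circle calls as a tab-separated, BED-style table.

    One row per call, ordered by (contig, start, end); floating columns are
    written with 4 decimals. The objects only need the attributes named in
    :data:`CIRCLE_COLUMNS` (interval fields come from ``.interval``).
    """
    rows = sorted(circles, key=lambda c: (c.interval.contig, c.interval.start, c.interval.end))
    with open(path, "w") as out:
        for c in rows:
            fields = [
                c.interval.contig,
                str(c.interval.start),
                str(c.interval.end),
                str(c.n_discordant),
                str(c.n_split),
                f"{c.circle_score:.4f}",
                f"{c.mean_coverage:.4f}",
                f"{c.sd_coverage:.4f}",
                f"{c.fraction_uncovered:.4f}",
                f"{c.coverage_increase_start:.4f}",
                f"{c.coverage_increase_end:.4f}",
            ]
            out.write("\t".join(fields) + "\n")


def read_bed_intervals(path: str | os.PathLike) -> list[GenomicInterval]:
    """First three columns of a BED file as intervals (comments skipped)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    return out
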