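"""Shared fixtures: toy SAM/FASTA builders and session-scoped simulated
datasets run through the full pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pysam
import pytest

from ecckit.calling import call_circles
from ecckit.extract import extract_to_file
from ecckit.evaluate import benchmark
from ecckit.io import ReadRecord, read_bed_intervals
from ecckit.simulate import (
    SimulationParams,
    generate_synthetic_genome,
    simulate_dataset,
    sort_alignment,
)


def make_record(
    name: str = "r1",
    contig: str = "contig1",
    pos: int = 0,
    cigar: tuple[tuple[str, int], ...] = (("M", 100),),
    mapq: int = 60,
    flag: int = 0,
    mate_contig: str | None = None,
    mate_pos: int = 0,
    template_length: int = 0,
    sequence: str = "",
    base_qualities: tuple[int, ...] = (),
    supplementary_placements: tuple = (),
) -> ReadRecord:
    if not sequence:
        qlen = sum(n for op, n in cigar if op in "MIS=X")
        sequence = "A" * qlen
        base_qualities = (30,) * qlen
    return ReadRecord(
        query_name=name,
        contig=contig,
        pos=pos,
        cigar=cigar,
        mapq=mapq,
        flag=flag,
        mate_contig=mate_contig if mate_contig is not None else contig,
        mate_pos=mate_pos,
        template_length=template_length,
        sequence=sequence,
        base_qualities=base_qualities,
        supplementary_placements=supplementary_placements,
    )


def write_sam(path, records, contigs=(("contig1", 100_000),), sort_order="queryname"):
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": sort_order},
            "SQ": [{"SN": c, "LN": n} for c, n in contigs],
        }
    )
    from ecckit.io import record_to_pysam

    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            out.write(record_to_pysam(rec, header))
    return str(path)


@pytest.fixture
def toy_fasta(tmp_path):
    path = tmp_path / "toy.fa"
    path.write_text(">toy\nACGT\n")
    return str(path)


@dataclass
class PipelineRun:
    genome: str
    truth_bed: str
    truth: list
    calls: list
    result: object
    coord_bam: str
    candidates_bam: str


def run_pipeline(genome: str, out_dir: Path, n_circles: int, params: SimulationParams) -> PipelineRun:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = simulate_dataset(genome, out_dir, n_circles, params, truth_sam=True)
    name_bam = str(out_dir / "name.bam")
    coord_bam = str(out_dir / "coord.bam")
    cand_bam = str(out_dir / "cand.bam")
    cand_sorted = str(out_dir / "cand.sorted.bam")
    sort_alignment(paths["truth_sam"], name_bam, by_name=True)
    sort_alignment(paths["truth_sam"], coord_bam, index=True)
    extract_to_file(name_bam, cand_bam)
    sort_alignment(cand_bam, cand_sorted, index=True)
    calls = call_circles(cand_sorted, coord_bam, genome)
    truth = read_bed_intervals(paths["truth_bed"])
    result = benchmark([c.interval for c in calls], truth, fraction=0.95)
    return PipelineRun(
        genome=genome,
        truth_bed=paths["truth_bed"],
        truth=truth,
        calls=calls,
        result=result,
        coord_bam=coord_bam,
        candidates_bam=cand_sorted,
    )


@pytest.fixture(scope="session")
def genome_5mb(tmp_path_factory):
    path = tmp_path_factory.mktemp("genome") / "genome5mb.fa"
    return generate_synthetic_genome(path, n_contigs=1, contig_length=5_000_000, gc=0.41, seed=101)


@pytest.fixture(scope="session")
def run_30x(genome_5mb, tmp_path_factory):
    """30X benchmark replicate: 300 circles, 150-10,000 nt, full noise model."""
    return run_pipeline(
        genome_5mb,
        tmp_path_factory.mktemp("sim30x"),
        n_circles=300,
        params=SimulationParams(coverage=30.0, seed=102),
    )


@pytest.fixture(scope="session")
def run_7_5x(genome_5mb, tmp_path_factory):
    """Quarter-depth replicate of the 30X design."""
    return run_pipeline(
        genome_5mb,
        tmp_path_factory.mktemp("sim75x"),
        n_circles=300,
        params=SimulationParams(coverage=7.5, seed=102),
    )


@pytest.fixture(scope="session")
def run_short(genome_5mb, tmp_path_factory):
    """Very short circles (150-350 nt) at 30X."""
    return run_pipeline(
        genome_5mb,
        tmp_path_factory.mktemp("simshort"),
        n_circles=250,
        params=SimulationParams(
            coverage=30.0, seed=103, circle_length_min=150, circle_length_max=350
        ),
    )


@pytest.fixture(scope="session")
def run_errorfree(tmp_path_factory):
    """Zero error rates + truth alignments: single-nucleotide resolution run."""
    gdir = tmp_path_factory.mktemp("genome_ef")
    genome = generate_synthetic_genome(gdir / "g1mb.fa", 1, 1_000_000, 0.5, seed=104)
    return run_pipeline(
        genome,
        tmp_path_factory.mktemp("simexact"),
        n_circles=30,
        params=SimulationParams(
            coverage=30.0, seed=105,
            substitution_rate=0.0, indel_rate=0.0, base_error_rate=0.0,
        ),
    )
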