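"""Benchmark metrics against a truth interval set.

Sensitivity is the fraction of truth circles matched by at least one call
and precision the fraction of calls matching at least one truth circle,
with matching defined by fractional interval overlap (default 0.95,
applied reciprocally). Also provides the coverage-fraction histogram and
the breakpoint-read versus mean-coverage Pearson correlation used as
orthogonal quality diagnostics on circle-enriched data without a truth
set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io import GenomicInterval


@dataclass
class BenchmarkResult:
    sensitivity: float
    precision: float
    n_truth: int
    n_called: int
    n_matched: int        # truth circles matched by >= 1 call


def fractional_overlap_match(
    a: GenomicInterval,
    b: GenomicInterval,
    fraction: float = 0.95,
    reciprocal: bool = True,
) -> bool:
    """True when the overlap covers ``fraction`` of both intervals
    (``reciprocal=False``: of ``a`` only)."""
    ov = a.overlap(b)
    if ov <= 0:
        return False
    if ov < fraction * len(a):
        return False
    return (not reciprocal) or ov >= fraction * len(b)


def _match_any(
    queries: Sequence[GenomicInterval],
    subjects: Sequence[GenomicInterval],
    fraction: float,
    reciprocal: bool,
) -> int:
    """Number of queries matched by >= 1 subject (greedy, many-to-one)."""
    by_contig: dict[str, list[GenomicInterval]] = {}
    for s in subjects:
        by_contig.setdefault(s.contig, []).append(s)
    for lst in by_contig.values():
        lst.sort(key=lambda i: i.start)
    matched = 0
    for q in queries:
        pool = by_contig.get(q.contig, [])
        starts = np.array([i.start for i in pool]) if pool else np.array([])
        if not pool:
            continue
        # subjects starting before q.end can overlap
        hi = int(np.searchsorted(starts, q.end))
        for s in pool[:hi]:
            if s.end <= q.start:
                continue
            if fractional_overlap_match(q, s, fraction, reciprocal):
                matched += 1
                break
    return matched


def benchmark(
    calls: Sequence[GenomicInterval],
    truth: Sequence[GenomicInterval],
    fraction: float = 0.95,
    reciprocal: bool = True,
) -> BenchmarkResult:
    """Sensitivity/precision of ``calls`` against ``truth`` at the given
    overlap fraction. Empty truth is an error; empty calls give
    sensitivity 0 and precision 1 by convention (with a warning)."""
    if not truth:
        raise ValueError("truth set is empty")
    if not calls:
        warnings.warn("empty call set: precision defined as 1.0 by convention")
        return BenchmarkResult(0.0, 1.0, len(truth), 0, 0)
    n_matched_truth = _match_any(truth, calls, fraction, reciprocal)
    n_correct_calls = _match_any(calls, truth, fraction, reciprocal)
    return BenchmarkResult(
        sensitivity=n_matched_truth / len(truth),
        precision=n_correct_calls / len(calls),
        n_truth=len(truth),
        n_called=len(calls),
        n_matched=n_matched_truth,
    )


def coverage_fraction_histogram(calls: Sequence, bin_width: float = 0.10) -> list[int]:
    """Histogram of covered fraction (1 - fraction_uncovered) over calls,
    in bins of ``bin_width`` covering [0, 1]; the top bin is closed."""
    n_bins = int(round(1.0 / bin_width))
    counts = [0] * n_bins
    for c in calls:
        covered = 1.0 - c.fraction_uncovered
        idx = min(n_bins - 1, int(covered / bin_width))
        counts[idx] += 1
    return counts


def breakpoint_coverage_correlation(calls: Sequence) -> float:
    """Pearson r between breakpoint-read count (split + discordant) and
    mean coverage across calls; raises on degenerate (zero-variance)
    input."""
    if len(calls) < 2:
        raise ValueError("need >= 2 calls")
    x = np.array([c.n_split + c.n_discordant for c in calls], dtype=float)
    y = np.array([c.mean_coverage for c in calls], dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance on one axis; correlation undefined")
    r, _p = stats.pearsonr(x, y)
    return float(r)
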