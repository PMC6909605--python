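# Methods

## Pipeline overview

ecckit detects extrachromosomal circular DNA (eccDNA) from paired-end
alignments in four stages: candidate extraction, breakpoint-graph
construction, guided probabilistic realignment of soft clips, and circle
calling with hard filters. The model assumes a single-contig circle whose
junction joins a downstream coordinate (the circle end) back to an
upstream one (the circle start); multi-segment circle structure and
interchromosomal junctions are out of scope.

All internal coordinates are 0-based half-open. SAM's 1-based convention
is converted exactly once, at parse time (inside pysam), so BED output and
alignment input cannot drift by one.

## Candidate extraction

A single pass over a name-sorted alignment file keeps three read classes:
discordant pairs, soft-clipped reads, and hard-clipped reads. The
discordance rule is purely positional/orientational: mates aligned in
opposite orientation with the second-in-pair read leftmost. It is applied
to the primary alignments identified by the first/second-in-pair flags
(file order within a name group is arbitrary), without consulting the
aligner's proper-pair flag. Discordant labelling takes precedence: a
clipped member of a discordant pair is emitted once, as discordant (its
clip is still realigned later). Interchromosomal pairs are dropped,
secondary alignments are ignored, and supplementary alignments travel
with their primaries through the SA tag. The minimum clip length to emit
a candidate is 1 nt — uninformative clips are rejected later by the
realignment probability threshold, not at extraction.

Note that the positional rule identifies outward-facing ("reverse read
leftmost") pairs only when read 1 is the fragment's forward-strand read;
on libraries where read 1/read 2 orientation is random relative to the
genome, half of the junction-spanning pairs present the mirrored flag
pattern. Split-read evidence, which calling requires anyway, is
unaffected.

## Insert-size model

μ and σ are the sample mean and standard deviation (ddof = 1) of absolute
template lengths over up to 100,000 aligner-flagged proper pairs with no
clipped bases, each pair counted once through its positive-TLEN member. A
dataset with fewer than two usable pairs is an error.

## Breakpoint graph

Candidates sorted by coordinate are clustered by single linkage with gap
threshold K = 500 nt (default; `--cluster-distance`). K exceeds the
default insert spread (μ + 5σ ≈ 425 nt at 300 ± 25), so the mates of one
junction co-cluster, while unrelated loci separated by more than K do
not chain together on a circle-enriched library where coverage between
circles is sparse.

Per cluster, nodes are the maximal merged alignment spans of the members
(half-open merging, zero-gap adjacency allowed, for determinism). Every
member contributes an edge from its node to the node containing its
discordant mate or supplementary placement, creating the target node when
the position falls outside all existing nodes. Support accumulates per
node pair.

Edge weights normalise per-placement contributions over all edges of the
graph. The default contribution is 1 − 10^(−Q/10) — the probability that
a placement with mapping quality Q is correct — so that edges supported
only by unreliable placements get low weight and are pruned (threshold
0.01, no renormalisation afterwards). The alternative mode
(`--weight-as-printed`) uses 10^(−Q/10) itself; it is retained because the
complement form is this package's own reading of the pruning rationale
(low-weight edges should be the *unlikely* ones), and the two modes are
otherwise identical. With the uniform high mapping qualities of clean
simulations the choice is immaterial.

Node intervals are extended symmetrically by μ + 5σ before realignment,
clamped to the contig, so that nodes seeded only by discordant reads —
whose alignment spans stop one insert short of the junction — still
contain the breakpoint. The extension multiplier is `--extension-sigmas`.

## Probabilistic realignment

For each soft-clipped candidate, the search space is the union of the
extended intervals of the nodes connected by an edge to the node holding
the anchor. Overlapping intervals are merged into disjoint regions first:
nodes created independently for nearby mate placements can overlap, and
enumerating the same genomic placement twice would split the probability
mass of a unique hit below any acceptance threshold.

Placements are enumerated per region with edlib's infix (semi-global)
Myers bit-vector alignment: the best placement is recorded, its reference
footprint masked, and the search repeated until n_hits = 10 placements are
collected or the best remaining edit distance exceeds
ceil(0.05 × clip length). Each placement is scored by the PSSM log-odds
model: per aligned column log2((1−p_e)/q(g)) on match and
log2((p_e/3)/q(g)) on mismatch, where p_e = 10^(−q/10) from the base
quality, clamped to (1e−5, 0.75) — an unclamped phred-0 base would make
match and mismatch scores cross. Only the clipped bases are scored; the
anchor is treated as fixed. The background q(g) is the base composition
of the graph's merged extended intervals, floored at 0.01 and renormalised
to avoid log blow-ups on skewed composition.

Indels subtract an affine gap cost p + (a−1)·e bits for a gap of length a,
with defaults p = 5, e = 1 bits: one 1-nt gap costs about 2.5 high-quality
matches, so a short gap is accepted only when supported by several extra
matching bases. Scores convert to probabilities by a max-shifted base-2
softmax over the enumerated candidate set (a tractable stand-in for "all
possible alignments"; n_hits is configurable). The top placement (ties
broken by leftmost reference offset) is accepted iff its probability
exceeds 0.99 and its edit distance is ≤ 0.05 × clip length. Two equally
good loci therefore always reject (probability 0.5), which is the
designed behaviour for ambiguous clips; in unique sequence context clips
of 5 nt realign with probability ~1.

## Circle calling

An accepted right-side clip placed left of its anchor (or left-side clip
placed right) is a circular junction (start = placement start resp.
anchor start, end = anchor end resp. placement end); outward placements
are deletion-type signals and are not emitted. Junctions are grouped at
exact nucleotide resolution — no fuzzy clustering — and a discordant pair
attaches to the smallest junction whose interval, extended by μ + 5σ,
contains the pair's outer span.

Hard filters, in order: MAPQ < 20 removes discordant pairs (either mate)
and split-read primary alignments before graph construction (low-MAPQ
*secondary* split alignments are instead routed through realignment);
support requires ≥ 2 breakpoint reads including ≥ 1 split; allele
frequency — split reads divided by the mean depth at the two junction
nucleotides (start and end−1, the minimal literal reading of "breakpoint
nucleotides") — must exceed 0.1, with a zero-depth denominator treated as
keep since positive evidence exists; the allele-frequency filter runs
before interval merging. Finally, calls overlapping reciprocally by
≥ 0.99 merge transitively into their union span with summed support.

Output metrics per call: circle score Σ(clip length × realignment
probability) over supporting splits; mean and population standard
deviation of per-base depth inside the call; fraction of uncovered bases;
and boundary coverage-increase ratios (reads starting in the first 100 nt
inside the start over reads starting in that window extended 200 nt
upstream, and symmetrically with read ends at the circle end; empty
denominators report 1.0). Coverage counts primary, non-duplicate
alignments only, which avoids double-counting split reads through their
supplementary records.

## Simulator

The simulator emulates a Circle-Seq library: linear DNA is assumed fully
removed, so all fragments originate on circles. A reference (the bundled
generator writes i.i.d. random genomes at a chosen GC) is first mutated —
i.i.d. substitutions at 0.001/base and indels at 0.0001/base with
geometric(0.7) lengths capped at 10 — to model genetic variation absent
from the alignment reference; a coordinate map carries truth coordinates
back to the original reference across indel shifts. Circles are sampled
with lengths uniform on [150, 10,000] nt and uniform starts; read pairs
per circle follow the requested mean coverage (or a global read count
split proportionally to circle length).

Fragments are sampled on the rotated circular sequence with insert
lengths N(300, 25) truncated to [read length, circle length], which
produces all three read classes from one model: a read overlapping the
junction becomes a split read, a fragment whose insert spans the junction
without either read crossing it becomes a discordant pair, everything
else is concordant. Sequencing errors are uniform per base (default
0.001 ≈ phred 30, constant qualities). Read 1 is the fragment's
forward-strand read — under this convention junction-spanning pairs carry
exactly the discordant orientation signature the extractor tests, which
is what makes the extraction-recall property checkable; real libraries
randomise read order, a feature the generator deliberately does not
model (see candidate extraction above).

Besides FASTQ and the truth BED, the simulator can emit a truth SAM with
each read's correct linear placement: soft-clipped CIGARs for split reads
and, for clips ≥ 20 nt, a supplementary alignment with reciprocal SA tags,
mirroring how BWA-MEM reports long split alignments. The truth SAM lets
the entire caller, including graph construction from supplementary
placements, run and be tested without any external aligner. What passing
on this data does *not* show: robustness to mapping error, repeats,
quality-by-cycle error profiles, PCR duplicates, or rolling-circle
chimeras — none of which the generator emulates. Benchmarking against an
external aligner over the FASTQ output is the supported path for those
questions.

## Problem sizes and numerical choices

The package's benchmark replicates (tests and `scripts/acceptance.py`)
use a 5-Mb single-contig synthetic genome with 300 circles (150–10,000 nt)
at 30X and 7.5X, and 250 short circles (150–350 nt) at 30X — a
scaled-down replicate of the published whole-genome design that keeps the
per-circle read sampling identical while remaining desk-scale. Sensitivity
and precision are evaluated at 0.95 overlap, applied reciprocally (a
one-way mode exists for the literal one-directional reading); matching is
greedy many-to-one. Note the benchmark definitions used here are the
standard ones — sensitivity over truth, precision over calls.

Degenerate cases are defined explicitly: an all-MAPQ-0 graph in
correct-mapping mode has zero total contribution and is flagged rather
than divided through; empty call sets evaluate to precision 1.0 with a
warning; empty truth is an error; probability normalisation is asserted
to 1e−9 throughout.

## Known limitations

- Junction grouping is exact; two split reads whose placements disagree by
  1 nt (possible with indel-bearing clips) form separate junctions and
  must each find their own support.
- The discordance rule is orientation-literal (see above) and will both
  miss mirrored junction pairs and admit mirrored concordant pairs on
  random-orientation libraries; downstream filters absorb the noise but
  discordant read counts should be read as approximate on real data.
- Circles shorter than the read length are handled (both anchors ≥ 1 nt)
  but a read wrapping more than once is placed by its first wrap only.
- No CRAM input, no multi-sample output, no genotype likelihoods, no
  reconstruction of internal circle structure.
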