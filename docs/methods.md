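# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the package. Nothing here reports an empirical
number that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate conventions

All internal coordinates are 0-based, half-open, on the forward strand.
GFF3 and the calls/truth TSVs use 1-based inclusive coordinates; BED
stays 0-based half-open. A backsplice junction is stored *normalized*:
`acceptor` = leftmost circle base, `donor` = rightmost, regardless of
strand; for minus-strand circles the biological acceptor/donor roles are
therefore swapped relative to the field names, and the strand field
carries the orientation. This single convention eliminates off-by-one
drift between stages; conversions exist only at file boundaries.

## Detection model

**Anchors.** Candidate selection uses exact (zero-mismatch) matching of
the read's two terminal 20-mers against both genome strands, with
uniqueness counted over both strands combined. "Perfect and unique" is
read literally: an anchor with any second hit (including its own reverse
complement elsewhere, or a palindromic self-hit) disqualifies the read.
This is the conservative reading — stricter anchoring can only lower the
false-discovery rate, at a small sensitivity cost on repetitive genomes.

**Chiastic geometry.** On '+', the head (5') anchor must start strictly
downstream of the tail anchor; mirrored on '-'. The 15-kb window is
measured as the *footprint* of both anchor windows (leftmost window start
to rightmost window end). Footprint vs start-to-start differs by at most
one anchor length (20 bp) and the footprint bounds the genomic content
the pseudo-genome must cover, which is the quantity that matters.

**Colinear prefilter.** A read is "fully mapped" (and excluded from the
circRNA search) when some single ungapped placement seeded by either
anchor covers it at >= `min_identity` (default 0.95) leaving fewer than
20 unaligned bases at each end. The prefilter is an efficiency/safety
stage; `use_prefilter=False` (CLI `--no-prefilter`) runs the chiastic
test on everything. On all synthetic libraries tested the two paths
accept identical candidate sets, because a colinearly-explicable read
cannot also have unique chiastic anchors.

**Pseudo-genome.** Block D = 5.1 kb starting at the head-anchor start;
block U = 5.1 kb ending at the tail-anchor end; concatenated D then U
(downstream first), mirrored on the reverse complement for '-'
candidates. Blocks truncate at chromosome edges and are never padded, so
interior candidates always yield exactly 10,200 bases. The block
descriptors are invertible; coordinate round-trips are exercised by
property tests. The 5.1-kb flank is justified by the intron/gene size
distribution the generator mirrors (effectively all introns < 5 kb), so
a junction side can never fall outside its block given the 15-kb window.

**Spliced aligner.** A deliberate re-implementation of cDNA-to-genome
splicing for this restricted geometry rather than a wrapper around a
general-purpose aligner: the read is split into a 5' segment aligned
ungapped from the start of block D and a 3' segment aligned ungapped to
the end of block U; every split point between the two anchors is scored
(prefix/suffix match arrays, O(read length)); substitutions only, no
indels. Acceptance requires `matches / read_length >= min_identity`
(default 0.95; the published pipeline states no identity threshold for
this step, so one conservative knob is exposed). Tie-breaking among
equal-score splits — which occur exactly when the junction has sequence
homology — prefers a split whose genomic junction carries GT..AG, then
the leftmost split in read coordinates. The chosen split provably attains
the exhaustive all-splits maximum (tested against an independent
brute-force scorer). Reads whose terminal segments each lie inside one
exon — the designed-read geometry — are fully covered; internal
(non-backsplice) introns *within* a segment are not modelled, a logged
limitation that does not affect the benchmark design.

**Splice signal.** A spliceosomal backsplice removes the intron
downstream of the sense donor and upstream of the sense acceptor, so on
'+' the genome must read `AG | circle | GT`, and on '-' the same sense
signal appears as `AC | circle | CT` on the forward strand. Junctions
whose two-base flanks run off the chromosome fail the check. The
published rule names the signal but not the coordinate arithmetic; this
reading makes designed exon-boundary junctions pass by construction,
which is the only self-consistent interpretation.

**Mate filter.** The mate is probed with the same anchor-seed machinery.
Drop iff the mate's best *unique* placement (a full colinear placement,
or unique terminal-anchor evidence) lies even partly outside
`[acceptor, donor]` or on another chromosome; keep when the mate is
unmapped, ambiguous, or consistent with the circle — including mates
that themselves cross the backsplice or span an internal intron of the
circle. Unmapped mates are kept because the published rule drops only
mates that map outside.

**Support.** "Independent reads" are distinct read identifiers
(mate-suffixed); both mates of a pair can each span the junction and then
count separately. Optional collapsing of the two mates of one fragment
(`dedup_fragments`) is off by default since the source method mentions no
deduplication. Calls need `min_support >= 2` by default. IDs follow
`<prefix><chrom:02d>circ<serial:05d>`, serial in coordinate order per
chromosome.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *structural* features the pipeline depends
on: multi-chromosome uniform-composition genomes; non-overlapping
multi-exon genes on both strands (default 30 genes of 2-15 exons of
80-400 bp, introns 60-1,000 bp — far below the 5-kb flank bound); every
intron rewritten to canonical GT..AG on its transcript's strand; a
CDS/5'UTR/3'UTR partition (UTRs up to 200 nt) and a 10% ncRNA fraction;
stranded 2x100 bp pairs with fragment length 300 +/- 50, substitution-only
errors, configurable strand-orientation accuracy (real libraries: 92.7% -
98.3%; default 1.0) and a configurable circular fraction (default 0.05 of
molecules — a deliberate over-expression of circles relative to real
tissue so that junction-spanning coverage is attainable at desk-scale
read counts).

Designed backsplice reads follow the published recipe — 20-80 bp
terminal segments of two different exons of one transcript,
reverse-assembled head-to-tail — with two reads per designed site by
default (the source does not state its read count per site; with fewer
than two, the >= 2-support filter would zero out sensitivity by
construction, so the count is an explicit parameter). Designed sites are
restricted to *intron-flanked* exon boundaries (exon indices 1..n-2), so
every designed junction satisfies the GT..AG rule by construction and any
benchmark miss is attributable to anchor non-uniqueness or segment-length
edge cases, each of which is reason-coded in the rejection log. Mates are
synthesized inside the circle span by default (making the mate filter
neutral, as the benchmark intends); `mate_mode="random"` places them
randomly to exercise the filter, which demonstrably collapses
sensitivity.

What the generator does **not** emulate: sequence repeats and
paralogy (anchors are almost always unique on a random genome, so the
benchmark's near-perfect sensitivity is an upper bound relative to real
genomes with repeat families); indels and quality-score structure;
library-chemistry effects (poly(A) selection/depletion, RNase R);
expression-level realism beyond a uniform mixture. Passing tests
therefore validate the *algorithmic* correctness of the pipeline and its
filters, not its end-to-end yield on real tissue data.

Determinism: every generator consumes a `numpy` Generator derived from
`rng_seed`; identical configurations produce byte-identical FASTQ and
truth sets, and the evaluation harness derives per-data-set seeds from
the master seed.

## Evaluation conventions

Sensitivity = recovered designed sites / designed sites; FDR = calls
matching no designed site / total calls, with FDR defined as 0 when no
calls are made (stable reporting instead of NaN). Matching is one-to-one
and greedy with `junction_slack` tolerance per endpoint; the default
slack is 0 because designed junctions sit at exact exon boundaries. FDR
is counted at junction level (each unique called junction is one trial),
not read level.

The benchmark experiment is run at 2 chromosomes x 2 Mb, ~300 genes,
five data sets of 1,500 designed sites — large enough that anchor
uniqueness, junction-space saturation and tie-break behaviour are all
exercised, while a full run (generation, indexing, five pipeline passes)
completes in seconds on one CPU.

## Target-mimic geometry

The pairing rules are implemented as: perfect Watson-Crick pairing at
miRNA positions 2-8 (the seed); exactly one 3-nt bulge on the circRNA
side, inserted between adjacent miRNA positions p/p+1 with p in {9, 10,
11} (i.e. the bulge sits opposite the 9th-12th positions — the
established target-mimic geometry, with the source's "at the 5'"
fragment of the bulge rule absorbed into the seed requirement); no other
gap; weighted mismatches over all remaining paired positions (1 and
9..end) at most 3.0, with G:U counted 0.5. The scan wraps across the
backsplice by default (`wrap=False` disables). At most one site is
emitted per circle offset — the bulge placement with the fewest weighted
mismatches, smallest p on ties — so a single physical site is not
reported once per admissible bulge placement.

Flank analyses: inverted repeats are *exact* reverse-complement matches
(no wobble) of >= 18 bp between the 500-bp flanks, reported as maximal
matches; the MITE screen requires both 500-bp flanks to overlap an
element by >= 1 bp, using the same windows as the complement search.
Flanks are taken from genomic sequence regardless of annotation.

## Known limitations

* No indel handling anywhere (anchors, aligner, mate probing); the
  method is exact-match seeded by design.
* Alternative *splicing* circularization (the internal exon structure of
  a circle) is not inferable from junction-spanning short reads and is
  out of scope; only alternative *backsplicing* (distinct junctions per
  parental gene) is reported.
* Expression quantification, RNase R enrichment modelling and cross-
  species reanalysis are out of scope.
* `classify` picks a single best-matching transcript (most endpoints
  explained, then overlap length, then ID — deterministic); loci with
  dense overlapping isoforms may be sensitive to this tie-break.
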