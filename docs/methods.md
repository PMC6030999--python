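# Methods

## Evidence model

`svcurate` treats every read pair and split read near a candidate SV as an
observation that supports exactly one event class. The model assumes an
Illumina-style forward–reverse paired library: a concordant pair maps
`(+,-)` in genomic order with an outer span (rightmost mapped end minus
leftmost mapped start) near the library insert size. Deviations are
classified deterministically:

| orientation (genomic order) | span condition        | class        |
|-----------------------------|-----------------------|--------------|
| `(+,-)`                     | span ≤ mean + Z·sd    | NORMAL       |
| `(+,-)`                     | span > mean + Z·sd    | DELETION     |
| `(-,+)` (everted)           | any                   | DUPLICATION  |
| `(+,+)`                     | any                   | INVERSION_FF |
| `(-,-)`                     | any                   | INVERSION_RR |

The classification is total (every strand/span combination maps to one
class) and monotone (growing the span of a `(+,-)` pair never demotes a
DELETION back to NORMAL).

**Outer span, not TLEN.** The insert size used everywhere is the outer
distance between mapped ends, recomputed from both mates' coordinates
rather than read from the SAM template-length field. This keeps pair and
split observations on a single y-axis and is robust to aligner-specific
TLEN conventions.

**Insert statistics.** The mean and *population* standard deviation of the
outer span are estimated from the first 10,000 properly-paired, primary,
non-duplicate `(+,-)` pairs in the file — cheap, reproducible, and
sufficient for a threshold used only at Z = 4 (default). Z = 4 makes the
false-discordant tail of a well-behaved library ≈ `P(|N(0,1)| > 4)/2 ≈
3×10⁻⁵` per pair, so a reference sample shows essentially no spurious
deletion-colored pairs.

**Split reads.** A split read's aligned segments (its own plus those in the
standard `SA:Z:` supplementary tag) are ordered by their offset within the
read, derived from the soft/hard-clip structure of each segment's CIGAR
(strand-aware: a reverse-strand alignment's leading clip sits at the read's
3′ end). Adjacent segments in read order form one observation; the same
read seen from its primary and its supplementary record is emitted once.
Classification: opposite segment strands support an inversion (FF when the
genomically-left segment is forward, RR otherwise); same-strand segments
whose order is flipped *relative to the read's direction of travel across
the genome* support a tandem duplication; order-preserving same-strand
segments support a deletion. The direction-of-travel qualification matters:
a reverse-strand read walks the genome right-to-left, so its natural
segment order is genomically descending, and ignoring this would
misclassify every reverse-strand deletion split as a duplication.

**Filters.** Unmapped, secondary, duplicate and QC-fail records are ignored
everywhere; supplementary records are used only for split detection (never
for pairs or coverage, avoiding double counting). Inter-chromosomal mates
and splits are excluded — translocation rendering is out of scope.

**Coverage** counts aligned bases of primary, non-duplicate reads per
reference position (soft-clipped bases and deletion gaps inside a read's
reference span do not count), via `pysam.count_coverage` with the flag
filter above.

**Downsampling.** Concordant pairs carry little information per glyph, so
each sample keeps at most `max_normals` (default 100) NORMAL pairs per
window — a seeded uniform sample without replacement that preserves input
order. All discordant pairs are always kept. The cap is per window; a
global cap would make one window's density depend on another's.

## Coordinates and identifiers

All internal coordinates are 0-based half-open; VCF input is converted on
read (`POS−1` → start, `INFO/END` → end) and back on write. A record with a
VCF ID keeps it as its image id; otherwise the id is
`chrom_start_end_svtype`. The same derivation runs at plot time and at VCF
annotation time, so scores always rejoin their records.

## Rendering

One figure per SV: a locator bar spanning the call, one panel per sample in
the given order (sample of interest first), and a gene/annotation panel
when annotations intersect the window. The window pads the call by
`max(min_pad, pad_fraction × length)` — defaults 1,000 bp and 0.5, chosen
so flanking concordant coverage is always visible for context. Pairs are
solid lines with square endpoints, splits dashed lines with circle
endpoints, both at y = outer span and colored by class (grey-black NORMAL,
black DELETION, red DUPLICATION, blue `(+,+)` and green `(-,-)` inversion —
the blue/green assignment is arbitrary but fixed). The span axis is linear
up to the 98th percentile of the panel's spans with larger spans clamped to
the axis top, so a handful of extreme pairs cannot flatten the rest.
Coverage uses an independent right axis scaled to the sample's own maximum.
Glyph alpha decreases with panel glyph count so that density reads as color
intensity; this is an aesthetic choice with no analytical role. Rendering
never mutates its inputs, and batch rendering derives each SV's
downsampling seed from the SV id (CRC32-mixed), making output independent
of worker count and scheduling.

GFF3 (1-based inclusive) and BED (0-based half-open) annotation files are
parsed by a small column reader (plain or gzip); `gene`/`exon` GFF3
features keep their kind, everything else is a generic region.

## Curation scoring

A project is a single JSON file holding the config, the image list (from
the plot manifest) and an append-only response log. Local single-file
persistence replaces any hosted store: project isolation is the filesystem,
and authentication is out of scope. A reviewer may re-score an image; the
latest response per (image, reviewer) wins.

Scores map answers to numbers and aggregate with mean, median, mode,
population sd, min or max. Mode ties break toward the larger mapped value
(a tie between "event" and "no event" readings is resolved in favor of
flagging the event for review). Score classes (UNANIMOUS_*, UNAMBIGUOUS_*,
AMBIGUOUS, with the 0.2/0.8 cutoffs inclusive on the ambiguous side) are
defined only for 0/1 value maps aggregated by mean; any other mapping
reports a bare score.

VCF annotation is line-level text editing: one `##INFO=<ID=SVP,Number=1,
Type=Float,...>` header line and `SVP=<score>` (4 decimals) appended to
scored records' INFO. Nothing else in the file is touched, so
annotate-then-strip is the byte identity — a property the tests assert.

Concordance analysis restricts to unambiguous scores: a low score agrees
with a homozygous-reference genotype or a copy number in the copy-neutral
band (1.4, 2.4]; a high score agrees with a non-reference genotype or a
copy number below 1.4. Copy number above the band at a low score is counted
as disagreement (it suggests a duplication signal the deletion-oriented
analysis does not model); missing calls leave the denominator.

## Synthetic data

The generator emulates the alignment *signatures* of SVs without sequence:
the alternate haplotype is modeled as an ordered list of reference blocks
(deletion removes a block, tandem duplication repeats one, inversion
reverse-strands one), fragments are placed uniformly on the alternate
genome with truncated-normal lengths, and read coordinates are mapped back
to the reference block-by-block. Reference-contiguous same-strand segments
are re-fused (the trailing junction of a tandem duplication maps back
contiguously and is one alignment to a real aligner). A read crossing a
breakpoint becomes a primary + supplementary split pair with reciprocal
`SA` tags at rate `split_read_fraction` (default 0.5), otherwise its longer
segment is emitted soft-clipped; segments under 20 aligned bases are
dropped, as an aligner would. Each sample is two haplotypes at half depth;
het places the SV on one.

Defaults: 100 bp reads, 400 ± 50 bp outer spans (a typical short-read
library), 30× depth, one contig (`chrS`, 100 kb by default; the cohort
generator uses 15 kb contigs, one per SV, which comfortably hold a 2 kb
event plus its padded window). SAM records carry constant sequence/quality,
`MC`/`NM`/`RG` tags and aligner-style proper-pair flags; files are
coordinate-sorted in memory and indexed, making output byte-identical for a
fixed seed. The generator also books its own truth: the discordant pairs
and split records it actually emitted per sample, plus the expected
coverage ratio over the SV (DEL het 0.5, DEL hom 0, DUP het 1.5, INV 1).

What the generator does **not** model: sequencing errors, GC and coverage
bias, mappability artifacts, repeat-mediated false signals, or
micro-homology at breakpoints. Passing tests therefore demonstrate that the
extraction/classification/scoring machinery is correct on clean signals,
not that curation of noisy real-genome images would reach the same
accuracy.

Simulated reviewers answer with the true label with probability
1 − error_rate, else a uniform wrong label, independently per (reviewer,
image), deterministic per seed. With 9 reviewers at error rate e, the
expected unanimous fraction for binary answers is `(1−e)⁹ + e⁹` and the
at-most-one-dissent fraction `(1−e)⁹ + 9e(1−e)⁸ + (sym.)` ≈ 0.93 at
e = 0.05 — the end-to-end test asserts ≥ 0.80 to leave sampling slack at
30 images.

## Problem sizes

The test suite and acceptance script run everything at desk scale by
design: 10–15 kb contigs, 20–30× depth, 30-SV cohorts, 20-seed recovery
sweeps. These sizes give per-window evidence counts (tens of discordant
pairs, thousands of concordant pairs per sample) in the same regime as a
real 30× genome window, which is what the extraction and downsampling code
actually sees.

## Known limitations

* Breakend (BND)/translocation evidence and long-read alignments are not
  rendered.
* CRAM requires the reference to be resolvable by pysam; there is no
  auto-fetch.
* Score classes are undefined for non-0/1 mappings by construction.
* The pair extractor needs either `MC` tags or an intact index to find a
  mate's end; a pair whose mate record is missing from the file is skipped
  with a warning.
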