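"""Alignment evidence for structural-variant windows.

Extracts paired-end and split-read observations plus per-base coverage from
coordinate-sorted, indexed BAM/CRAM files, classifies every observation by
the SV type its geometry supports, and downsamples concordant ("normal")
pairs so that large events stay cheap to draw.

Classification follows standard discordant-pair conventions for Illumina
forward-reverse libraries.  With mates stored in genomic order:

==============  =======================================  ==============
orientation     span condition                           class
==============  =======================================  ==============
(+, -)          span <= mean + z * sd                    NORMAL
(+, -)          span >  mean + z * sd                    DELETION
(-, +)          any (everted pair)                       DUPLICATION
(+, +)          any                                      INVERSION_FF
(-, -)          any                                      INVERSION_RR
==============  =======================================  ==============

"Span" is always the outer distance (rightmost mapped end minus leftmost
mapped start), never the SAM template-length field, so paired-end and
split-read observations share one y-axis when plotted.

Split reads (primary + supplementary segments linked by ``SA`` tags) use an
analogous rule: opposite segment strands support an inversion; same-strand
segments whose read order is flipped relative to genomic order support a
tandem duplication; same-strand, order-preserving segments support a
deletion.
"""

from __future__ import annotations

import logging
import math
import os
import random
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .errors import DegenerateInputError, FormatError

logger = logging.getLogger(__name__)

SV_TYPES = ("DEL", "DUP", "INV", "INS")

DEFAULT_Z = 4.0
DEFAULT_MAX_NORMALS = 100
DEFAULT_MAX_SAMPLED = 10_000


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class EvidenceClass(Enum):
    """SV type supported by a single pair/split observation."""

    NORMAL = "NORMAL"
    DELETION = "DELETION"
    DUPLICATION = "DUPLICATION"
    INVERSION_FF = "INVERSION_FF"
    INVERSION_RR = "INVERSION_RR"

    @property
    def color(self) -> str:
        return _CLASS_COLORS[self]


#: display colors: grey-black for concordant pairs, black for deletion,
#: red for duplication, blue/green for the two inversion orientations.
_CLASS_COLORS = {
    EvidenceClass.NORMAL: "#5a5a5a",
    EvidenceClass.DELETION: "#000000",
    EvidenceClass.DUPLICATION: "#d62728",
    EvidenceClass.INVERSION_FF: "#1f77b4",
    EvidenceClass.INVERSION_RR: "#2ca02c",
}


@dataclass(frozen=True)
class SVCall:
    """One candidate structural variant (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    svtype: str
    id: str = ""

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("SVCall.chrom must be non-empty")
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SVTYPE {self.svtype!r}")
        if self.svtype == "INS":
            if self.end < self.start:
                raise ValueError("INS requires end >= start")
        elif self.start >= self.end:
            raise ValueError("start must be < end for DEL/DUP/INV")
        if not self.id:
            object.__setattr__(self, "id", synthesize_sv_id(
                self.chrom, self.start, self.end, self.svtype))

    @property
    def length(self) -> int:
        return self.end - self.start


def synthesize_sv_id(chrom: str, start: int, end: int, svtype: str) -> str:
    """Stable identifier for a call lacking a VCF ID."""
    return f"{chrom}_{start}_{end}_{svtype}"


@dataclass(frozen=True)
class GenomicWindow:
    """0-based half-open region of one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid window {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return start < self.end and end > self.start


@dataclass(frozen=True)
class InsertStats:
    """Outer-span distribution of concordant pairs, plus the Z threshold.

    A (+,-) pair is "normal" when its outer span is within ``z`` standard
    deviations of the mean; the default Z is 4.
    """

    mean: float
    sd: float
    z: float = DEFAULT_Z
    n: int = 1

    def __post_init__(self):
        if self.sd < 0 or self.z <= 0 or self.n < 1:
            raise ValueError("invalid InsertStats")

    @property
    def upper(self) -> float:
        """Largest span still considered concordant."""
        return self.mean + self.z * self.sd


@dataclass(frozen=True)
class PairEvidence:
    """One read pair, mates stored in genomic order."""

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    left_strand: str
    right_strand: str
    span: int
    evclass: EvidenceClass | None = None

    @classmethod
    def from_mates(cls, a_start, a_end, a_strand, b_start, b_end, b_strand,
                   evclass=None) -> "PairEvidence":
        """Build from two mates in arbitrary order; span is the outer distance."""
        if (a_start, a_end) > (b_start, b_end):
            a_start, a_end, a_strand, b_start, b_end, b_strand = \
                b_start, b_end, b_strand, a_start, a_end, a_strand
        return cls(a_start, a_end, b_start, b_end, a_strand, b_strand,
                   span=max(a_end, b_end) - a_start, evclass=evclass)


@dataclass(frozen=True)
class SplitEvidence:
    """Two adjacent aligned segments of one split read, in genomic order.

    ``read_order_flipped`` is true when, walking along the read in its
    direction of travel across the genome, the genomically-left segment
    comes later than the genomically-right one (for forward-strand
    segments: the left segment is later in the read; for reverse-strand
    segments the read walks right-to-left, so the test inverts).  A flipped
    same-strand split is the signature of a tandem-duplication junction.
    """

    seg1_start: int
    seg1_end: int
    seg2_start: int
    seg2_end: int
    seg1_strand: str
    seg2_strand: str
    read_order_flipped: bool
    span: int
    evclass: EvidenceClass | None = None


@dataclass(frozen=True)
class CoverageTrack:
    """Per-base aligned read depth over a window."""

    window: GenomicWindow
    depth: np.ndarray

    def __post_init__(self):
        if len(self.depth) != len(self.window):
            raise ValueError("depth length does not match window")

    @property
    def max_depth(self) -> int:
        return int(self.depth.max(initial=0))


@dataclass
class SampleTracks:
    """All plotted evidence for one sample in one window."""

    sample_name: str
    window: GenomicWindow
    pairs: list[PairEvidence]
    splits: list[SplitEvidence]
    coverage: CoverageTrack
    insert_stats: InsertStats


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_pair(pair: PairEvidence, stats: InsertStats) -> EvidenceClass:
    """Classify a read pair by orientation first, then span threshold.

    Total and deterministic: every (strand pair, span) maps to exactly one
    class.
    """
    key = (pair.left_strand, pair.right_strand)
    if key == ("+", "-"):
        return EvidenceClass.DELETION if pair.span > stats.upper else EvidenceClass.NORMAL
    if key == ("-", "+"):
        return EvidenceClass.DUPLICATION
    if key == ("+", "+"):
        return EvidenceClass.INVERSION_FF
    if key == ("-", "-"):
        return EvidenceClass.INVERSION_RR
    raise ValueError(f"bad strand pair {key}")


def classify_split(split: SplitEvidence) -> EvidenceClass:
    """Classify a split-read segment pair (both segments on one chromosome)."""
    if split.seg1_strand != split.seg2_strand:
        return (EvidenceClass.INVERSION_FF if split.seg1_strand == "+"
                else EvidenceClass.INVERSION_RR)
    if split.read_order_flipped:
        return EvidenceClass.DUPLICATION
    return EvidenceClass.DELETION


# ---------------------------------------------------------------------------
# alignment-file access helpers
# ---------------------------------------------------------------------------

def _open_alignments(source) -> tuple[pysam.AlignmentFile, bool]:
    if isinstance(source, pysam.AlignmentFile):
        return source, False
    return pysam.AlignmentFile(str(source)), True


def _is_primary(rec: pysam.AlignedSegment) -> bool:
    return not (rec.is_unmapped or rec.is_secondary or rec.is_supplementary
                or rec.is_duplicate or rec.is_qcfail)


def _strand(rec: pysam.AlignedSegment) -> str:
    return "-" if rec.is_reverse else "+"


_CIG_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIG_RE.findall(cigar)]
    if not ops or "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise FormatError(f"malformed CIGAR {cigar!r}")
    return ops


def _cigar_ref_len(ops: Sequence[tuple[int, str]]) -> int:
    return sum(n for n, op in ops if op in "MDN=X")


def _cigar_clips(ops: Sequence[tuple[int, str]]) -> tuple[int, int]:
    """(leading, trailing) clipped bases in SAM (reference) orientation."""
    lead = trail = 0
    for n, op in ops:
        if op in "SH":
            lead += n
        else:
            break
    for n, op in reversed(ops):
        if op in "SH":
            trail += n
        else:
            break
    return lead, trail


@dataclass(frozen=True)
class _Segment:
    """One aligned segment of a (possibly split) read."""

    rname: str
    start: int
    end: int
    strand: str
    read_offset: int  # offset of the segment's first aligned base in the read


def _segment_from_cigar(rname: str, pos0: int, strand: str, cigar: str) -> _Segment:
    ops = _parse_cigar(cigar)
    lead, trail = _cigar_clips(ops)
    # in SAM, a reverse-strand CIGAR starts at the read's 3' end
    offset = trail if strand == "-" else lead
    return _Segment(rname, pos0, pos0 + _cigar_ref_len(ops), strand, offset)


def _segment_from_record(rec: pysam.AlignedSegment) -> _Segment:
    return _segment_from_cigar(rec.reference_name, rec.reference_start,
                               _strand(rec), rec.cigarstring)


def _parse_sa_tag(sa: str) -> list[_Segment]:
    """Parse ``SA:Z:rname,pos,strand,CIGAR,mapQ,NM;...`` (pos is 1-based)."""
    segs = []
    for entry in sa.rstrip(";").split(";"):
        if not entry:
            continue
        parts = entry.split(",")
        if len(parts) != 6 or parts[2] not in "+-":
            raise FormatError(f"malformed SA entry {entry!r}")
        rname, pos, strand, cigar = parts[0], int(parts[1]) - 1, parts[2], parts[3]
        segs.append(_segment_from_cigar(rname, pos, strand, cigar))
    return segs


# ---------------------------------------------------------------------------
# insert-size statistics
# ---------------------------------------------------------------------------

def estimate_insert_stats(source, max_sampled: int = DEFAULT_MAX_SAMPLED,
                          z: float = DEFAULT_Z) -> InsertStats:
    """Estimate the concordant-pair outer-span distribution.

    Scans records from the start of the file and uses the first
    ``max_sampled`` properly-paired, primary, non-duplicate pairs in (+,-)
    orientation.  The span of a pair is its outer distance; the standard
    deviation is the population sd.

    Raises
    ------
    DegenerateInputError
        If no qualifying pair exists.
    """
    if max_sampled < 1:
        raise ValueError("max_sampled must be >= 1")
    af, own = _open_alignments(source)
    spans: list[int] = []
    pending: dict[str, tuple[int, int, bool]] = {}
    try:
        for rec in af.fetch(until_eof=True):
            if len(spans) >= max_sampled:
                break
            if not (_is_primary(rec) and rec.is_proper_pair and rec.is_paired):
                continue
            if rec.mate_is_unmapped or rec.reference_id != rec.next_reference_id:
                continue
            qname = rec.query_name
            if qname in pending:
                o_start, o_end, o_rev = pending.pop(qname)
                s0, e0 = min(rec.reference_start, o_start), max(rec.reference_end, o_end)
                left_rev = o_rev if o_start <= rec.reference_start else rec.is_reverse
                right_rev = rec.is_reverse if o_start <= rec.reference_start else o_rev
                if not left_rev and right_rev:  # (+,-) in genomic order
                    spans.append(e0 - s0)
            else:
                pending[qname] = (rec.reference_start, rec.reference_end, rec.is_reverse)
    finally:
        if own:
            af.close()
    if not spans:
        raise DegenerateInputError("no qualifying concordant pairs to estimate insert size")
    arr = np.asarray(spans, dtype=float)
    return InsertStats(mean=float(arr.mean()), sd=float(arr.std(ddof=0)),
                       z=z, n=len(spans))


# ---------------------------------------------------------------------------
# evidence extraction
# ---------------------------------------------------------------------------

def _mate_segment(af: pysam.AlignmentFile, rec: pysam.AlignedSegment) -> _Segment | None:
    """Locate the mate's primary alignment (MC-tag fast path, else index fetch)."""
    rname = af.get_reference_name(rec.next_reference_id)
    pos = rec.next_reference_start
    strand = "-" if rec.mate_is_reverse else "+"
    if rec.has_tag("MC"):
        return _segment_from_cigar(rname, pos, strand, rec.get_tag("MC"))
    for cand in af.fetch(rname, pos, pos + 1):
        if (cand.query_name == rec.query_name and _is_primary(cand)
                and cand.is_read1 != rec.is_read1 and cand.reference_start == pos):
            return _segment_from_record(cand)
    return None


def extract_pair_evidence(source, window: GenomicWindow,
                          stats: InsertStats) -> list[PairEvidence]:
    """All classified read pairs with a primary alignment in the window.

    A pair is reported once, provided at least one mate's primary alignment
    overlaps the window and both mates map to ``window.chrom``.  Unpaired
    reads and pairs with an unmapped mate are skipped.
    """
    af, own = _open_alignments(source)
    out: list[PairEvidence] = []
    seen: set[str] = set()
    try:
        if window.chrom not in af.references:
            return out
        for rec in af.fetch(window.chrom, window.start, window.end):
            if not _is_primary(rec) or not rec.is_paired or rec.mate_is_unmapped:
                continue
            if rec.reference_id != rec.next_reference_id:
                continue  # inter-chromosomal pairs out of scope
            if rec.query_name in seen:
                continue
            mate = _mate_segment(af, rec)
            if mate is None:
                logger.warning("mate of %s not found; pair skipped", rec.query_name)
                continue
            seen.add(rec.query_name)
            pair = PairEvidence.from_mates(
                rec.reference_start, rec.reference_end, _strand(rec),
                mate.start, mate.end, mate.strand)
            out.append(replace(pair, evclass=classify_pair(pair, stats)))
    finally:
        if own:
            af.close()
    return out


def extract_split_evidence(source, window: GenomicWindow) -> list[SplitEvidence]:
    """Classified split-read segment pairs overlapping the window.

    Each read's aligned segments (its own plus those in the ``SA`` tag) are
    ordered by their offset within the read; adjacent segments in read order
    form one observation.  A read seen from both its primary and its
    supplementary record is emitted once.  Segments on other chromosomes are
    excluded; malformed SA entries skip the record with a warning.
    """
    af, own = _open_alignments(source)
    out: list[SplitEvidence] = []
    seen: set[tuple] = set()
    try:
        if window.chrom not in af.references:
            return out
        for rec in af.fetch(window.chrom, window.start, window.end):
            if rec.is_unmapped or rec.is_secondary or rec.is_duplicate or rec.is_qcfail:
                continue
            if not rec.has_tag("SA"):
                continue
            try:
                segs = [_segment_from_record(rec)] + _parse_sa_tag(rec.get_tag("SA"))
            except (FormatError, ValueError) as exc:
                logger.warning("skipping %s: %s", rec.query_name, exc)
                continue
            segs.sort(key=lambda s: s.read_offset)
            for a, b in zip(segs, segs[1:]):
                if a.rname != window.chrom or b.rname != window.chrom:
                    continue
                s1, s2 = sorted((a, b), key=lambda s: (s.start, s.end))
                if not (window.overlaps(s1.start, s1.end)
                        or window.overlaps(s2.start, s2.end)):
                    continue
                key = (rec.query_name, rec.is_read1,
                       s1.start, s1.end, s2.start, s2.end)
                if key in seen:
                    continue
                seen.add(key)
                raw_flip = s1.read_offset > s2.read_offset
                # a reverse-strand read travels the genome right-to-left, so
                # its natural segment order is genomically descending
                if s1.strand == s2.strand == "-":
                    raw_flip = not raw_flip
                split = SplitEvidence(
                    s1.start, s1.end, s2.start, s2.end, s1.strand, s2.strand,
                    read_order_flipped=raw_flip,
                    span=max(s1.end, s2.end) - s1.start)
                out.append(replace(split, evclass=classify_split(split)))
    finally:
        if own:
            af.close()
    return out


def downsample_normal_pairs(pairs: Sequence[PairEvidence], max_normals: int,
                            seed: int) -> list[PairEvidence]:
    """Keep all discordant pairs and at most ``max_normals`` NORMAL pairs.

    The retained NORMAL subset is a seeded uniform sample without
    replacement; relative input order is preserved.
    """
    if max_normals < 0:
        raise ValueError("max_normals must be >= 0")
    normal_idx = [i for i, p in enumerate(pairs) if p.evclass is EvidenceClass.NORMAL]
    if len(normal_idx) <= max_normals:
        return list(pairs)
    keep = set(random.Random(seed).sample(normal_idx, max_normals))
    return [p for i, p in enumerate(pairs)
            if p.evclass is not EvidenceClass.NORMAL or i in keep]


def compute_coverage(source, window: GenomicWindow) -> CoverageTrack:
    """Per-base depth of aligned bases from primary, non-duplicate reads.

    Soft-clipped bases and deletion gaps within a read's reference span do
    not contribute.
    """
    af, own = _open_alignments(source)
    try:
        if window.chrom not in af.references:
            return CoverageTrack(window, np.zeros(len(window), dtype=np.int64))
        a, c, g, t = af.count_coverage(
            window.chrom, window.start, window.end,
            quality_threshold=0, read_callback=_is_primary)
        depth = (np.asarray(a, dtype=np.int64) + np.asarray(c, dtype=np.int64)
                 + np.asarray(g, dtype=np.int64) + np.asarray(t, dtype=np.int64))
    finally:
        if own:
            af.close()
    return CoverageTrack(window, depth)


def gather_sample_evidence(source, window: GenomicWindow, z: float = DEFAULT_Z,
                           max_normals: int = DEFAULT_MAX_NORMALS, seed: int = 0,
                           sample_name: str | None = None,
                           max_sampled: int = DEFAULT_MAX_SAMPLED) -> SampleTracks:
    """Full evidence bundle for one sample: stats, pairs, splits, coverage."""
    af, own = _open_alignments(source)
    try:
        if sample_name is None:
            sample_name = _infer_sample_name(af)
        stats = estimate_insert_stats(af, max_sampled=max_sampled, z=z)
        pairs = downsample_normal_pairs(
            extract_pair_evidence(af, window, stats), max_normals, seed)
        splits = extract_split_evidence(af, window)
        coverage = compute_coverage(af, window)
    finally:
        if own:
            af.close()
    return SampleTracks(sample_name, window, pairs, splits, coverage, stats)


def _infer_sample_name(af: pysam.AlignmentFile) -> str:
    for rg in af.header.to_dict().get("RG", []):
        if "SM" in rg:
            return rg["SM"]
    return os.path.basename(af.filename.decode()
                            if isinstance(af.filename, bytes) else str(af.filename))


# ---------------------------------------------------------------------------
# VCF input and evidence dump
# ---------------------------------------------------------------------------

def load_sv_calls(vcf_path: str) -> list[SVCall]:
    """Read SV calls from a VCF (SVTYPE and END in INFO; POS-1 -> start)."""
    import cyvcf2

    calls = []
    for v in cyvcf2.VCF(str(vcf_path)):
        svtype = v.INFO.get("SVTYPE")
        if svtype not in SV_TYPES:
            logger.warning("skipping record %s:%s with SVTYPE=%r",
                           v.CHROM, v.POS, svtype)
            continue
        start = v.start  # POS - 1
        end = int(v.INFO.get("END", v.end))
        if svtype == "INS" and end <= start:
            end = start + 1
        vid = v.ID if v.ID not in (None, ".") else ""
        calls.append(SVCall(v.CHROM, start, end, svtype, id=vid))
    return calls


def write_evidence_tsv(tracks: Iterable[SampleTracks], path: str) -> None:
    """Dump per-window evidence as TSV (one row per pair/split observation)."""
    cols = ("sample", "kind", "class", "left_start", "left_end",
            "right_start", "right_end", "strands", "span")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for tr in tracks:
            for p in tr.pairs:
                fh.write("\t".join(map(str, (
                    tr.sample_name, "pair", p.evclass.value,
                    p.left_start, p.left_end, p.right_start, p.right_end,
                    p.left_strand + p.right_strand, p.span))) + "\n")
            for s in tr.splits:
                fh.write("\t".join(map(str, (
                    tr.sample_name, "split", s.evclass.value,
                    s.seg1_start, s.seg1_end, s.seg2_start, s.seg2_end,
                    s.seg1_strand + s.seg2_strand, s.span))) + "\n")
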