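"""Synthetic alignment files and reviewer responses with known ground truth.

Emulates the alignment signatures of structural variants in a short-read,
forward-reverse (Illumina-style) library without touching sequence space:
read pairs are drawn on the *alternate* haplotype (the one carrying the SV)
and their coordinates are mapped back to the reference, which reproduces the
field signatures exactly —

* deletion: (+,-) pairs whose outer span is inflated by the SV length, and
  split reads whose segments flank the deleted interval;
* tandem duplication: everted (-,+) pairs across the copy junction, and
  split reads whose read order is flipped relative to genomic order;
* inversion: (+,+) pairs/splits across the left breakpoint and (-,-) across
  the right one.

Reads are placed directly as alignment records (no sequence-level
realignment); SEQ and base qualities are constant because every consumer
reads coordinates, flags, and tags only.  A read crossing a breakpoint is
emitted as a primary + supplementary split pair (with reciprocal ``SA``
tags) at rate ``split_read_fraction``; otherwise only its longer segment is
kept, soft-clipped.  Output BAMs are coordinate-sorted in memory and
indexed, and are byte-identical for a fixed seed.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pysam

from .errors import DegenerateInputError
from .evidence import SVCall, synthesize_sv_id

logger = logging.getLogger(__name__)

DEFAULT_CONTIG = "chrS"
DEFAULT_REFERENCE_LENGTH = 100_000
DEFAULT_READ_LENGTH = 100
DEFAULT_INSERT_MEAN = 400.0
DEFAULT_INSERT_SD = 50.0
DEFAULT_SPLIT_FRACTION = 0.5

GENOTYPES = ("ref", "het", "hom")
INHERITANCE_PATTERNS = ("denovo", "paternal", "maternal", "biparental")

#: expected coverage over the SV interval relative to the flanks
COVERAGE_RATIO = {
    ("DEL", "ref"): 1.0, ("DEL", "het"): 0.5, ("DEL", "hom"): 0.0,
    ("DUP", "ref"): 1.0, ("DUP", "het"): 1.5, ("DUP", "hom"): 2.0,
    ("INV", "ref"): 1.0, ("INV", "het"): 1.0, ("INV", "hom"): 1.0,
}


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one planted-SV simulation.

    ``genotypes`` maps sample name -> {ref, het, hom}; each sample is
    simulated as two haplotypes at half the requested depth each.
    """

    sv: SVCall
    genotypes: dict[str, str] = field(default_factory=lambda: {"S1": "het"})
    reference_length: int = DEFAULT_REFERENCE_LENGTH
    depth: float = 30.0
    read_length: int = DEFAULT_READ_LENGTH
    insert_mean: float = DEFAULT_INSERT_MEAN
    insert_sd: float = DEFAULT_INSERT_SD
    split_read_fraction: float = DEFAULT_SPLIT_FRACTION
    seed: int = 1

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.read_length >= self.insert_mean:
            raise ValueError("read length must be < insert mean")
        if not 0 <= self.split_read_fraction <= 1:
            raise ValueError("split_read_fraction must be in [0, 1]")
        for g in self.genotypes.values():
            if g not in GENOTYPES:
                raise ValueError(f"unknown genotype {g!r}")
        if self.sv.svtype not in ("DEL", "DUP", "INV"):
            raise ValueError("simulation supports DEL, DUP, INV")
        if self.sv.start < 0 or self.sv.end > self.reference_length:
            raise ValueError("SV outside the reference contig")


@dataclass
class SampleTruth:
    """Ground truth for one simulated sample."""

    genotype: str
    n_support_pairs: int = 0
    n_support_splits: int = 0
    coverage_ratio: float = 1.0


@dataclass
class TruthTable:
    """Per-sample expected evidence counts for one planted SV."""

    sv: SVCall
    samples: dict[str, SampleTruth] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# haplotype geometry: the alternate genome as reference blocks
# ---------------------------------------------------------------------------

def _alt_blocks(sv: SVCall, ref_len: int) -> list[tuple[int, int, str]]:
    """Alternate haplotype as ordered reference blocks (start, end, strand)."""
    s, e = sv.start, sv.end
    if sv.svtype == "DEL":
        return [(0, s, "+"), (e, ref_len, "+")]
    if sv.svtype == "DUP":  # tandem: ...ref[s:e) ref[s:e)...
        return [(0, e, "+"), (s, e, "+"), (e, ref_len, "+")]
    if sv.svtype == "INV":
        return [(0, s, "+"), (s, e, "-"), (e, ref_len, "+")]
    raise ValueError(sv.svtype)


def _map_alt_interval(blocks, a: int, b: int) -> list[tuple[int, int, str]]:
    """Map alt-genome interval [a, b) to reference segments, in alt order."""
    segs = []
    off = 0
    for r0, r1, strand in blocks:
        blen = r1 - r0
        lo, hi = max(a, off), min(b, off + blen)
        if lo < hi:
            if strand == "+":
                segs.append((r0 + (lo - off), r0 + (hi - off), "+"))
            else:
                segs.append((r1 - (hi - off), r1 - (lo - off), "-"))
        off += blen
    return segs


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


@dataclass
class _Aln:
    """One SAM record under construction (0-based coordinates)."""

    qname: str
    flag: int
    pos: int
    cigar: str
    seq_len: int
    tlen: int = 0
    pnext: int = 0
    tags: list = field(default_factory=list)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 0x10)


def _read_segments(blocks, alt_a: int, alt_b: int, read_alt_strand: str,
                   read_length: int):
    """Aligned segments of one read: (ref_start, ref_end, strand, q0, q1).

    ``q0/q1`` are read coordinates of the segment's aligned bases; the final
    reference strand of a segment is the XOR of the read's alt-genome strand
    and the block strand it lands in.
    """
    out = []
    off = 0
    for br0, br1, bstrand in blocks:
        blen = br1 - br0
        lo, hi = max(alt_a, off), min(alt_b, off + blen)
        if lo < hi:
            if bstrand == "+":
                r0, r1 = br0 + (lo - off), br0 + (hi - off)
            else:
                r0, r1 = br1 - (hi - off), br1 - (lo - off)
            if read_alt_strand == "+":
                q0, q1 = lo - alt_a, hi - alt_a
            else:
                q0, q1 = alt_b - hi, alt_b - lo
            strand = bstrand if read_alt_strand == "+" else _flip(bstrand)
            out.append((r0, r1, strand, q0, q1))
        off += blen
    return _merge_contiguous(out)


def _merge_contiguous(segs):
    """Fuse consecutive segments that are reference-contiguous on the same
    strand: block junctions that map back contiguously (e.g. the trailing
    junction of a tandem duplication) are one alignment to an aligner."""
    merged = list(segs[:1])
    for r0, r1, st, q0, q1 in segs[1:]:
        p0, p1, pst, pq0, pq1 = merged[-1]
        if st == pst and (p1 == r0 or r1 == p0):
            merged[-1] = (min(p0, r0), max(p1, r1), st,
                          min(pq0, q0), max(pq1, q1))
        else:
            merged.append((r0, r1, st, q0, q1))
    return merged


def _segment_cigar(q0: int, q1: int, strand: str, read_length: int) -> str:
    m = q1 - q0
    lead, trail = (q0, read_length - q1) if strand == "+" else (read_length - q1, q0)
    parts = []
    if lead:
        parts.append(f"{lead}S")
    parts.append(f"{m}M")
    if trail:
        parts.append(f"{trail}S")
    return "".join(parts)


def _build_read(blocks, alt_a, alt_b, read_alt_strand, read_length, qname,
                read1: bool, emit_split: bool):
    """SAM records for one read; primary first.  Returns [] if unmappable."""
    segs = _read_segments(blocks, alt_a, alt_b, read_alt_strand, read_length)
    segs = [s for s in segs if s[1] - s[0] >= 20]  # drop slivers an aligner would clip
    if not segs:
        return []
    if not emit_split and len(segs) > 1:
        segs = [max(segs, key=lambda s: s[1] - s[0])]
    primary = max(segs, key=lambda s: s[1] - s[0])
    records = []
    base_flag = 0x1 | (0x40 if read1 else 0x80)
    for seg in segs:
        r0, r1, strand, q0, q1 = seg
        flag = base_flag | (0x10 if strand == "-" else 0)
        if seg is not primary:
            flag |= 0x800
        cigar = _segment_cigar(q0, q1, strand, read_length)
        rec = _Aln(qname, flag, r0, cigar, read_length)
        if len(segs) > 1:
            others = [s for s in segs if s is not seg]
            rec.tags.append(("SA", ";".join(
                f"{{rname}},{o[0] + 1},{o[2]},{_segment_cigar(o[3], o[4], o[2], read_length)},60,0"
                for o in others) + ";"))
        records.append(rec)
    records.sort(key=lambda r: 0 if not (r.flag & 0x800) else 1)
    return records


def _simulate_haplotype(rng: random.Random, blocks, spec: SimulationSpec,
                        qprefix: str) -> list[_Aln]:
    """All records for one haplotype at depth/2 fold coverage."""
    alt_len = sum(e - s for s, e, _ in blocks)
    rl = spec.read_length
    n_frags = int(round(spec.depth / 2 * alt_len / (2 * rl)))
    records: list[_Aln] = []
    for i in range(n_frags):
        flen = max(rl, int(round(rng.gauss(spec.insert_mean, spec.insert_sd))))
        flen = min(flen, alt_len)
        fs = rng.randrange(0, alt_len - flen + 1)
        qname = f"{qprefix}:{i}"
        emit_split = rng.random() < spec.split_read_fraction
        r1 = _build_read(blocks, fs, fs + min(rl, flen), "+", rl, qname,
                         True, emit_split)
        r2 = _build_read(blocks, fs + flen - min(rl, flen), fs + flen, "-",
                         rl, qname, False, emit_split)
        if not r1 or not r2:
            continue
        _set_mate_fields(r1, r2, spec)
        records.extend(r1)
        records.extend(r2)
    return records


def _cigar_ref_span(cigar: str) -> int:
    span = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MDN=X":
                span += int(num)
            num = ""
    return span


def _set_mate_fields(r1: list[_Aln], r2: list[_Aln], spec: SimulationSpec) -> None:
    p1, p2 = r1[0], r2[0]
    end1 = p1.pos + _cigar_ref_span(p1.cigar)
    end2 = p2.pos + _cigar_ref_span(p2.cigar)
    left = min(p1.pos, p2.pos)
    right = max(end1, end2)
    span = right - left
    # aligner-style proper-pair call: FR orientation, unsplit, sane span
    fr = ((p1.pos <= p2.pos and not p1.is_reverse and p2.is_reverse)
          or (p2.pos < p1.pos and not p2.is_reverse and p1.is_reverse))
    proper = (fr and len(r1) == 1 and len(r2) == 1
              and span <= spec.insert_mean + 4 * spec.insert_sd)
    leftmost = p1 if (p1.pos, 0) <= (p2.pos, 1) else p2
    for rec, mate in ((p1, p2), (p2, p1)):
        rec.pnext = mate.pos
        rec.flag |= 0x20 if mate.is_reverse else 0
        if proper:
            rec.flag |= 0x2
        rec.tlen = span if rec is leftmost else -span
        rec.tags.append(("MC", mate.cigar))
    # supplementary records inherit mate info from their primary
    for recs, mate in ((r1, p2), (r2, p1)):
        for rec in recs[1:]:
            rec.pnext = mate.pos
            rec.flag |= 0x20 if mate.is_reverse else 0
            rec.tags.append(("MC", mate.cigar))


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------

def _count_support(records: list[_Aln], spec: SimulationSpec) -> tuple[int, int]:
    """Discordant pairs and split observations among emitted records."""
    upper = spec.insert_mean + 4 * spec.insert_sd
    primaries: dict[tuple[str, bool], _Aln] = {}
    n_splits = 0
    split_seen: set[tuple[str, bool]] = set()
    for rec in records:
        key = (rec.qname, bool(rec.flag & 0x40))
        if rec.flag & 0x800:
            if key not in split_seen:
                split_seen.add(key)
        else:
            primaries[key] = rec
    # splits: each split read contributes (n_segments - 1) adjacent pairs;
    # the generator emits exactly 2 segments per split read
    n_splits = len(split_seen)
    n_pairs = 0
    by_q: dict[str, list[_Aln]] = {}
    for (q, _), rec in primaries.items():
        by_q.setdefault(q, []).append(rec)
    for q, recs in by_q.items():
        if len(recs) != 2:
            continue
        a, b = sorted(recs, key=lambda r: (r.pos, r.pos + _cigar_ref_span(r.cigar)))
        left_strand = "-" if a.is_reverse else "+"
        right_strand = "-" if b.is_reverse else "+"
        span = max(a.pos + _cigar_ref_span(a.cigar),
                   b.pos + _cigar_ref_span(b.cigar)) - a.pos
        if (left_strand, right_strand) != ("+", "-") or span > upper:
            n_pairs += 1
    return n_pairs, n_splits


# ---------------------------------------------------------------------------
# BAM output
# ---------------------------------------------------------------------------

def _write_bam(path: str, contigs: Sequence[tuple[str, int]], sample: str,
               records_by_contig: dict[str, list[_Aln]]) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs],
        "RG": [{"ID": sample, "SM": sample}],
    }
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for tid, (name, _len) in enumerate(contigs):
            recs = records_by_contig.get(name, [])
            recs.sort(key=lambda r: (r.pos, r.qname, r.flag))
            for r in recs:
                a = pysam.AlignedSegment(bam.header)
                a.query_name = r.qname
                a.flag = r.flag
                a.reference_id = tid
                a.reference_start = r.pos
                a.mapping_quality = 60
                a.cigarstring = r.cigar
                a.next_reference_id = tid
                a.next_reference_start = r.pnext
                a.template_length = r.tlen
                a.query_sequence = "A" * r.seq_len
                a.query_qualities = pysam.qualitystring_to_array("I" * r.seq_len)
                tags = [("RG", sample)] + [
                    (t, v.format(rname=name) if t == "SA" else v) for t, v in r.tags]
                a.set_tags(tags + [("NM", 0)])
                bam.write(a)
    pysam.index(str(path))


def _sample_records(spec: SimulationSpec, sample: str, genotype: str,
                    seed: int) -> tuple[list[_Aln], SampleTruth]:
    rng = random.Random(seed)
    ref_blocks = [(0, spec.reference_length, "+")]
    alt_blocks = _alt_blocks(spec.sv, spec.reference_length)
    hap_blocks = {
        "ref": (ref_blocks, ref_blocks),
        "het": (alt_blocks, ref_blocks),
        "hom": (alt_blocks, alt_blocks),
    }[genotype]
    records: list[_Aln] = []
    for h, blocks in enumerate(hap_blocks):
        records.extend(_simulate_haplotype(rng, blocks, spec, f"{sample}.h{h}"))
    n_pairs, n_splits = _count_support(records, spec)
    truth = SampleTruth(genotype, n_pairs, n_splits,
                        COVERAGE_RATIO[(spec.sv.svtype, genotype)])
    return records, truth


def simulate_sv_alignments(spec: SimulationSpec, out_path: str) -> TruthTable:
    """Write one sorted, indexed BAM per sample with a planted SV.

    When ``spec.genotypes`` names a single sample, ``out_path`` is that
    sample's BAM path; with several samples, ``out_path`` is treated as a
    directory and one ``<sample>.bam`` is written per sample.  Fully
    deterministic for a fixed seed.
    """
    import os

    truth = TruthTable(sv=spec.sv)
    contigs = [(spec.sv.chrom, spec.reference_length)]
    single = len(spec.genotypes) == 1
    for i, (sample, gt) in enumerate(sorted(spec.genotypes.items())):
        records, sample_truth = _sample_records(spec, sample, gt, spec.seed + i)
        truth.samples[sample] = sample_truth
        path = out_path if single else os.path.join(out_path, f"{sample}.bam")
        _write_bam(path, contigs, sample,
                   {spec.sv.chrom: records})
    return truth


def simulate_trio(spec: SimulationSpec, inheritance: str, out_dir: str,
                  child: str = "child", father: str = "father",
                  mother: str = "mother") -> tuple[dict[str, str], TruthTable]:
    """Simulate a trio; the child carries the SV per ``spec.genotypes``.

    ``inheritance`` in {denovo, paternal, maternal, biparental} sets the
    parents' genotypes (denovo: both ref).  Returns {sample: bam path} and
    the truth table.
    """
    import os

    if inheritance not in INHERITANCE_PATTERNS:
        raise ValueError(f"unknown inheritance pattern {inheritance!r}")
    child_gt = spec.genotypes.get(child, next(iter(spec.genotypes.values())))
    genotypes = {
        child: child_gt,
        father: "het" if inheritance in ("paternal", "biparental") else "ref",
        mother: "het" if inheritance in ("maternal", "biparental") else "ref",
    }
    trio_spec = replace(spec, genotypes=genotypes)
    os.makedirs(out_dir, exist_ok=True)
    truth = simulate_sv_alignments(trio_spec, out_dir)
    paths = {s: os.path.join(out_dir, f"{s}.bam") for s in genotypes}
    return paths, truth


def simulate_trio_cohort(specs: Sequence[tuple[SVCall, dict[str, str]]],
                         out_dir: str, depth: float = 30.0,
                         reference_length: int = 15_000,
                         read_length: int = DEFAULT_READ_LENGTH,
                         insert_mean: float = DEFAULT_INSERT_MEAN,
                         insert_sd: float = DEFAULT_INSERT_SD,
                         split_read_fraction: float = DEFAULT_SPLIT_FRACTION,
                         seed: int = 1) -> tuple[dict[str, str], dict[str, TruthTable]]:
    """Many planted SVs, one contig each, merged into one BAM per sample.

    ``specs`` is a list of (SVCall, {sample: genotype}); every SVCall must
    sit on its own contig.  Returns {sample: bam path} and
    {sv id: TruthTable}.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    samples = sorted({s for _, gts in specs for s in gts})
    contigs = [(sv.chrom, reference_length) for sv, _ in specs]
    if len({c for c, _ in contigs}) != len(contigs):
        raise ValueError("each SV must sit on its own contig")
    per_sample: dict[str, dict[str, list[_Aln]]] = {s: {} for s in samples}
    truths: dict[str, TruthTable] = {}
    for k, (sv, gts) in enumerate(specs):
        spec = SimulationSpec(sv=sv, genotypes=gts, reference_length=reference_length,
                              depth=depth, read_length=read_length,
                              insert_mean=insert_mean, insert_sd=insert_sd,
                              split_read_fraction=split_read_fraction, seed=seed)
        truth = TruthTable(sv=sv)
        for i, s in enumerate(samples):
            gt = gts.get(s, "ref")
            recs, st = _sample_records(spec, s, gt, (seed + 1_000 * k + i) % (2**31))
            truth.samples[s] = st
            per_sample[s][sv.chrom] = recs
        truths[sv.id] = truth
    paths = {}
    for s in samples:
        path = os.path.join(out_dir, f"{s}.bam")
        _write_bam(path, contigs, s, per_sample[s])
        paths[s] = path
    return paths, truths


# ---------------------------------------------------------------------------
# fixture VCF / truth TSV output
# ---------------------------------------------------------------------------

def write_sv_vcf(svs: Sequence[SVCall], path: str,
                 contig_length: int = DEFAULT_REFERENCE_LENGTH) -> None:
    """Minimal VCF 4.2 with SVTYPE/END INFO fields for the given calls."""
    lines = ["##fileformat=VCFv4.2",
             '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
             '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">']
    for chrom in dict.fromkeys(sv.chrom for sv in svs):
        lines.append(f"##contig=<ID={chrom},length={contig_length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for sv in svs:
        lines.append("\t".join((
            sv.chrom, str(sv.start + 1), sv.id, "N", f"<{sv.svtype}>",
            ".", "PASS", f"SVTYPE={sv.svtype};END={sv.end}")))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_truth_tsv(truths: dict[str, TruthTable], path: str) -> None:
    cols = ("sv_id", "chrom", "start", "end", "svtype", "sample", "genotype",
            "support_pairs", "support_splits", "coverage_ratio")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for sv_id, tt in truths.items():
            for sample, st in sorted(tt.samples.items()):
                fh.write("\t".join(map(str, (
                    sv_id, tt.sv.chrom, tt.sv.start, tt.sv.end, tt.sv.svtype,
                    sample, st.genotype, st.n_support_pairs, st.n_support_splits,
                    st.coverage_ratio))) + "\n")


# ---------------------------------------------------------------------------
# simulated reviewers
# ---------------------------------------------------------------------------

def simulate_reviewer_responses(truth: dict[str, str], n_reviewers: int,
                                error_rate: float, seed: int,
                                answers: Sequence[str] | None = None,
                                start_time: float = 1_600_000_000.0) -> list:
    """Simulated curation responses: each reviewer answers each image with
    the true label with probability 1 - error_rate, else a uniformly random
    wrong label from ``answers`` (default: the labels present in ``truth``).

    Deterministic for a fixed seed.
    """
    from .curation import ResponseRecord

    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    if answers is None:
        answers = sorted(set(truth.values()))
    rng = random.Random(seed)
    records = []
    t = start_time
    for r in range(n_reviewers):
        reviewer = f"reviewer{r + 1:02d}"
        for image_id in sorted(truth):
            true_label = truth[image_id]
            if error_rate > 0 and rng.random() < error_rate:
                wrong = [a for a in answers if a != true_label]
                answer = rng.choice(wrong) if wrong else true_label
            else:
                answer = true_label
            elapsed = round(rng.uniform(1.0, 5.0), 2)
            t += elapsed
            records.append(ResponseRecord(image_id=image_id, reviewer=reviewer,
                                          answer=answer, timestamp=t,
                                          elapsed_seconds=elapsed))
    return records
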