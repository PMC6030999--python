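"""Shared fixtures: hand-built SAM fixtures and brute-force oracles.

The oracles re-derive pair evidence and coverage from raw alignment records
with independent, straight-line logic so extraction code can be checked
against them exactly.
"""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from svcurate.evidence import GenomicWindow, InsertStats, PairEvidence


# ---------------------------------------------------------------------------
# building small BAMs from SAM text
# ---------------------------------------------------------------------------

SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chrT\tLN:10000\n"


def sam_to_bam(sam_text: str, path) -> str:
    """Write SAM text (records already coordinate-sorted) as an indexed BAM."""
    path = str(path)
    sam_path = path[:-4] + ".sam"
    with open(sam_path, "w") as fh:
        fh.write(sam_text)
    with pysam.AlignmentFile(sam_path) as sam, \
            pysam.AlignmentFile(path, "wb", template=sam) as bam:
        for rec in sam:
            bam.write(rec)
    pysam.index(path)
    return path


def pair_sam_lines(qname: str, pos1: int, strand1: str, pos2: int, strand2: str,
                   read_len: int = 50, chrom: str = "chrT", proper: bool = True,
                   mc: bool = True, dup: bool = False) -> list[str]:
    """Two primary SAM lines for a fully-aligned read pair (0-based input)."""
    cigar = f"{read_len}M"
    end1, end2 = pos1 + read_len, pos2 + read_len
    span = max(end1, end2) - min(pos1, pos2)
    lines = []
    for which, (p, st, mp, mst) in enumerate(
            [(pos1, strand1, pos2, strand2), (pos2, strand2, pos1, strand1)]):
        flag = 0x1 | (0x40 if which == 0 else 0x80)
        flag |= 0x10 if st == "-" else 0
        flag |= 0x20 if mst == "-" else 0
        flag |= 0x2 if proper else 0
        flag |= 0x400 if dup else 0
        tlen = span if p <= mp else -span
        tags = f"\tMC:Z:{cigar}" if mc else ""
        lines.append(f"{qname}\t{flag}\t{chrom}\t{p + 1}\t60\t{cigar}\t=\t"
                     f"{mp + 1}\t{tlen}\t{'A' * read_len}\t{'I' * read_len}"
                     f"{tags}")
    return lines


def build_sam(record_lines: list[str], header: str = SAM_HEADER) -> str:
    """Assemble a SAM document, sorting records by position."""
    def pos_of(line):
        f = line.split("\t")
        return (f[2], int(f[3]))

    return header + "".join(l + "\n" for l in sorted(record_lines, key=pos_of))


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def bruteforce_pairs(bam_path: str, window: GenomicWindow,
                     stats: InsertStats) -> set[tuple]:
    """Pair evidence recomputed by a naive full-file pass.

    Pairs every primary record by query name, keeps pairs where both mates
    map to the window chromosome and at least one overlaps the window, and
    classifies by the decision table written out longhand.
    """
    prim: dict[tuple, list] = {}
    with pysam.AlignmentFile(bam_path) as af:
        for rec in af.fetch(until_eof=True):
            if (rec.is_unmapped or rec.is_secondary or rec.is_supplementary
                    or rec.is_duplicate or rec.is_qcfail or not rec.is_paired):
                continue
            prim.setdefault(rec.query_name, []).append(
                (rec.reference_name, rec.reference_start, rec.reference_end,
                 "-" if rec.is_reverse else "+"))
    out = set()
    for qname, recs in prim.items():
        if len(recs) != 2:
            continue
        a, b = sorted(recs, key=lambda r: (r[1], r[2]))
        if a[0] != window.chrom or b[0] != window.chrom:
            continue
        if not (a[1] < window.end and a[2] > window.start) and \
                not (b[1] < window.end and b[2] > window.start):
            continue
        span = max(a[2], b[2]) - a[1]
        strands = (a[3], b[3])
        if strands == ("+", "-"):
            cls = "DELETION" if span > stats.mean + stats.z * stats.sd else "NORMAL"
        elif strands == ("-", "+"):
            cls = "DUPLICATION"
        elif strands == ("+", "+"):
            cls = "INVERSION_FF"
        else:
            cls = "INVERSION_RR"
        out.add((a[1], a[2], b[1], b[2], a[3], b[3], span, cls))
    return out


def pair_key(p: PairEvidence) -> tuple:
    return (p.left_start, p.left_end, p.right_start, p.right_end,
            p.left_strand, p.right_strand, p.span, p.evclass.value)


def bruteforce_coverage(bam_path: str, window: GenomicWindow) -> np.ndarray:
    """Per-base depth by tallying aligned reference positions read by read."""
    depth = np.zeros(len(window), dtype=np.int64)
    with pysam.AlignmentFile(bam_path) as af:
        for rec in af.fetch(until_eof=True):
            if (rec.is_unmapped or rec.is_secondary or rec.is_supplementary
                    or rec.is_duplicate or rec.is_qcfail):
                continue
            if rec.reference_name != window.chrom:
                continue
            for pos in rec.get_reference_positions():
                if window.start <= pos < window.end:
                    depth[pos - window.start] += 1
    return depth


def bruteforce_insert_stats(bam_path: str, max_sampled: int) -> tuple[float, float, int]:
    """Mean/population-sd of outer spans over the first qualifying pairs."""
    spans = []
    pending = {}
    with pysam.AlignmentFile(bam_path) as af:
        for rec in af.fetch(until_eof=True):
            if len(spans) >= max_sampled:
                break
            if (rec.is_unmapped or rec.is_secondary or rec.is_supplementary
                    or rec.is_duplicate or rec.is_qcfail):
                continue
            if not (rec.is_paired and rec.is_proper_pair) or rec.mate_is_unmapped:
                continue
            if rec.reference_id != rec.next_reference_id:
                continue
            if rec.query_name in pending:
                o = pending.pop(rec.query_name)
                mates = sorted([o, (rec.reference_start, rec.reference_end,
                                    rec.is_reverse)])
                if not mates[0][2] and mates[1][2]:
                    spans.append(max(o[1], rec.reference_end)
                                 - min(o[0], rec.reference_start))
            else:
                pending[rec.query_name] = (rec.reference_start,
                                           rec.reference_end, rec.is_reverse)
    arr = np.asarray(spans, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=0)), len(spans)


# ---------------------------------------------------------------------------
# common fixtures
# ---------------------------------------------------------------------------

@pytest.fixture()
def trio_config_json(tmp_path):
    import json

    path = tmp_path / "config.json"
    path.write_text(json.dumps({
        "project": "trio-demo",
        "curationQandA": {
            "question": "The SV in the top sample is:",
            "answers": ["GOOD", "BAD", "DE NOVO"],
            "keys": ["g", "b", "d"],
        },
    }))
    return str(path)
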