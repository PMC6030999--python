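"""Per-SV evidence figures.

Each figure stacks, top to bottom: a locator bar marking the predicted SV
interval, one panel per sample (in the order given, sample of interest
first), and an optional gene/annotation track.  All panels share the x-axis
(chromosomal position).  Within a sample panel, paired-end observations are
solid lines with square endpoints and split-read observations dashed lines
with circle endpoints, positioned at their outer span on the left y-axis
and colored by the SV class they support; per-base coverage is a grey
filled profile against an independent right y-axis.
"""

from __future__ import annotations

import concurrent.futures
import gzip
import logging
import os
import re
import zlib
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .errors import FormatError
from .evidence import (
    DEFAULT_MAX_NORMALS,
    DEFAULT_Z,
    EvidenceClass,
    GenomicWindow,
    SampleTracks,
    SVCall,
    gather_sample_evidence,
)

logger = logging.getLogger(__name__)

DEFAULT_PAD_FRACTION = 0.5
DEFAULT_MIN_PAD = 1_000
DEFAULT_DPI = 100

#: fraction of plotted spans kept on the linear y-axis; larger spans are
#: clamped to the axis top
SPAN_CLAMP_PERCENTILE = 98.0


# ---------------------------------------------------------------------------
# window & annotations
# ---------------------------------------------------------------------------

def compute_window(sv: SVCall, pad_fraction: float = DEFAULT_PAD_FRACTION,
                   min_pad: int = DEFAULT_MIN_PAD) -> GenomicWindow:
    """Plotting window around an SV: the call padded on both sides by
    ``max(min_pad, round(pad_fraction * sv length))``, clamped at 0."""
    if pad_fraction < 0 or min_pad < 0:
        raise ValueError("pad_fraction and min_pad must be >= 0")
    pad = max(min_pad, round(pad_fraction * (sv.end - sv.start)))
    return GenomicWindow(sv.chrom, max(0, sv.start - pad), sv.end + pad)


@dataclass(frozen=True)
class AnnotationTrack:
    """Gene/region intervals within a window, sorted by start."""

    intervals: tuple  # of (start, end, label, kind)
    source: str = ""


_GFF_KINDS = {"gene": "gene", "exon": "exon"}
def _gff_label(attrs: str) -> str | None:
    fields = dict(item.split("=", 1) for item in attrs.split(";") if "=" in item)
    for key in ("Name", "gene_name", "ID"):
        if key in fields:
            return fields[key]
    return None


def load_gene_annotations(path: str, window: GenomicWindow) -> AnnotationTrack:
    """Window-clipped intervals from a BED (0-based half-open) or GFF3
    (1-based inclusive, converted) file, optionally gzip/bgzip-compressed.

    GFF3 ``gene``/``exon`` features keep their kind; everything else (and
    all BED intervals) is kind ``region``.  Unparseable lines are skipped
    with a warning; an unrecognized extension raises :class:`FormatError`.
    """
    name = os.path.basename(path)
    stem = name[:-3] if name.endswith(".gz") else name
    if stem.endswith(".bed"):
        fmt = "bed"
    elif stem.endswith((".gff", ".gff3")):
        fmt = "gff3"
    else:
        raise FormatError(f"unknown annotation format: {name}")
    opener = gzip.open if name.endswith(".gz") else open
    intervals = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    label = fields[3] if len(fields) > 3 else ""
                    kind = "region"
                else:
                    chrom, start, end = fields[0], int(fields[3]) - 1, int(fields[4])
                    kind = _GFF_KINDS.get(fields[2], "region")
                    label = (_gff_label(fields[8]) if len(fields) > 8 else None) \
                        or fields[2]
            except (IndexError, ValueError):
                logger.warning("%s:%d: unparseable annotation line skipped", path, lineno)
                continue
            if chrom != window.chrom or not window.overlaps(start, end):
                continue
            intervals.append((max(start, window.start), min(end, window.end),
                              label, kind))
    # genes before their exons at equal start
    intervals.sort(key=lambda iv: (iv[0], iv[3] != "gene", iv[1]))
    return AnnotationTrack(tuple(intervals), source=name)


# ---------------------------------------------------------------------------
# figure spec & rendering
# ---------------------------------------------------------------------------

@dataclass
class FigureSpec:
    """Everything needed to draw one SV image."""

    sv: SVCall
    window: GenomicWindow
    samples: list[SampleTracks]
    annotations: list[AnnotationTrack] = field(default_factory=list)
    out_path: str = ""
    dpi: int = DEFAULT_DPI
    title: str = ""

    def __post_init__(self):
        if not self.samples:
            raise ValueError("FigureSpec requires at least one sample")


def _glyph_alpha(n_glyphs: int) -> float:
    """Denser panels get fainter glyphs so concentration reads as intensity."""
    return float(np.clip(25.0 / max(n_glyphs, 1), 0.25, 0.85))


def _span_axis_top(tracks: SampleTracks) -> float:
    spans = [p.span for p in tracks.pairs] + [s.span for s in tracks.splits]
    if not spans:
        return max(tracks.insert_stats.upper, 1.0)
    top = float(np.percentile(spans, SPAN_CLAMP_PERCENTILE))
    return max(top, 1.0)


def _draw_sample_panel(ax, tracks: SampleTracks) -> None:
    win = tracks.window
    top = _span_axis_top(tracks)
    alpha = _glyph_alpha(len(tracks.pairs) + len(tracks.splits))
    for p in tracks.pairs:
        y = min(p.span, top)
        ax.plot([p.left_start, p.right_end], [y, y], "-", marker="s",
                markersize=2.5, linewidth=0.8, color=p.evclass.color,
                alpha=alpha, gid=f"pair:{p.evclass.value}")
    for s in tracks.splits:
        y = min(s.span, top)
        ax.plot([s.seg1_start, s.seg2_end], [y, y], "--", marker="o",
                markersize=3.0, linewidth=0.8, color=s.evclass.color,
                alpha=alpha, gid=f"split:{s.evclass.value}")
    ax.set_xlim(win.start, win.end)
    ax.set_ylim(0, top * 1.05)
    ax.set_ylabel("insert size (bp)", fontsize=7)
    ax.text(0.005, 0.95, tracks.sample_name, transform=ax.transAxes,
            fontsize=8, va="top", fontweight="bold")
    cov = ax.twinx()
    cov.set_label("coverage-axis")
    x = np.arange(win.start, win.end)
    cov.fill_between(x, tracks.coverage.depth, step="mid", color="grey",
                     alpha=0.35, zorder=0, gid="coverage")
    cov.set_ylim(0, max(tracks.coverage.max_depth, 1) * 1.1)
    cov.set_ylabel("coverage", fontsize=7)


def _draw_locator(ax, sv: SVCall, window: GenomicWindow) -> None:
    ax.plot([sv.start, sv.end], [0.5, 0.5], "-", color="black", linewidth=6,
            solid_capstyle="butt", gid="sv-locator")
    ax.set_xlim(window.start, window.end)
    ax.set_ylim(0, 1)
    ax.set_yticks([])


def _draw_annotations(ax, window: GenomicWindow,
                      annotations: list[AnnotationTrack]) -> None:
    y = 0
    for track in annotations:
        for start, end, label, kind in track.intervals:
            height = 0.6 if kind == "exon" else 0.25
            ax.add_patch(plt.Rectangle((start, y - height / 2), end - start,
                                       height, color="#4b3ca7",
                                       gid=f"ann:{kind}"))
            if kind != "exon" and label:
                ax.text((start + end) / 2, y + 0.45, label, fontsize=6,
                        ha="center")
        y -= 1
    ax.set_xlim(window.start, window.end)
    ax.set_ylim(min(y, -1) + 0.3, 1)
    ax.set_yticks([])


def build_sv_figure(spec: FigureSpec):
    """Construct (without saving) the matplotlib Figure for one SV.

    Panel axes carry labels ``locator``, ``sample:<name>`` and
    ``annotations`` (coverage twins are ``coverage-axis``), and glyphs carry
    gids ``pair:<class>`` / ``split:<class>``, so callers and tests can
    introspect the layout.  The spec's sample tracks are not mutated.
    """
    n = len(spec.samples)
    has_ann = any(t.intervals for t in spec.annotations)
    nrows = 1 + n + (1 if has_ann else 0)
    heights = [0.4] + [3.0] * n + ([0.9] if has_ann else [])
    fig, axes = plt.subplots(
        nrows, 1, sharex=True, figsize=(8, 0.6 + sum(heights) * 0.55),
        gridspec_kw={"height_ratios": heights}, squeeze=False)
    axes = axes[:, 0]
    title = spec.title or (f"{spec.sv.svtype} {spec.sv.chrom}:"
                           f"{spec.sv.start}-{spec.sv.end}")
    fig.suptitle(title, fontsize=9)
    axes[0].set_label("locator")
    _draw_locator(axes[0], spec.sv, spec.window)
    for ax, tracks in zip(axes[1:1 + n], spec.samples):
        ax.set_label(f"sample:{tracks.sample_name}")
        _draw_sample_panel(ax, tracks)
    if has_ann:
        axes[-1].set_label("annotations")
        _draw_annotations(axes[-1], spec.window, spec.annotations)
    axes[-1].set_xlabel(f"{spec.window.chrom} position", fontsize=8)
    for ax in axes:
        ax.tick_params(labelsize=6)
    return fig


def render_sv_figure(spec: FigureSpec) -> str:
    """Render and write the PNG for one SV; returns the output path."""
    if not spec.out_path:
        raise ValueError("FigureSpec.out_path is required")
    fig = build_sv_figure(spec)
    try:
        fig.savefig(spec.out_path, dpi=spec.dpi)
    finally:
        plt.close(fig)
    return spec.out_path


# ---------------------------------------------------------------------------
# batch rendering & manifest
# ---------------------------------------------------------------------------

_SAFE_RE = re.compile(r"[^A-Za-z0-9._-]")


def safe_image_name(sv_id: str) -> str:
    """Deterministic image filename for an SV id."""
    return _SAFE_RE.sub("_", sv_id) + ".png"


@dataclass
class ManifestEntry:
    image: str
    chrom: str
    start: int
    end: int
    svtype: str
    id: str
    status: str = "ok"  # ok | render_failed


MANIFEST_COLUMNS = ("image", "chrom", "start", "end", "svtype", "id", "status")


def write_manifest(entries, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for e in entries:
            fh.write("\t".join(map(str, (e.image, e.chrom, e.start, e.end,
                                         e.svtype, e.id, e.status))) + "\n")


def read_manifest(path: str) -> list[ManifestEntry]:
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != MANIFEST_COLUMNS:
            raise FormatError(f"unexpected manifest header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            entries.append(ManifestEntry(f[0], f[1], int(f[2]), int(f[3]),
                                         f[4], f[5], f[6]))
    return entries


def _sv_seed(seed: int, sv_id: str) -> int:
    """Per-SV downsampling seed, independent of worker scheduling."""
    return (seed ^ zlib.crc32(sv_id.encode())) & 0x7FFFFFFF


def _render_one(sv: SVCall, bam_paths, sample_names, annotation_path,
                out_dir, z, max_normals, seed, pad_fraction, min_pad,
                dpi) -> ManifestEntry:
    image = safe_image_name(sv.id)
    entry = ManifestEntry(image, sv.chrom, sv.start, sv.end, sv.svtype, sv.id)
    try:
        window = compute_window(sv, pad_fraction, min_pad)
        tracks = [gather_sample_evidence(path, window, z=z,
                                         max_normals=max_normals,
                                         seed=_sv_seed(seed, sv.id),
                                         sample_name=name)
                  for path, name in zip(bam_paths, sample_names)]
        annotations = ([load_gene_annotations(annotation_path, window)]
                       if annotation_path else [])
        render_sv_figure(FigureSpec(sv, window, tracks, annotations,
                                    out_path=os.path.join(out_dir, image),
                                    dpi=dpi))
    except Exception as exc:  # per-SV isolation: one bad call must not kill the batch
        logger.warning("render failed for %s: %s", sv.id, exc)
        entry.status = "render_failed"
    return entry


def render_batch(svs, bam_paths, sample_names, out_dir,
                 annotation_path: str | None = None, z: float = DEFAULT_Z,
                 max_normals: int = DEFAULT_MAX_NORMALS, seed: int = 0,
                 pad_fraction: float = DEFAULT_PAD_FRACTION,
                 min_pad: int = DEFAULT_MIN_PAD, dpi: int = DEFAULT_DPI,
                 workers: int = 1) -> list[ManifestEntry]:
    """Render one image per SV; failures are recorded, not raised.

    Rendering is independent per SV (each uses a seed derived from its id),
    so the output is identical for any worker count.
    """
    if len(bam_paths) != len(sample_names):
        raise ValueError("need one sample name per alignment file")
    os.makedirs(out_dir, exist_ok=True)
    args = [(sv, list(bam_paths), list(sample_names), annotation_path, out_dir,
             z, max_normals, seed, pad_fraction, min_pad, dpi) for sv in svs]
    if workers <= 1:
        return [_render_one(*a) for a in args]
    with concurrent.futures.ProcessPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(_render_one_star, args))


def _render_one_star(a):
    return _render_one(*a)
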