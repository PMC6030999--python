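"""Curation projects: questions, responses, scores, reports, annotated VCFs.

A curation project pairs a batch of SV images with a configurable question
and answer set.  Reviewers' answers are persisted in a single-file JSON
store; a *curation score* per image is computed by mapping each answer to a
numeric value and aggregating (mean, median, mode, sd, min or max).

Under the canonical 0/1 mapping with mean aggregation (e.g. GOOD and
DE NOVO -> 1, BAD -> 0), scores fall in [0, 1] and are classified:

* ``UNANIMOUS_HIGH`` / ``UNANIMOUS_LOW`` — score exactly 1 / exactly 0;
* ``UNAMBIGUOUS_HIGH`` / ``UNAMBIGUOUS_LOW`` — at most one dissenting vote
  (score > 0.8 / < 0.2);
* ``AMBIGUOUS`` — more than one dissenting vote (0.2 <= score <= 0.8).

Reports are tab-delimited; scores can also be written into a VCF as an
INFO tag (default ``SVP``), leaving every other byte of the file intact.
"""

from __future__ import annotations

import json
import logging
import os
import re
import statistics
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ConfigError, DegenerateInputError, FormatError
from .evidence import SVCall, synthesize_sv_id

logger = logging.getLogger(__name__)

AGGREGATIONS = ("mean", "median", "mode", "sd", "min", "max")

SCORE_CLASSES = ("UNANIMOUS_HIGH", "UNANIMOUS_LOW", "UNAMBIGUOUS_HIGH",
                 "UNAMBIGUOUS_LOW", "AMBIGUOUS")

#: the trio experiment's canonical answer->value map
TRIO_VALUE_MAP = {"GOOD": 1.0, "DE NOVO": 1.0, "BAD": 0.0}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurationConfig:
    """Question/answer scheme for one project."""

    project: str
    question: str
    answers: tuple
    key_bindings: dict
    reviewers: tuple = ()

    def __post_init__(self):
        if len(self.answers) < 2:
            raise ConfigError("answers: need at least 2 answer options")
        if len(set(self.answers)) != len(self.answers):
            raise ConfigError("answers: labels must be unique")
        keys = list(self.key_bindings.values())
        if len(set(keys)) != len(keys):
            raise ConfigError("keys: key bindings must be unique")
        if set(self.key_bindings) != set(self.answers):
            raise ConfigError("keys: need exactly one key per answer")


def load_curation_config(path: str) -> CurationConfig:
    """Parse a ``config.json`` with fields
    ``{"project", "curationQandA": {"question", "answers", "keys"}}``."""
    try:
        with open(path) as fh:
            raw = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"config is not valid JSON: {exc}") from exc
    try:
        qa = raw["curationQandA"]
        project, question = raw["project"], qa["question"]
        answers, keys = list(qa["answers"]), list(qa["keys"])
    except KeyError as exc:
        raise ConfigError(f"config missing field {exc.args[0]!r}") from exc
    if len(keys) != len(answers):
        raise ConfigError("keys: need exactly one key per answer")
    return CurationConfig(project=project, question=question,
                          answers=tuple(answers),
                          key_bindings=dict(zip(answers, keys)),
                          reviewers=tuple(raw.get("reviewers", ())))


# ---------------------------------------------------------------------------
# responses & store
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseRecord:
    """One reviewer's answer for one image."""

    image_id: str
    reviewer: str
    answer: str
    timestamp: float
    elapsed_seconds: float = 0.0

    def __post_init__(self):
        if self.elapsed_seconds < 0:
            raise ValueError("elapsed_seconds must be >= 0")


@dataclass
class ImageEntry:
    """One curated image and the SV call behind it."""

    id: str
    chrom: str
    start: int
    end: int
    svtype: str
    image: str = ""


class CurationStore:
    """Single-file JSON store for one project's images and responses."""

    def __init__(self, path: str, config: CurationConfig,
                 images: dict[str, ImageEntry], responses: list[ResponseRecord]):
        self.path = path
        self.config = config
        self.images = images
        self.responses = responses

    # -- persistence ---------------------------------------------------
    @classmethod
    def create(cls, path: str, config: CurationConfig,
               images: Iterable[ImageEntry]) -> "CurationStore":
        store = cls(path, config, {im.id: im for im in images}, [])
        store.save()
        return store

    @classmethod
    def load(cls, path: str) -> "CurationStore":
        with open(path) as fh:
            raw = json.load(fh)
        cfg = raw["config"]
        config = CurationConfig(project=cfg["project"], question=cfg["question"],
                                answers=tuple(cfg["answers"]),
                                key_bindings=dict(cfg["key_bindings"]),
                                reviewers=tuple(cfg.get("reviewers", ())))
        images = {i["id"]: ImageEntry(**i) for i in raw["images"]}
        responses = [ResponseRecord(**r) for r in raw["responses"]]
        return cls(path, config, images, responses)

    def save(self) -> None:
        cfg = self.config
        raw = {
            "config": {"project": cfg.project, "question": cfg.question,
                       "answers": list(cfg.answers),
                       "key_bindings": dict(cfg.key_bindings),
                       "reviewers": list(cfg.reviewers)},
            "images": [vars(im) for im in self.images.values()],
            "responses": [vars(r) for r in self.responses],
        }
        tmp = self.path + ".tmp"
        with open(tmp, "w") as fh:
            json.dump(raw, fh, indent=1)
        os.replace(tmp, self.path)

    # -- responses -----------------------------------------------------
    def record_response(self, record: ResponseRecord, save: bool = True) -> None:
        """Append a response; the latest answer per (image, reviewer) wins."""
        if record.image_id not in self.images:
            raise KeyError(f"unknown image_id {record.image_id!r}")
        if record.answer not in self.config.answers:
            raise ValueError(f"answer {record.answer!r} not in "
                             f"{self.config.answers}")
        self.responses.append(record)
        if save:
            self.save()

    def import_responses_tsv(self, path: str) -> tuple[int, list[str]]:
        """Merge a batch-response TSV; returns (accepted count, rejected lines)."""
        accepted, rejected = 0, []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expect = ["image_id", "reviewer", "answer", "timestamp",
                      "elapsed_seconds"]
            if header != expect:
                raise FormatError(f"unexpected response TSV header in {path}")
            for lineno, line in enumerate(fh, 2):
                f = line.rstrip("\n").split("\t")
                try:
                    rec = ResponseRecord(f[0], f[1], f[2], float(f[3]), float(f[4]))
                    self.record_response(rec, save=False)
                    accepted += 1
                except (IndexError, ValueError, KeyError) as exc:
                    logger.warning("%s:%d rejected: %s", path, lineno, exc)
                    rejected.append(f"line {lineno}: {exc}")
        self.save()
        return accepted, rejected

    def latest_responses(self) -> dict[str, dict[str, ResponseRecord]]:
        """image_id -> reviewer -> latest response (insertion order breaks
        timestamp ties)."""
        latest: dict[str, dict[str, ResponseRecord]] = {}
        for rec in self.responses:
            per_image = latest.setdefault(rec.image_id, {})
            prev = per_image.get(rec.reviewer)
            if prev is None or rec.timestamp >= prev.timestamp:
                per_image[rec.reviewer] = rec
        return latest


def export_responses_tsv(responses: Sequence[ResponseRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("image_id\treviewer\tanswer\ttimestamp\telapsed_seconds\n")
        for r in responses:
            fh.write(f"{r.image_id}\t{r.reviewer}\t{r.answer}\t"
                     f"{r.timestamp}\t{r.elapsed_seconds}\n")


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreMapping:
    """Answer->value map plus an aggregation function name."""

    value_map: dict
    aggregation: str = "mean"

    def __post_init__(self):
        if self.aggregation not in AGGREGATIONS:
            raise ConfigError(f"unknown aggregation {self.aggregation!r}")

    @property
    def is_binary_mean(self) -> bool:
        """True for the 0/1 mean mapping, for which score classes are defined."""
        return (self.aggregation == "mean"
                and set(self.value_map.values()) <= {0, 1, 0.0, 1.0})


@dataclass
class CurationScore:
    """Aggregated score for one image."""

    image_id: str
    n_responses: int
    answer_counts: dict
    score: float | None
    score_class: str | None = None


def aggregate_curation_score(responses: Sequence[str],
                             mapping: ScoreMapping) -> float:
    """Aggregate one image's answers into a score.

    Mode ties break toward the larger mapped value; sd is the population
    standard deviation.  Order of responses is irrelevant.
    """
    if not responses:
        raise DegenerateInputError("no responses to aggregate")
    try:
        values = [mapping.value_map[a] for a in responses]
    except KeyError as exc:
        raise ConfigError(f"answer {exc.args[0]!r} has no mapped value") from exc
    agg = mapping.aggregation
    if agg == "mean":
        return statistics.fmean(values)
    if agg == "median":
        return float(statistics.median(values))
    if agg == "mode":
        counts = Counter(values)
        best = max(counts.values())
        return float(max(v for v, c in counts.items() if c == best))
    if agg == "sd":
        return statistics.pstdev(values)
    if agg == "min":
        return float(min(values))
    return float(max(values))


def classify_curation_score(score: float) -> str:
    """Qualitative class of a 0/1-mean score (defined on [0, 1] only)."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    if score == 1.0:
        return "UNANIMOUS_HIGH"
    if score == 0.0:
        return "UNANIMOUS_LOW"
    if score > 0.8:
        return "UNAMBIGUOUS_HIGH"
    if score < 0.2:
        return "UNAMBIGUOUS_LOW"
    return "AMBIGUOUS"


def compute_scores(store: CurationStore, mapping: ScoreMapping) -> list[CurationScore]:
    """One CurationScore per image, ordered by (chrom, start); images with
    no responses get score None."""
    latest = store.latest_responses()
    out = []
    for im in sorted(store.images.values(), key=lambda i: (i.chrom, i.start, i.id)):
        per_image = latest.get(im.id, {})
        answers = [r.answer for r in per_image.values()]
        counts = {a: 0 for a in store.config.answers}
        for a in answers:
            counts[a] += 1
        if answers:
            score = aggregate_curation_score(answers, mapping)
            cls = (classify_curation_score(score)
                   if mapping.is_binary_mean else None)
        else:
            score, cls = None, None
        out.append(CurationScore(im.id, len(answers), counts, score, cls))
    return out


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def generate_report(store: CurationStore, mapping: ScoreMapping) -> list[list[str]]:
    """Tab-delimited report rows (header first), one row per image ordered
    by (chrom, start); unscored images keep an empty score field."""
    header = ["image_id", "chrom", "start", "end", "svtype", "n_responses"]
    header += [f"count_{a}" for a in store.config.answers]
    header += ["score", "score_class"]
    rows = [header]
    for sc in compute_scores(store, mapping):
        im = store.images[sc.image_id]
        row = [sc.image_id, im.chrom, str(im.start), str(im.end), im.svtype,
               str(sc.n_responses)]
        row += [str(sc.answer_counts[a]) for a in store.config.answers]
        row += ["" if sc.score is None else f"{sc.score:.4f}",
                sc.score_class or ""]
        rows.append(row)
    return rows


def write_report(store: CurationStore, mapping: ScoreMapping, path: str) -> None:
    rows = generate_report(store, mapping)
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# VCF annotation
# ---------------------------------------------------------------------------

def _record_image_id(fields: list[str]) -> str:
    """Image id for a VCF record: the ID column, else the synthesized id
    (same derivation the plotting step uses)."""
    if fields[2] not in (".", ""):
        return fields[2]
    info = fields[7]
    svtype = _info_get(info, "SVTYPE") or "DEL"
    end = _info_get(info, "END")
    start0 = int(fields[1]) - 1
    end0 = int(end) if end else start0 + 1
    return synthesize_sv_id(fields[0], start0, end0, svtype)


def _info_get(info: str, key: str) -> str | None:
    for item in info.split(";"):
        if item.startswith(key + "="):
            return item[len(key) + 1:]
    return None


def annotate_vcf_with_scores(in_path: str, scores, out_path: str,
                             tag: str = "SVP") -> None:
    """Copy a VCF, adding an INFO header line for ``tag`` and a per-record
    ``tag=<score to 4 decimals>`` for every scored record.

    ``scores`` is a {image_id: score} mapping or a list of
    :class:`CurationScore`.  Unscored records and all other file content
    are preserved byte for byte.
    """
    if not isinstance(scores, dict):
        scores = {s.image_id: s.score for s in scores if s.score is not None}
    header_line = (f'##INFO=<ID={tag},Number=1,Type=Float,'
                   f'Description="Curation score (aggregated reviewer answers)">')
    out_lines = []
    seen_records = False
    with open(in_path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("##fileformat"):
        raise FormatError(f"{in_path} does not look like a VCF")
    for line in lines:
        if line.startswith("#CHROM"):
            out_lines.append(header_line)
            out_lines.append(line)
            continue
        if line.startswith("#"):
            out_lines.append(line)
            continue
        seen_records = True
        fields = line.split("\t")
        if len(fields) < 8:
            raise FormatError(f"malformed VCF record: {line[:80]!r}")
        image_id = _record_image_id(fields)
        if image_id in scores and scores[image_id] is not None:
            entry = f"{tag}={scores[image_id]:.4f}"
            fields[7] = entry if fields[7] in (".", "") else fields[7] + ";" + entry
            out_lines.append("\t".join(fields))
        else:
            out_lines.append(line)
    with open(out_path, "w") as fh:
        fh.write("\n".join(out_lines) + "\n")


def strip_vcf_scores(in_path: str, out_path: str, tag: str = "SVP") -> None:
    """Inverse of :func:`annotate_vcf_with_scores`: drop the tag's header
    line and every per-record occurrence."""
    tag_re = re.compile(rf"(?:^|;){re.escape(tag)}=[^;]*")
    out_lines = []
    with open(in_path) as fh:
        lines = fh.read().splitlines()
    for line in lines:
        if line.startswith(f"##INFO=<ID={tag},"):
            continue
        if line.startswith("#"):
            out_lines.append(line)
            continue
        fields = line.split("\t")
        if len(fields) >= 8:
            info = tag_re.sub("", fields[7])
            info = info.lstrip(";")
            fields[7] = info if info else "."
            out_lines.append("\t".join(fields))
        else:
            out_lines.append(line)
    with open(out_path, "w") as fh:
        fh.write("\n".join(out_lines) + "\n")


# ---------------------------------------------------------------------------
# summary & concordance
# ---------------------------------------------------------------------------

@dataclass
class CurationSummary:
    """Cohort-level view of curation scores under the 0/1 mean mapping."""

    n_scored: int
    n_unscored: int
    n_excluded: int
    frac_unanimous_high: float
    frac_unanimous_low: float
    frac_unanimous: float
    frac_unambiguous: float
    frac_ambiguous: float
    median_size_all: float | None
    median_size_unanimous: float | None
    median_size_unambiguous: float | None
    median_size_ambiguous: float | None
    svtype_counts: dict = field(default_factory=dict)


def summarize_curation(scores: Sequence[CurationScore], svs: Sequence[SVCall],
                       exclusions: Sequence[str] = ()) -> CurationSummary:
    """Score-distribution summary after removing excluded images.

    Fractions are over *scored* images only; unscored images are counted
    separately.  "Unambiguous" (score < 0.2 or > 0.8) includes the
    unanimous images; "ambiguous" is the complement (0.2 <= score <= 0.8).
    Median sizes use end - start of the matching SV calls.
    """
    excluded = set(exclusions)
    sv_by_id = {sv.id: sv for sv in svs}
    kept = [s for s in scores if s.image_id not in excluded]
    scored = [s for s in kept if s.score is not None]
    if not scored:
        raise DegenerateInputError("no scored images after exclusions")
    n = len(scored)
    uh = [s for s in scored if s.score == 1.0]
    ul = [s for s in scored if s.score == 0.0]
    unamb = [s for s in scored if s.score < 0.2 or s.score > 0.8]
    amb = [s for s in scored if 0.2 <= s.score <= 0.8]

    def med_size(group):
        sizes = [sv_by_id[s.image_id].length for s in group
                 if s.image_id in sv_by_id]
        return float(statistics.median(sizes)) if sizes else None

    svtype_counts = Counter(sv_by_id[s.image_id].svtype for s in scored
                            if s.image_id in sv_by_id)
    return CurationSummary(
        n_scored=n, n_unscored=len(kept) - n, n_excluded=len(scores) - len(kept),
        frac_unanimous_high=len(uh) / n, frac_unanimous_low=len(ul) / n,
        frac_unanimous=(len(uh) + len(ul)) / n,
        frac_unambiguous=len(unamb) / n, frac_ambiguous=len(amb) / n,
        median_size_all=med_size(scored), median_size_unanimous=med_size(uh + ul),
        median_size_unambiguous=med_size(unamb), median_size_ambiguous=med_size(amb),
        svtype_counts=dict(svtype_counts))


@dataclass(frozen=True)
class OrthogonalCalls:
    """Independent genotype / copy-number calls keyed by image id."""

    genotype: dict = field(default_factory=dict)   # id -> hom_ref|het|hom_alt|missing
    copy_number: dict = field(default_factory=dict)  # id -> float | None


def load_orthogonal_calls(path: str) -> OrthogonalCalls:
    """TSV with columns image_id, genotype, copy_number ('.'/NA/missing ok)."""
    gt, cn = {}, {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["image_id", "genotype", "copy_number"]:
            raise FormatError(f"unexpected orthogonal-calls header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if f[1] in ("hom_ref", "het", "hom_alt"):
                gt[f[0]] = f[1]
            if len(f) > 2 and f[2] not in (".", "", "NA", "missing"):
                cn[f[0]] = float(f[2])
    return OrthogonalCalls(genotype=gt, copy_number=cn)


@dataclass
class ConcordanceResult:
    """Agreement between curation scores and orthogonal calls."""

    genotype_agreement: float | None
    cn_agreement: float | None
    n_genotype: int
    n_cn: int
    genotype_breakdown: dict = field(default_factory=dict)
    cn_breakdown: dict = field(default_factory=dict)


def concordance_with_orthogonal(scores: Sequence[CurationScore],
                                calls: OrthogonalCalls,
                                cn_band: tuple[float, float] = (1.4, 2.4)
                                ) -> ConcordanceResult:
    """Agreement of unambiguous deletion scores with genotype / copy number.

    Only scores < 0.2 or > 0.8 are eligible (the caller restricts to
    deletions).  A low score agrees with a homozygous-reference genotype or
    a copy number in the copy-neutral band; a high score agrees with a
    non-reference genotype or a copy number below the band.  Copy number
    above the band at a low score counts as disagreement; missing calls
    leave the denominator.
    """
    lo, hi = cn_band
    eligible = [s for s in scores if s.score is not None
                and (s.score < 0.2 or s.score > 0.8)]
    if not eligible:
        raise DegenerateInputError("no unambiguous scores for concordance")
    gt_break = {"low_agree": 0, "low_disagree": 0, "high_agree": 0,
                "high_disagree": 0}
    cn_break = dict(gt_break)
    for s in eligible:
        high = s.score > 0.8
        gt = calls.genotype.get(s.image_id)
        if gt in ("hom_ref", "het", "hom_alt"):
            agree = (gt != "hom_ref") if high else (gt == "hom_ref")
            gt_break[("high_" if high else "low_") + ("agree" if agree else "disagree")] += 1
        cn = calls.copy_number.get(s.image_id)
        if cn is not None:
            agree = (cn < lo) if high else (lo < cn <= hi)
            cn_break[("high_" if high else "low_") + ("agree" if agree else "disagree")] += 1
    n_gt = sum(gt_break.values())
    n_cn = sum(cn_break.values())
    return ConcordanceResult(
        genotype_agreement=((gt_break["low_agree"] + gt_break["high_agree"]) / n_gt
                            if n_gt else None),
        cn_agreement=((cn_break["low_agree"] + cn_break["high_agree"]) / n_cn
                      if n_cn else None),
        n_genotype=n_gt, n_cn=n_cn,
        genotype_breakdown=gt_break, cn_breakdown=cn_break)
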