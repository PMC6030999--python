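"""Tests for curation configuration, scoring, reports and VCF annotation."""

import json
import math

import pytest
from hypothesis import given, settings, strategies as st

from svcurate.curation import (
    CurationConfig,
    CurationScore,
    CurationStore,
    ImageEntry,
    OrthogonalCalls,
    ResponseRecord,
    ScoreMapping,
    TRIO_VALUE_MAP,
    aggregate_curation_score,
    annotate_vcf_with_scores,
    classify_curation_score,
    compute_scores,
    concordance_with_orthogonal,
    generate_report,
    load_curation_config,
    strip_vcf_scores,
    summarize_curation,
)
from svcurate.errors import ConfigError, DegenerateInputError
from svcurate.evidence import SVCall
from svcurate.synthetic import write_sv_vcf

MEAN01 = ScoreMapping(value_map=dict(TRIO_VALUE_MAP), aggregation="mean")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def test_trio_config_loads(trio_config_json):
    cfg = load_curation_config(trio_config_json)
    assert cfg.answers == ("GOOD", "BAD", "DE NOVO")
    assert cfg.key_bindings == {"GOOD": "g", "BAD": "b", "DE NOVO": "d"}


def test_cancer_config_loads(tmp_path):
    path = tmp_path / "cancer.json"
    path.write_text(json.dumps({
        "project": "tumor-normal",
        "curationQandA": {
            "question": "In which samples does the SV appear?",
            "answers": ["TUMOR", "BOTH", "NORMAL", "NEITHER"],
            "keys": ["t", "b", "n", "x"]}}))
    cfg = load_curation_config(str(path))
    assert len(cfg.answers) == 4


@pytest.mark.parametrize("answers,keys,msg", [
    (["GOOD", "BAD"], ["g", "g"], "keys"),
    (["GOOD", "GOOD"], ["g", "b"], "answers"),
    (["GOOD"], ["g"], "answers"),
    (["GOOD", "BAD"], ["g"], "keys"),
])
def test_invalid_config_rejected(tmp_path, answers, keys, msg):
    path = tmp_path / "bad.json"
    path.write_text(json.dumps({
        "project": "p", "curationQandA":
            {"question": "q?", "answers": answers, "keys": keys}}))
    with pytest.raises(ConfigError, match=msg):
        load_curation_config(str(path))


def test_missing_field_named_in_error(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text(json.dumps({"project": "p"}))
    with pytest.raises(ConfigError, match="curationQandA"):
        load_curation_config(str(path))


# ---------------------------------------------------------------------------
# store & responses
# ---------------------------------------------------------------------------

@pytest.fixture()
def store(tmp_path, trio_config_json):
    cfg = load_curation_config(trio_config_json)
    images = [ImageEntry("sv1", "chr1", 100, 600, "DEL", "sv1.png"),
              ImageEntry("sv2", "chr2", 200, 900, "DUP", "sv2.png")]
    return CurationStore.create(str(tmp_path / "store.json"), cfg, images)


def test_record_response_and_supersession(store):
    store.record_response(ResponseRecord("sv1", "alice", "GOOD", 1.0))
    scores = compute_scores(store, MEAN01)
    assert scores[0].n_responses == 1 and scores[0].score == 1.0
    # same reviewer re-scores: latest answer wins, count stays 1
    store.record_response(ResponseRecord("sv1", "alice", "BAD", 2.0))
    scores = compute_scores(store, MEAN01)
    assert scores[0].n_responses == 1 and scores[0].score == 0.0


def test_unknown_image_and_invalid_answer_rejected(store):
    with pytest.raises(KeyError):
        store.record_response(ResponseRecord("nope", "alice", "GOOD", 1.0))
    with pytest.raises(ValueError):
        store.record_response(ResponseRecord("sv1", "alice", "MAYBE", 1.0))


def test_store_round_trip(store):
    store.record_response(ResponseRecord("sv1", "alice", "GOOD", 1.0))
    loaded = CurationStore.load(store.path)
    assert loaded.config == store.config
    assert loaded.responses == store.responses
    assert set(loaded.images) == {"sv1", "sv2"}


def test_import_responses_rejects_bad_rows(store, tmp_path):
    tsv = tmp_path / "resp.tsv"
    tsv.write_text(
        "image_id\treviewer\tanswer\ttimestamp\telapsed_seconds\n"
        "sv1\talice\tGOOD\t1.0\t2.0\n"
        "sv1\tbob\tMAYBE\t1.5\t2.0\n"       # invalid answer
        "ghost\tcarol\tGOOD\t2.0\t2.0\n")   # unknown image
    accepted, rejected = store.import_responses_tsv(str(tsv))
    assert accepted == 1 and len(rejected) == 2


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("answers,mapping,expected", [
    (["GOOD"] * 9, MEAN01, 1.0),
    (["GOOD"] * 5 + ["BAD"] * 4, MEAN01, 5 / 9),
    (["BAD"] * 9, MEAN01, 0.0),
    (["GOOD", "DE NOVO", "BAD"], MEAN01, 2 / 3),
    (["TUMOR", "TUMOR", "BOTH"],
     ScoreMapping({"TUMOR": 3, "BOTH": 2, "NORMAL": 1, "NEITHER": 0}, "mode"),
     3.0),
    (["TUMOR", "BOTH", "NORMAL", "NEITHER"],
     ScoreMapping({"TUMOR": 3, "BOTH": 2, "NORMAL": 1, "NEITHER": 0}, "mode"),
     3.0),  # four-way tie breaks toward the larger value
    (["GOOD", "BAD"], ScoreMapping(TRIO_VALUE_MAP, "median"), 0.5),
    (["GOOD", "BAD", "BAD"], ScoreMapping(TRIO_VALUE_MAP, "min"), 0.0),
    (["GOOD", "BAD", "BAD"], ScoreMapping(TRIO_VALUE_MAP, "max"), 1.0),
])
def test_aggregate_examples(answers, mapping, expected):
    assert aggregate_curation_score(answers, mapping) == pytest.approx(expected)


def test_aggregate_sd_is_population_sd():
    mapping = ScoreMapping(TRIO_VALUE_MAP, "sd")
    got = aggregate_curation_score(["GOOD", "GOOD", "BAD", "BAD"], mapping)
    assert got == pytest.approx(0.5)  # population sd of [1,1,0,0]


def test_aggregate_empty_raises():
    with pytest.raises(DegenerateInputError):
        aggregate_curation_score([], MEAN01)


@given(answers=st.lists(st.sampled_from(["GOOD", "BAD", "DE NOVO"]),
                        min_size=1, max_size=30),
       agg=st.sampled_from(["mean", "median", "mode", "min", "max"]))
@settings(deadline=None)
def test_score_bounds_and_permutation_invariance(answers, agg):
    """Any [0,1]-valued map with a non-sd aggregation yields a score in
    [0,1], independent of response order."""
    mapping = ScoreMapping(dict(TRIO_VALUE_MAP), agg)
    score = aggregate_curation_score(answers, mapping)
    assert 0.0 <= score <= 1.0
    assert aggregate_curation_score(list(reversed(answers)), mapping) == score
    assert aggregate_curation_score(sorted(answers), mapping) == score


# ---------------------------------------------------------------------------
# score classes
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("score,expected", [
    (1.0, "UNANIMOUS_HIGH"),
    (0.0, "UNANIMOUS_LOW"),
    (8 / 9, "UNAMBIGUOUS_HIGH"),   # one dissent in nine
    (1 / 9, "UNAMBIGUOUS_LOW"),
    (0.5, "AMBIGUOUS"),
    (0.2, "AMBIGUOUS"),            # inclusive bounds
    (0.8, "AMBIGUOUS"),
])
def test_score_class_examples(score, expected):
    assert classify_curation_score(score) == expected


def test_score_class_rejects_out_of_range():
    with pytest.raises(ValueError):
        classify_curation_score(1.01)
    with pytest.raises(ValueError):
        classify_curation_score(-0.01)


@given(score=st.one_of(st.floats(0, 1), st.sampled_from([0.0, 0.2, 0.8, 1.0])))
def test_score_class_partitions_unit_interval(score):
    """Every score in [0,1] gets exactly one of the five classes, and the
    classes tile the interval consistently."""
    cls = classify_curation_score(score)
    assert cls in ("UNANIMOUS_HIGH", "UNANIMOUS_LOW", "UNAMBIGUOUS_HIGH",
                   "UNAMBIGUOUS_LOW", "AMBIGUOUS")
    if cls == "UNANIMOUS_HIGH":
        assert score == 1.0
    elif cls == "UNANIMOUS_LOW":
        assert score == 0.0
    elif cls == "UNAMBIGUOUS_HIGH":
        assert 0.8 < score < 1.0
    elif cls == "UNAMBIGUOUS_LOW":
        assert 0.0 < score < 0.2
    else:
        assert 0.2 <= score <= 0.8


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def test_report_rows_counts_and_unscored(store):
    store.record_response(ResponseRecord("sv1", "alice", "GOOD", 1.0))
    store.record_response(ResponseRecord("sv1", "bob", "GOOD", 1.1))
    store.record_response(ResponseRecord("sv1", "carol", "GOOD", 1.2))
    rows = generate_report(store, MEAN01)
    header, r1, r2 = rows
    assert header[:6] == ["image_id", "chrom", "start", "end", "svtype",
                          "n_responses"]
    assert r1[0] == "sv1" and r1[5] == "3"
    assert r1[header.index("count_GOOD")] == "3"
    assert r1[header.index("score")] == "1.0000"
    # sv2 never scored: present with empty score
    assert r2[0] == "sv2" and r2[5] == "0" and r2[header.index("score")] == ""


def test_report_conserves_latest_response_counts(store):
    store.record_response(ResponseRecord("sv1", "alice", "GOOD", 1.0))
    store.record_response(ResponseRecord("sv1", "alice", "BAD", 2.0))  # supersedes
    store.record_response(ResponseRecord("sv2", "bob", "GOOD", 1.0))
    rows = generate_report(store, MEAN01)
    header = rows[0]
    count_cols = [i for i, h in enumerate(header) if h.startswith("count_")]
    total = sum(int(r[i]) for r in rows[1:] for i in count_cols)
    assert total == 2  # distinct (image, reviewer) latest responses


# ---------------------------------------------------------------------------
# VCF annotation
# ---------------------------------------------------------------------------

@pytest.fixture()
def sv_vcf(tmp_path):
    svs = [SVCall("chr1", 100, 600, "DEL", id="sv1"),
           SVCall("chr2", 200, 900, "DUP", id="sv2"),
           SVCall("chr3", 300, 800, "INV", id="sv3")]
    path = str(tmp_path / "in.vcf")
    write_sv_vcf(svs, path, contig_length=10_000)
    return path, svs


def test_annotate_adds_header_and_tags(sv_vcf, tmp_path):
    in_path, _ = sv_vcf
    out = str(tmp_path / "out.vcf")
    annotate_vcf_with_scores(in_path, {"sv1": 1.0, "sv3": 5 / 9}, out)
    lines = open(out).read().splitlines()
    assert any(l.startswith("##INFO=<ID=SVP,Number=1,Type=Float") for l in lines)
    recs = {l.split("\t")[2]: l.split("\t")[7] for l in lines
            if not l.startswith("#")}
    assert recs["sv1"].endswith(";SVP=1.0000")
    assert "SVP" not in recs["sv2"]           # unscored record untouched
    assert recs["sv3"].endswith(";SVP=0.5556")


def test_annotate_strip_round_trip_is_identity(sv_vcf, tmp_path):
    in_path, _ = sv_vcf
    out = str(tmp_path / "out.vcf")
    back = str(tmp_path / "back.vcf")
    annotate_vcf_with_scores(in_path, {"sv1": 1.0, "sv2": 0.0}, out)
    strip_vcf_scores(out, back)
    assert open(back, "rb").read() == open(in_path, "rb").read()


def test_annotate_synthesized_id_matches_plot_rule(tmp_path):
    # record with ID "." must map through chrom_start_end_svtype
    vcf = tmp_path / "noid.vcf"
    vcf.write_text("##fileformat=VCFv4.2\n"
                   '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
                   '##INFO=<ID=END,Number=1,Type=Integer,Description="e">\n'
                   "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
                   "chr1\t101\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=600\n")
    out = str(tmp_path / "out.vcf")
    annotate_vcf_with_scores(str(vcf), {"chr1_100_600_DEL": 0.25}, out)
    rec = [l for l in open(out) if not l.startswith("#")][0]
    assert rec.rstrip().endswith("SVP=0.2500")


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def _score(image_id, value):
    return CurationScore(image_id, 9, {}, value,
                         classify_curation_score(value) if value is not None
                         else None)


def test_summary_known_fractions():
    """10 SVs: 7 unanimous-high, 1 unanimous-low, 2 ambiguous."""
    svs = [SVCall("chr1", i * 1000, i * 1000 + 500 + i, "DEL", id=f"s{i}")
           for i in range(10)]
    values = [1.0] * 7 + [0.0] + [0.5] * 2
    scores = [_score(f"s{i}", v) for i, v in enumerate(values)]
    summary = summarize_curation(scores, svs)
    assert summary.frac_unanimous == pytest.approx(0.8)
    assert summary.frac_unanimous_high == pytest.approx(0.7)
    assert summary.frac_unanimous_low == pytest.approx(0.1)
    assert summary.frac_unambiguous == pytest.approx(0.8)
    assert summary.frac_ambiguous == pytest.approx(0.2)
    assert summary.frac_unambiguous + summary.frac_ambiguous == pytest.approx(1.0)
    assert summary.svtype_counts == {"DEL": 10}
    # ambiguous stratum: s8 (508) and s9 (509) -> median 508.5
    assert summary.median_size_ambiguous == pytest.approx(508.5)


def test_summary_all_unanimous_leaves_ambiguous_median_empty():
    svs = [SVCall("chr1", 0, 500, "DEL", id="a"),
           SVCall("chr1", 1000, 1700, "DEL", id="b")]
    scores = [_score("a", 1.0), _score("b", 1.0)]
    summary = summarize_curation(scores, svs)
    assert summary.frac_unanimous == 1.0
    assert summary.median_size_ambiguous is None


def test_summary_exclusions_and_degenerate():
    svs = [SVCall("chr1", 0, 500, "DEL", id="a")]
    scores = [_score("a", 1.0)]
    with pytest.raises(DegenerateInputError):
        summarize_curation(scores, svs, exclusions=["a"])
    summary = summarize_curation(scores + [_score("b", 0.5)], svs,
                                 exclusions=["b"])
    assert summary.n_excluded == 1 and summary.n_scored == 1


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def test_concordance_examples():
    scores = [_score("hi", 1.0), _score("lo", 0.0)]
    calls = OrthogonalCalls(genotype={"hi": "het", "lo": "hom_ref"},
                            copy_number={"hi": 1.0, "lo": 2.0})
    res = concordance_with_orthogonal(scores, calls)
    assert res.genotype_agreement == 1.0 and res.cn_agreement == 1.0
    # cn 1.0 at score 0 is an orthogonal false positive -> disagreement
    calls2 = OrthogonalCalls(copy_number={"lo": 1.0})
    res2 = concordance_with_orthogonal([_score("lo", 0.0)], calls2)
    assert res2.cn_agreement == 0.0
    assert res2.cn_breakdown["low_disagree"] == 1


def test_concordance_hand_tallied_eight_of_ten():
    scores = [_score(f"s{i}", 1.0 if i < 6 else 0.0) for i in range(10)]
    gt = {f"s{i}": "het" for i in range(5)}          # s0-s4 agree (high, non-ref)
    gt["s5"] = "hom_ref"                             # disagree (high, ref)
    gt.update({f"s{i}": "hom_ref" for i in range(6, 9)})  # s6-s8 agree
    gt["s9"] = "het"                                 # disagree (low, non-ref)
    res = concordance_with_orthogonal(scores, OrthogonalCalls(genotype=gt))
    assert res.n_genotype == 10
    assert res.genotype_agreement == pytest.approx(0.8)


def test_concordance_excludes_ambiguous_and_missing():
    scores = [_score("a", 1.0), _score("b", 0.5), _score("c", 0.0)]
    calls = OrthogonalCalls(genotype={"a": "hom_alt"})  # b ambiguous, c missing
    res = concordance_with_orthogonal(scores, calls)
    assert res.n_genotype == 1 and res.genotype_agreement == 1.0
    with pytest.raises(DegenerateInputError):
        concordance_with_orthogonal([_score("b", 0.5)], calls)
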