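# svcurate

Manual curation is still the most reliable quality-control step for
structural-variant (SV) call sets: the human eye separates a genuine
deletion, duplication or inversion signal from alignment artifacts faster
and more robustly than any single caller. `svcurate` is an offline toolkit
for doing that at call-set scale:

* **evidence** — extract paired-end alignments, split-read alignments and
  per-base coverage from indexed BAM/CRAM files for the window around each
  candidate SV, and classify every observation by the SV type its geometry
  supports (discordant-pair conventions for Illumina forward–reverse
  libraries: `(+,-)` pairs with an outer span above `mean + Z·sd` support a
  deletion, everted `(-,+)` pairs a tandem duplication, `(+,+)`/`(-,-)`
  pairs the two inversion orientations; concordant pairs are downsampled).
* **render** — draw one image per SV: an SV locator bar, one stacked panel
  per sample (pairs as solid lines with square ends, splits as dashed lines
  with circle ends, placed by genomic position and outer span, colored by
  supported SV type; coverage as a grey profile on a right axis), and an
  optional gene/annotation track, all sharing the x-axis.
* **curation** — manage a local curation project: a JSON question/answer
  configuration, a single-file response store, *curation scores* (an
  answer→value map plus an aggregation: mean, median, mode, sd, min, max),
  qualitative score classes, tab-delimited reports, `SVP`-annotated VCFs,
  and concordance analysis against orthogonal genotype/copy-number calls.
* **synthetic** — generate fully deterministic trio BAMs with planted
  DEL/DUP/INV signatures (inflated-span pairs, everted pairs, same-strand
  breakpoint pairs, `SA`-tagged split reads, coverage dips/gains) plus
  simulated reviewer responses, so the entire pipeline is testable with no
  data downloads.

The curation score of an image with responses $a_1,\dots,a_n$ under a value
map $v$ and the mean aggregation is $s = \tfrac1n\sum_i v(a_i)$. With the
canonical trio mapping (`GOOD`, `DE NOVO` → 1, `BAD` → 0), scores are
classed as *unanimous* ($s \in \{0, 1\}$), *unambiguous* (at most one
dissenting vote: $s < 0.2$ or $s > 0.8$) or *ambiguous*
($0.2 \le s \le 0.8$).

## Worked example

```bash
# 1. make a synthetic trio fixture: 2 DELs, 2 DUPs, 2 INVs
svcurate simulate -o demo --n-del 2 --n-dup 2 --n-inv 2 --seed 7
# -> "6 SVs x 3 samples -> demo"

# 2. render one evidence image per SV (child on top)
svcurate plot -v demo/svs.vcf -o demo/img \
    -b demo/child.bam -n child -b demo/father.bam -n father \
    -b demo/mother.bam -n mother --seed 3
# -> "rendered 6/6 images -> demo/img"

# 3. start a curation project and import reviewer answers
svcurate project init --config config.json \
    --manifest demo/img/manifest.tsv --store demo/project.json
# -> "project 'trio-demo' with 6 images -> demo/project.json"
svcurate project import-responses --store demo/project.json \
    --responses responses.tsv
# -> "imported 54 responses (0 rejected)"

# 4. report and annotate
svcurate project report --store demo/project.json --out demo/report.tsv
svcurate project annotate --store demo/project.json \
    --vcf demo/svs.vcf --out demo/svs.svp.vcf
# -> "annotated 6 records with SVP -> demo/svs.svp.vcf"
```

`config.json` follows the `{"project", "curationQandA": {"question",
"answers", "keys"}}` schema, e.g. answers `["GOOD", "BAD", "DE NOVO"]` with
keys `["g", "b", "d"]`. The report has one row per image — its SV
coordinates, the number of responses, one count column per answer, the
score and its class; a unanimously-GOOD image shows `score 1.0000,
UNANIMOUS_HIGH`. The annotated VCF is byte-identical to the input except
for the added `##INFO=<ID=SVP,...>` header line and per-record
`SVP=<score>` entries.

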