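# ecbench

Gold-standard generation and base-resolution evaluation for sequencing
error-correction tools.

Computational error correction promises to remove sequencing errors from
short-read data before downstream analysis, but judging whether a tool
helped requires knowing, for every base of every read, what the correct
base actually was. `ecbench` builds that ground truth three ways and
then scores any corrected read set against it:

- **Simulation** — a wgsim-style paired-end simulator that emits each
  read twice: with substitution errors and error-free, with the origin
  and per-mate error counts encoded in the read name.
- **UMI consensus** — reads sharing a unique molecular identifier are
  collapsed by per-position majority vote; a base needs ≥ 80% support,
  and a single under-supported position discards the whole cluster so
  genuine low-frequency variants are never voted away.
- **Haplotype assignment** — for reads from a known mixture of viral
  haplotypes, each read's truth is the minimum-mismatch haplotype window
  beneath it; editors for error-rate titration and haplotype-diversity
  reduction produce controlled dataset series.

Evaluation aligns each (true, raw, corrected) trio into one three-row
alignment and labels every column: TN (correct base untouched), TP
(error fixed), FP (correct base broken), FN (error ignored), FN_WRONG
(error changed to another wrong base), FP_INDEL (tool-introduced
insertion/deletion), TP_TRIM / FP_TRIM (terminal trimming of an
erroneous / correct base). With FN_all = FN + FN_WRONG and
FP_all = FP + FP_INDEL, the reported metrics are

    precision   = TP / (TP + FP_all)
    sensitivity = TP / (TP + FN_all)
    gain        = (TP − FP_all) / (TP + FN_all)
    trim %      = (TP_TRIM + FP_TRIM) / total bases
    trim eff.   = TP_TRIM / (TP_TRIM + FP_TRIM)
    f-score     = 2·P·S / (P + S)

Gain is the headline number: 1.0 means every error fixed and nothing
broken, 0 is neutral, negative means the tool did net harm.

The intended user runs an error-correction tool on the raw FASTQ, then
points `ecbench` at the true/raw/corrected files. Audience: method
developers benchmarking correction tools, and anyone who needs a
quantitative answer to "did error correction help on data like mine".

## Worked example

```
ecbench tcr-panel --n-transcripts 3 --transcript-len 1000 --seed 7 --out panel.fa
ecbench simulate --ref panel.fa --coverage 8 --read-len 100 --frag-mean 200 \
    --err-rate 0.01 --seed 7 --out-prefix sim
cat sim.true.1.fq sim.true.2.fq > true.fq
cat sim.raw.1.fq  sim.raw.2.fq  > raw.fq
# a perfect "tool" for illustration: hand the true reads back as corrected
ecbench evaluate --true true.fq --raw raw.fq --corrected true.fq \
    --out records.csv --totals totals.json
```

This prints `simulated 120 pairs -> sim.*.fq` and
`evaluated 240 reads -> records.csv`. `totals.json` then contains

```
"tp": 210, "fp": 0, "fn": 0, "tn": 23790, "total_bases": 24000,
"precision": 1.0, "sensitivity": 1.0, "gain": 1.0
```

meaning: the 24,000 raw bases carried 210 substitution errors, all 210
were fixed and no correct base was changed, so precision, sensitivity
and gain are all exactly 1.0 — the expected result when the corrected
reads equal the truth. Re-running with `--corrected raw.fq` (a tool that
changes nothing) gives `tp = fp = 0`, all 210 errors counted as FN, and
gain exactly 0.0. `records.csv` holds one line per read with ≥ 1 event,
e.g.

```
tcr_transcript_1_107_290_0:0:0_2:0:0_14/2,100,2,0,0,0,0,0,0
```

(a 100 bp read whose 2 errors were both corrected). With a BED file of
genome categories, `ecbench report --records records.csv --bed cats.bed
--out summary.csv` breaks the same metrics out per category (reads
overlapping no interval are reported under "normal").

The UMI and haplotype routes mirror this flow from real data:

```
ecbench umi-consensus --in umi_reads.fq --umi-prefix 12 --threshold 0.8 \
    --min-size 3 --out-true true.fq --out-raw raw.fq --report report.json
ecbench hap-truth --reads reads.fq --haplotypes haps.fa \
    --out-true true.fq --out-raw kept.fq
ecbench hap-titrate  --raw kept.fq --true true.fq --target-rate 0.0033 --seed 7 --out titrated.fq
ecbench hap-diversity --hap-a 89.6 --hap-b YU2 --haplotypes haps.fa --reads kept.fq \
    --target-hamming 0.002 --seed 7 --out-haplotypes haps2.fa --out-reads reads2.fq
```

Everything is also available as a library (`import ecbench`); the CLI is
a thin wrapper.

## Layout

- `src/ecbench/io_formats.py` — FASTQ/FASTA/BED I/O, wgsim-name parsing,
  UMI extraction, compressed evaluation-record format
- `src/ecbench/read_simulator.py` — simulator and synthetic fixture
  generators (UMI clusters, haplotype mixtures)
- `src/ecbench/gold_standard_umi.py` — UMI clustering and consensus
- `src/ecbench/gold_standard_haplotype.py` — haplotype assignment,
  titration, diversity reduction
- `src/ecbench/evaluation_core.py` — trio alignment and base
  classification
- `src/ecbench/metrics_report.py` — metrics, stratification, reports
- `docs/methods.md` — models, parameters, numerical choices, limitations
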