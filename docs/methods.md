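# Methods

`ecbench` evaluates computational error correction of short sequencing
reads at base resolution. The core idea: if every raw read is paired
with an error-free ("true") copy of itself, then any corrected read set
can be scored by aligning each (true, raw, corrected) trio and labelling
every base by what the correction tool did to it. The package provides
three routes to such gold-standard pairs, the classifier itself, and the
summary metrics.

## Gold-standard construction

### Simulation (wgsim-style)

`read_simulator.simulate_reads` draws paired-end fragments from a
reference and emits both the erroneous and the error-free copy of each
read. Per reference sequence of length L, the number of pairs is
`round(L * coverage / (2 * read_len))`. Fragment starts are uniform over
valid positions; fragment lengths are a rounded normal truncated to
`[read_len, L]` by rejection sampling (up to 1000 draws, then clipped) —
rejection rather than clipping keeps the realized mean unbiased when the
bounds are far from the mean, which they are at the defaults. Mate 1 is
the fragment's left end; mate 2 is the reverse complement of its right
end. Substitution errors are injected independently per base at
`err_rate`, with the replacement uniform over the three alternative
bases, so the per-mate error counts embedded in the read names are exact.
Defaults (100 bp reads, 200 bp mean fragment, 1% error) follow common
short-read settings for immune-repertoire simulation; `frag_std`
defaults to 10% of the mean, which is stated only as a mean in the
protocols this emulates. Template mutations (`mut_rate`, default 0) are
applied before read extraction and appear in both copies: they model
genuine variants and are never scored as errors. Only substitution
sequencing errors are simulated; the classifier handles indels and
trimming in *corrected* reads regardless.

Read names follow the wgsim grammar
`chrom_pos1_pos2_e1:0:0_e2:0:0_counter/mate` with 1-based outer fragment
coordinates and a decimal global pair counter. Chromosome names may
contain underscores; the parser takes the six structural tokens from the
right.

### UMI consensus

`gold_standard_umi` groups reads by exact UMI (sequence prefix of a
configurable length, or a header-token regex — library designs differ
and neither placement is universal) and calls a per-position majority
consensus. A position's modal base is accepted iff its fraction of the
voting members is ≥ `threshold` (default 0.8, compared inclusively, so
exactly 80% support passes); if any position fails, the entire cluster
is discarded — this is what protects genuine low-frequency variants from
being voted away, at the cost of throwing away reads. The threshold must
exceed 0.5 so the winning base is unique. Clusters below `min_size`
(default 3) are discarded: a singleton "consensus" cannot correct
anything, and 3 is the conventional floor for UMI-consensus protocols.
Members whose length differs from the cluster's modal length are dropped
from the vote (ties toward the shorter length) rather than aligned — the
protocol targets fixed-length amplicon reads, and aligning stragglers
would invent structure the data should not have. Qualities are ignored:
the vote is a pure base-count majority. Output modes: `per-read`
(default) emits one (raw payload, consensus) pair per voting member so
evaluation runs against the original raw reads; `per-cluster`
deduplicates to one pair per cluster (first member by name as the raw
representative).

### Haplotype assignment (viral mixtures)

For reads drawn from a known mixture of closely related genomes
(intra-host viral populations), `gold_standard_haplotype.assign_read`
places each read on every haplotype, both strands, by a mismatch-only
semi-global scan (read fully inside the haplotype, free ends on the
haplotype) and keeps the placement with the fewest mismatches. Ties
break by haplotype input order, then leftmost offset, then '+' strand.
Mismatch-only placement is deliberate: the error-free read is defined
positionally as the haplotype window under the read, so indel-bearing
placements would have no well-defined truth; reads whose best placement
exceeds `max_mismatch_frac` (default 0.1) are dropped as unmapped, which
is where indel-requiring reads end up.

Two dataset editors support sensitivity studies:

- **Error-rate titration** (`titrate_error_rate`): all error positions
  across the dataset are pooled; a uniform random subset is reverted to
  the true base so that exactly `round(target_rate * total_bases)`
  errors remain. Operating dataset-wide (not per read) matches how such
  error-rate series are reported. Raising the rate is refused.
- **Diversity reduction** (`reduce_haplotype_diversity`): for two
  equal-length, column-comparable haplotypes A and B, a uniform random
  subset of their differing columns is set in B to A's base until the
  Hamming fraction equals `round(target * L) / L`. Reads assigned to B
  receive the same replacement at covered positions, with one guard: a
  read base that was a sequencing error before the edit is re-drawn
  uniformly from the three bases different from the new truth, so the
  edit never silently repairs an error and per-read error counts are
  preserved exactly. For haplotypes of unequal length,
  `align_haplotypes` (unit-cost global alignment via edlib) and
  `aligned_hamming_fraction` (gap columns excluded) prepare the inputs;
  the columnwise editors themselves require equal lengths.

## Base classification

`evaluation_core.align_trio` builds one gapped three-row alignment per
trio in two deterministic stages: a global Needleman–Wunsch alignment of
true vs raw, then a global alignment of the corrected sequence against
the resulting two-row column profile (a corrected symbol scores the mean
of its match/mismatch scores against the two member symbols; a gap
member contributes the gap weight). A dedicated multiple-sequence
aligner would also work here, but a built-in engine with fixed
tie-breaking (diagonal > up > left) makes results reproducible to the
byte with no external binary. For users who prefer a conventional MSA
engine, `align_trio_msa` (CLI `--msa-exec`) shells out to any program
that takes a three-record FASTA path and prints the aligned FASTA on
stdout (e.g. `mafft --quiet`); the adapter verifies that the gapped rows
reproduce the inputs.

Scoring defaults to match +1 / mismatch −1 / gap −5, plus an
infinitesimal (1e-9, far below the 0.5 score granularity) extra penalty
on gap moves. The stiff gap penalty is load-bearing: raw reads are
positionally paired with their error-free templates, so for equal-length
substitution-only trios the correct alignment is gap-free — under a mild
penalty (e.g. −2), runs of clustered errors occasionally buy a
scoring-equivalent or better gapped alignment and corrupt the counts,
which a 10^4-trio equivalence test against a positionwise classifier
exposes. With the defaults, gaps appear only when sequence lengths
genuinely differ (tool indels or trimming).

Each column (t, r, c over {A,C,G,T,N,-}) receives exactly one label:

| condition | label |
|---|---|
| r = c ≠ '-', r = t | TN |
| r = c ≠ '-', r ≠ t | FN |
| r, c bases, c ≠ r, c = t | TP |
| r, c bases, c ≠ r, c ≠ t, r = t | FP |
| r, c bases, c ≠ r, c ≠ t, r ≠ t | FN_WRONG |
| c = '-' in a terminal gap run, r ≠ t | TP_TRIM |
| c = '-' in a terminal gap run, r = t | FP_TRIM |
| c = '-' interior, t = '-' | TP (inserted base removed) |
| c = '-' interior, r = t | FP_INDEL |
| c = '-' interior, r ≠ t ≠ '-' | FN_WRONG |
| r = '-', c = t | TP (deleted base restored) |
| r = '-', c ≠ t | FP_INDEL |
| r = '-', c = '-' | non-scoring |

Terminal trim runs are the maximal leading and trailing gap runs of the
corrected row only. N matches only itself, so an N written over a
correct base is FP. The raw-gap/corrected-gap column is non-scoring
because the base was never presented to the tool.

`evaluate_dataset` matches reads by name across the three inputs (mate
suffixes make paired-end names unique, so each mate is scored as an
independent single-end read), requires identical name sets for true and
raw, refuses corrected reads absent from the truth set, and handles
corrected-set dropouts by `missing_policy`: `skip` (default, counted and
listed) or `as-trimmed` (every raw base becomes TP_TRIM/FP_TRIM by its
error status). Records are processed in sorted name order, so output is
invariant to input order.

## Records and metrics

Per-read counts are stored as one CSV line —
`read_name,length,TP,FN,FN_WRONG,FP,FP_INDEL,FP_TRIM,TP_TRIM` — written
only for reads with at least one event; all-TN reads contribute to
dataset totals (TN, total bases) but not to the file. A single leading
`#` comment names the field order. TN is not a column: when records are
re-read, TN is inferred as `length` minus the scored substitution and
trim events.

With FN_all = FN + FN_WRONG and FP_all = FP + FP_INDEL:

- precision = TP / (TP + FP_all)
- sensitivity = TP / (TP + FN_all)
- gain = (TP − FP_all) / (TP + FN_all)
- trim percent = (TP_TRIM + FP_TRIM) / total bases
- trim efficiency = TP_TRIM / (TP_TRIM + FP_TRIM)
- f-score = 2·P·S / (P + S) (harmonic mean of the above precision and
  sensitivity; used as the single balance figure)

Every zero-denominator case returns 0. Algebraically, gain ≤ sensitivity
≤ 1 and all ratio metrics sit in [0, 1]; gain alone can go negative
(tool did more harm than good). Tables round metrics to 4 decimals; JSON
output keeps full precision.

`stratify_by_category` assigns each read's counts to every BED category
whose interval overlaps the read's origin fragment (from its wgsim-style
name or an explicit lookup table); reads overlapping nothing go to
"normal", unparseable origins to "unassigned" (or an error in strict
mode). Because a read can overlap several categories, category rows need
not sum to the global totals.

## What the synthetic generators do and do not emulate

The fixture generators produce i.i.d. uniform reference sequence,
uniform fragment placement, position-independent substitution errors,
and exactly known truth. Real data has composition bias, coverage
nonuniformity, quality-correlated and strand-correlated errors,
amplification jackpots within UMI clusters, and indel sequencing errors
— none of which are modelled. Passing tests therefore demonstrate that
the bookkeeping (classification, counting, metric algebra, exact
residual-error arithmetic) is correct under controlled conditions, not
that any particular correction tool will behave comparably on real
libraries. Problem sizes used by the test suite and the acceptance
script (1–5 kb references, 9 kb two-haplotype mixtures, 10^4 read pairs,
10^4 random trios) were chosen as the smallest sizes at which the
binomial 4σ calibration checks are meaningful.

## Known limitations

- Raw-read indel errors are not simulated; the classifier's indel
  columns are exercised only through corrected-read indels and trimming.
- UMI clustering is exact-match; sequencing errors inside the UMI itself
  create spurious small clusters (real pipelines often merge UMIs within
  1 mismatch).
- The two-stage profile alignment is a heuristic stand-in for full
  three-way alignment; for substitution-dominated short reads the two
  agree, but heavily indel-edited corrected reads may be tiled
  differently than a simultaneous three-sequence optimum would.
- Haplotype truth assignment ignores mapping quality ties beyond the
  documented deterministic tie-break; in a mixture of near-identical
  haplotypes, reads from shared regions are assigned to the
  first-listed haplotype, which is irrelevant for truth replacement
  (the windows are identical there) but visible in assignment reports.
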