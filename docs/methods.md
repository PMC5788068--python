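# Methods

## Workflow

seqscrub implements a two-pass quality-control design: statistics are
taken on the raw reads, the preprocessing chain runs, the same
statistics are taken on the surviving reads, and the warn/fail verdict
is evaluated on the *clean* statistics only. Raw statistics are reported
but never judged — the point of the second pass is to detect a
preprocessing setup that is unsuitable for the dataset at hand.

The per-read chain runs in a fixed order: fixed end trimming → 3'
adapter localization and cutting → quality end trimming → optional
DNA/RNA transform → filter battery → (globally) deduplication. Adapter
detection runs before quality trimming so it sees the unmutilated 3'
sequence; quality trimming afterwards can still erode what the adapter
cut exposed. Zero-length reads are legal intermediates and are removed
by the length filter.

## Statistics and quantiles

All QC state lives in two mergeable accumulators. `PositionStats` holds,
per cycle, a 5-vector of base counts over {A, C, G, T, N} (U from
RNA-transformed reads counts as T; any unrecognized character counts as
N) and a 94-bin quality histogram (Phred 0–93). `DatasetStats` adds
dataset totals and the per-reason filter tally. Merging is elementwise
addition, padded to the longer read length; the empty accumulator is the
identity, and merging is associative and commutative. Every block of a
parallel run produces one accumulator pair, and the whole-run statistics
are the fold of the block deltas — tested to be identical to a serial
accumulation.

Per-cycle quantiles (boxplot min/Q1/median/Q3/max) use the inverted-CDF
(type-1) rule on the integer histogram: the q-quantile is the smallest
Phred value whose cumulative count reaches ⌈q·depth⌉. On integer-valued
Phred data this is exact, order-statistic-equivalent, and cheap on a
histogram; it is cross-checked in the tests against a sort-based oracle.

## Verdict thresholds

On the clean data, per cycle:

* median quality < 20 → fail; otherwise < 25 → warn;
* |A% − T%| or |G% − C%| > 20 percentage points → fail; otherwise > 10 →
  warn.

All comparisons are strict, so values exactly at a threshold never
trigger. Composition percentages use the cycle depth including N as the
denominator, and the percentage-point difference is computed from the
integer counts (|countA − countT|·100/depth) rather than from stored
fractions, so boundary cases compare exactly in floating point.
Every nonzero-depth cycle is evaluated; low-depth trailing cycles are
not suppressed, but findings carry their position so users can discount
them.

## Adapter alignment

The adapter scanner is an exhaustive ungapped scan: every start offset
from 0 to length − min_overlap is scored by comparing the adapter prefix
to the read gaplessly, with overhang off the 3' end allowed. `N` in the
read counts as a mismatch. A candidate is valid when its aligned length
reaches `min_overlap` (default 6) and its mismatch count stays within
⌊rate·aligned_len⌋ (default rate 0.1). Among valid candidates the
smallest mismatch rate wins, ties broken by the leftmost offset; an
exact match short-circuits the scan (nothing can beat rate 0, and the
first exact match is already the leftmost). Insertions and deletions are
never considered — a single inserted base inside an otherwise exact
adapter destroys the hit at mismatch budget 0, which the tests assert.
Defaults are conventional for 3'-adapter trimmers and configurable.
Cutting removes everything from the adapter start through the 3' end.
Reads with a detected adapter are trimmed by default; `drop_adapter_reads`
discards them instead.

## Filters and attribution

Filters run in a fixed order — excluded batch, adapter (when dropping),
length (minimum, and the length-window maximum where configured),
ambiguous-base fraction, mean quality, low-quality-base fraction — and a
dropped read is tallied under the first failing check only. This makes
the conservation law `raw reads = clean reads + Σ tally` exact, which is
asserted after every pipeline run. For pairs, a check fails when either
mate fails it and one verdict covers the pair, so output mate files stay
synchronized with no orphan reads. Tallies are in read units (a dropped
pair counts 2), keeping conservation exact for paired data. A "low
quality base" is one with Phred strictly below `low_qual_value` (default
5); "mean quality" is the arithmetic mean of Phred scores. All filter
comparisons are strict, mirroring the verdict rules.

Module-specific tally keys extend the fixed families through the same
mechanism: `polya` (sRNA poly-A contaminants), `no_anchor` (DGE reads
without the anchor motif). sRNA reads beyond the length-window maximum
are tallied under `short_length`, documented here as the length-window
reason.

Deduplication is sequence-identity only: the key is a 128-bit MD5 digest
of the uppercase bases (mate1 + separator + mate2 for pairs), so
qualities and read names are ignored and orientation is as given. The
first occurrence is kept. Because dedup is order-dependent, it runs as a
single streaming pre-pass over the input before blocking — per-block
stages stay pure and the serial ≡ parallel guarantee holds exactly. The
key set lives in memory (16 bytes/unique sequence), which is the
intended desk scale.

## Modules

* **general** — the full chain, for DNA resequencing.
* **dge** — single-end tag extraction: the first occurrence of the
  anchor motif (default `CATG`, the NlaIII site) is located and the 17
  bases following it are retained, anchor excluded (the anchor is
  adjacent to, not part of, the target; `keep_anchor` prepends it for
  CATG+17 conventions). Anchor-less reads and tags containing any N are
  dropped — zero N tolerance overrides the general fraction threshold.
  Multiple anchor occurrences resolve to the leftmost.
* **srna** — single-end: adapter cut (small-RNA inserts are shorter than
  the read, so most reads carry the adapter), poly-A removal (A-content
  ≥ 0.7 of the read, the `polya_fraction` default, chosen to separate
  adenine-dominated mRNA contaminants from genuine inserts), then an
  18–30 nt length window reflecting mature small-RNA sizes, then quality
  filters.
* **meta** — the general chain with the mean-quality and
  low-quality-fraction filters, dedup, and batch exclusion disabled by
  default (all overridable): adapter and quality end trimming plus
  length and ambiguity filters.

## Quality encodings

Phred+33 and Phred+64 are supported; scores are stored numerically and
the offset only affects serialization, so conversion is involutive by
construction. Auto-detection uses the standard disjointness argument:
any quality character below ASCII 59 proves +33; all characters ≥ 64
with a maximum above 74 indicate +64; otherwise +33 is assumed and the
call flagged ambiguous. Only 4-line FASTQ records are accepted (the
universal instrument output form); parse errors name the 1-based record
ordinal. Desynchronized paired files are an error at the first offending
record — re-pairing is out of scope.

## Block-parallel execution

Input pairs are cut into fixed-size blocks (default 100 000 reads).
Each block is processed by one task on a thread pool; block results are
merged in ascending block index, so clean FASTQ bytes and all reports
are a pure function of (input, configuration), independent of worker
count and completion order — asserted byte-for-byte on a grid of
(workers, block size) combinations. Output order equals input order.
Merged output files are written under temporary names and moved into
place atomically; with merging disabled, per-block files carry
zero-padded index suffixes and concatenate to the integrated file. A
failing block aborts the run naming the block index.

## Synthetic data

The fixture generator emulates the features the workflow must recover,
with a sidecar ground-truth table (one row per read): adapter
read-through planted by overwriting the read suffix at a recorded
offset; duplicates created by copying an earlier read's bases (fresh
qualities — dedup is sequence-only); DGE reads built as prefix + anchor
+ tag + suffix with earlier accidental anchor occurrences scrubbed;
sRNA reads as insert + adapter fill, with poly-A contaminants at a
configurable rate; per-cycle quality from a clipped discretized normal
around a target median (symmetric, so the median recovers the target
exactly at large n); optional per-cycle A/T composition bias. Read names
follow the CASAVA colon convention with configurable tile labels so
batch exclusion is testable. Everything is a pure function of the seed.

It does not model platform error spectra, indels, genome-derived
sequence, or coverage structure — passing tests demonstrate the
correctness of the bookkeeping and decision rules, not performance on
any particular instrument's artifacts.

Two deterministic builders sharpen the threshold scans: one gives a
designated cycle an exact type-1 median (half the reads at q, half at
q+5), the other an exact A/T count imbalance; 1000 reads make every
integer percentage-point step exact. Scans over median 0–40 and
imbalance 0–30 recover the cut points 20/25 and 10/20 exactly.

## Problem sizes and budgets

Default test and acceptance runs use 100–4000 read fixtures per case and
one 100 000-read fixture for the serial ≡ parallel grid; the adapter
oracle comparison uses 1000 randomized cases and the monoid check 200
random splits. These sizes exercise every code path while keeping the
full suite around a minute on one CPU.

## Known limitations

* No gapped or scored adapter alignment, adapter inference, 5' adapters,
  or UMI handling.
* No orphan-read rescue: a failing mate drops the pair.
* Dedup memory grows with unique sequences; no disk-backed or
  probabilistic mode.
* Plots are minimal matplotlib renderings of the report tables, not
  publication figures.
* Per-read quality/length distributions, DGE singleton filtering, and
  sRNA screening against ncRNA databases are not implemented.
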